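"""LFP observation model and two-condition synthetic dataset generation.

Each region's pyramidal depolarization is observed directly with unit gain
(one channel per region, no sensor mixing).  Observation noise is Gaussian,
smoothed along time with a 4-sample kernel and scaled so the ratio of mean
signal power to mean noise power hits a target SNR (25 dB by default, the
level of a very good ERP recording).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import N_STATES, V_PYR, ERPParameters, NetworkSpec, MODULATED, BASELINE
from .integrators import SolverOptions, Trajectory, integrate

__all__ = [
    "SimulatedDataset",
    "observe_lfp",
    "make_noise",
    "scale_to_snr",
    "generate_dataset",
]

SMOOTHING_SAMPLES = 4  # noise smoothing kernel length, in time samples


def observe_lfp(traj: Trajectory, net: NetworkSpec) -> np.ndarray:
    """Channels x samples matrix: region-k channel = region-k v_pyr, gain 1."""
    idx = np.arange(net.n_regions) * N_STATES + V_PYR
    return traj.sampled_states[:, idx].T.copy()


def make_noise(shape, tau_ms: float = 1.0,
               seed: Optional[int] = None) -> np.ndarray:
    """Smoothed Gaussian observation noise (pre-scaling).

    Per-channel i.i.d. standard normal deviates convolved along time with a
    normalized 4-sample boxcar.  ``tau_ms`` is the sampling interval and is
    recorded for bookkeeping only: the kernel is defined in samples.
    """
    n_ch, n_t = shape
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_ch, n_t + SMOOTHING_SAMPLES - 1))
    kernel = np.full(SMOOTHING_SAMPLES, 1.0 / SMOOTHING_SAMPLES)
    return np.stack([np.convolve(raw[c], kernel, mode="valid")
                     for c in range(n_ch)])


def scale_to_snr(signal: np.ndarray, noise: np.ndarray,
                 target_db: float) -> np.ndarray:
    """Scale ``noise`` so 10 log10(P_signal / P_noise) equals ``target_db``.

    Powers are pooled over all channels and samples (one global factor).
    """
    p_sig = float(np.mean(np.asarray(signal) ** 2))
    p_noi = float(np.mean(np.asarray(noise) ** 2))
    if p_sig == 0.0:
        raise ValueError("signal has zero power; SNR undefined")
    return noise * np.sqrt(p_sig / (p_noi * 10.0 ** (target_db / 10.0)))


def measured_snr_db(signal: np.ndarray, noise: np.ndarray) -> float:
    """Realized SNR in dB of a signal/noise pair."""
    return 10.0 * np.log10(np.mean(signal ** 2) / np.mean(noise ** 2))


@dataclass
class SimulatedDataset:
    """Two-condition observed LFP series plus generative ground truth."""

    times: np.ndarray
    y_baseline: np.ndarray     # channels x samples
    y_modulated: np.ndarray
    net: NetworkSpec
    params: ERPParameters
    scheme: str
    snr_db: float
    seed: Optional[int]
    clean_baseline: Optional[np.ndarray] = None
    clean_modulated: Optional[np.ndarray] = None

    @property
    def n_channels(self) -> int:
        return self.y_baseline.shape[0]

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def observations(self) -> np.ndarray:
        """Stacked (2, channels, samples) array, baseline first."""
        return np.stack([self.y_baseline, self.y_modulated])

    def to_json(self, path):
        """Persist arrays plus a generative manifest as one JSON archive."""
        payload = {
            "times": self.times.tolist(),
            "y_baseline": self.y_baseline.tolist(),
            "y_modulated": self.y_modulated.tolist(),
            "scheme": self.scheme,
            "snr_db": self.snr_db,
            "seed": self.seed,
            "manifest": _ground_truth_manifest(self.net, self.params),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def export_text(self, prefix):
        """Delimited-text export, one file per condition (time + channels)."""
        for name, y in (("baseline", self.y_baseline),
                        ("modulated", self.y_modulated)):
            arr = np.column_stack([self.times, y.T])
            header = "time_ms\t" + "\t".join(
                f"region{k + 1}" for k in range(self.n_channels))
            np.savetxt(f"{prefix}_{name}.tsv", arr, delimiter="\t",
                       header=header, comments="")


def _ground_truth_manifest(net: NetworkSpec, params: ERPParameters) -> dict:
    return {
        "n_regions": net.n_regions,
        "A_forward": net.A_forward.tolist(),
        "A_backward": net.A_backward.tolist(),
        "A_lateral": net.A_lateral.tolist(),
        "C_input": net.C_input.tolist(),
        "D_extrinsic": net.D_extrinsic.tolist(),
        "modulation_factors": {
            k: np.asarray(v, dtype=float).tolist()
            for k, v in params.modulation_factors.items()},
        "tau_e": params.tau_e,
        "tau_i": params.tau_i,
        "input_onset": params.input_onset,
        "input_width": params.input_width,
    }


def generate_dataset(net: NetworkSpec, params: ERPParameters,
                     options: Optional[SolverOptions] = None,
                     snr_db: float = 25.0, seed: Optional[int] = None,
                     t_grid: Optional[np.ndarray] = None,
                     keep_clean: bool = True) -> SimulatedDataset:
    """Simulate a baseline + modulated dataset at calibrated SNR.

    Both conditions are integrated (with the adaptive Runge-Kutta scheme by
    default), observed through the unit-gain LFP model, and corrupted with
    independently drawn smoothed Gaussian noise; one global scale factor per
    condition calibrates the noise to ``snr_db``.
    """
    options = options or SolverOptions(scheme="rk")
    traj_b = integrate(net, params, BASELINE, options, t_grid)
    traj_m = integrate(net, params, MODULATED, options, t_grid)
    y_b = observe_lfp(traj_b, net)
    y_m = observe_lfp(traj_m, net)
    times = traj_b.sampled_times
    tau = float(times[1] - times[0])
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(2)
    out = []
    for y, sub_seed in zip((y_b, y_m), sub):
        noise = make_noise(y.shape, tau, seed=sub_seed)
        out.append(y + scale_to_snr(y, noise, snr_db))
    return SimulatedDataset(
        times=times, y_baseline=out[0], y_modulated=out[1], net=net,
        params=params, scheme=options.scheme, snr_db=snr_db, seed=seed,
        clean_baseline=y_b if keep_clean else None,
        clean_modulated=y_m if keep_clean else None)
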