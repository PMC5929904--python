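"""Structured-text serialization of model specifications and datasets.

Network and parameter specifications round-trip through YAML with keys
mirroring the dataclass fields; matrices are row-major nested lists and
region indices are 1-based in files (0-based in memory).  Datasets
round-trip through the JSON archive written by
:meth:`delaydcm.observation.SimulatedDataset.to_json`.
"""

from __future__ import annotations

import json
from dataclasses import asdict
import numpy as np
import yaml

from .model import ERPParameters, NetworkSpec
from .observation import SimulatedDataset

__all__ = [
    "save_network",
    "load_network",
    "save_parameters",
    "load_parameters",
    "load_dataset",
]


def _mask_to_pairs(mask: np.ndarray) -> list:
    """Boolean connection mask -> list of 1-based [target, source] pairs."""
    return [[int(k) + 1, int(l) + 1] for k, l in zip(*np.nonzero(mask))]


def _pairs_to_mask(pairs, n: int) -> np.ndarray:
    mask = np.zeros((n, n), dtype=bool)
    for k, l in pairs or []:
        mask[int(k) - 1, int(l) - 1] = True
    return mask


def save_network(net: NetworkSpec, path) -> None:
    doc = {
        "n_regions": net.n_regions,
        "A_forward": net.A_forward.tolist(),
        "A_backward": net.A_backward.tolist(),
        "A_lateral": net.A_lateral.tolist(),
        "C_input": net.C_input.tolist(),
        "D_extrinsic_ms": net.D_extrinsic.tolist(),
        "mod_forward": _mask_to_pairs(net.mod_mask_forward),
        "mod_backward": _mask_to_pairs(net.mod_mask_backward),
        "mod_intrinsic": [int(k) + 1
                          for k in np.nonzero(net.mod_mask_intrinsic)[0]],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_network(path) -> NetworkSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    n = int(doc["n_regions"])
    intr = np.zeros(n, dtype=bool)
    for k in doc.get("mod_intrinsic") or []:
        intr[int(k) - 1] = True
    return NetworkSpec(
        n,
        A_forward=doc.get("A_forward"),
        A_backward=doc.get("A_backward"),
        A_lateral=doc.get("A_lateral"),
        C_input=doc.get("C_input"),
        D_extrinsic=doc.get("D_extrinsic_ms"),
        mod_mask_forward=_pairs_to_mask(doc.get("mod_forward"), n),
        mod_mask_backward=_pairs_to_mask(doc.get("mod_backward"), n),
        mod_mask_intrinsic=intr,
    )


def save_parameters(params: ERPParameters, path) -> None:
    doc = asdict(params)
    doc["modulation_factors"] = {
        k: np.asarray(v, dtype=float).tolist()
        for k, v in params.modulation_factors.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_parameters(path) -> ERPParameters:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    mf = {k: np.asarray(v, dtype=float)
          for k, v in (doc.pop("modulation_factors", None) or {}).items()}
    return ERPParameters(modulation_factors=mf, **doc)


def load_dataset(path) -> SimulatedDataset:
    """Load a dataset archive written by ``SimulatedDataset.to_json``."""
    with open(path) as fh:
        doc = json.load(fh)
    man = doc["manifest"]
    n = int(man["n_regions"])
    net = NetworkSpec(
        n, A_forward=man["A_forward"], A_backward=man["A_backward"],
        A_lateral=man["A_lateral"], C_input=man["C_input"],
        D_extrinsic=man["D_extrinsic"],
        mod_mask_forward=np.asarray(man["A_forward"], float) > 0,
        mod_mask_backward=np.asarray(man["A_backward"], float) > 0)
    params = ERPParameters(
        tau_e=man["tau_e"], tau_i=man["tau_i"],
        input_onset=man["input_onset"], input_width=man["input_width"],
        modulation_factors={k: np.asarray(v, float)
                            for k, v in man["modulation_factors"].items()})
    return SimulatedDataset(
        times=np.asarray(doc["times"], float),
        y_baseline=np.asarray(doc["y_baseline"], float),
        y_modulated=np.asarray(doc["y_modulated"], float),
        net=net, params=params, scheme=doc["scheme"],
        snr_db=float(doc["snr_db"]), seed=doc["seed"])
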