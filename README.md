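# delaydcm

Dynamic causal modeling (DCM) of event-related electrophysiological
responses, with two interchangeable solvers for the delay differential
equations (DDEs) that govern the underlying neural mass model.

## The problem

DCM explains evoked responses (LFP/EEG/MEG) with a biophysical network
model: each brain region is a 3-subpopulation neural mass (spiny stellate,
pyramidal, inhibitory interneuron populations) coupled by forward, backward
and lateral connections, and differences between experimental conditions are
modeled as multiplicative *modulations* of connection strengths.  Because
axonal conduction takes milliseconds — the same scale as synaptic dynamics —
the model is a system of DDEs,

    dx/dt = f(t, u(t), x(t − d_kl)),

with intrinsic (within-region, 2 ms) and extrinsic (between-region, free,
16 ms prior) conduction delays `d_kl`.

Standard DCM software sidesteps the DDEs: delayed states are replaced by a
first-order Taylor expansion `x(t−d) ≈ x(t) − d·ẋ(t)`, turning the system
into ODEs solved with a fixed-step local-linearization update
`x(t+τ) = x(t) + (e^{τJ} − I)J⁻¹ ψ(t, x(t))`.  This package implements that
scheme (`ta`) next to a dde23-style adaptive embedded Runge–Kutta 2(3)
solver with a cubic-Hermite continuous extension (`rk`), and the full
workflow needed to quantify what the approximation does to scientific
conclusions: calibrated synthetic two-condition datasets, variational-
Laplace inversion (free energy `F = accuracy − complexity`), random-effects
Bayesian model selection (Dirichlet expected/exceedance probabilities) and
Bayesian model averaging.

It is a library for users who fit neural mass models to event-related data
and need to know whether their delay and connectivity estimates are solver
artifacts.

## Worked example

`examples/02_delay_sweep.py` integrates a 2-region, forward-only network
noiselessly with both schemes while sweeping the conduction delay:

```
region-2 latency shift relative to the 4 ms delay:
  delay    8 ms: rk +4 ms, ta +3 ms (ideal +4)
  delay   16 ms: rk +12 ms, ta +9 ms (ideal +12)
  delay   32 ms: rk +28 ms, ta +18 ms (ideal +28)
```

The adaptive solver shifts the downstream response by exactly the delay
increment and leaves its shape untouched (peak 0.399 mV throughout); the
Taylor scheme attenuates the shift (+18 ms instead of +28 ms) and inflates
the peak (0.408 → 0.657 mV as the delay grows) — the integration artifact
that propagates into parameter estimates.

`examples/03_invert_dataset.py` generates a 25 dB SNR dataset whose forward
connection is modulated by 0.5 and backward by 0.8 between conditions, then
inverts the generative model with the adaptive scheme:

```
converged after 7 iterations, F = 5907.3 (accuracy 5955.9, complexity 48.6)
  b_forward_1_0    estimate   0.50  90% CI [  0.50,   0.50]  (true 0.5)
  b_backward_0_1   estimate   0.79  90% CI [  0.76,   0.83]  (true 0.8)
  delay_1_0        estimate  15.74  90% CI [ 15.54,  15.93]  (true 16.0)
  delay_0_1        estimate  15.77  90% CI [ 15.46,  16.09]  (true 16.0)
```

`examples/04_model_comparison.py` runs the reduced 2-region study (8
datasets, F/B/FB model family) and reports the random-effects comparison;
the generative FB model wins with expected posterior probability > 0.8 and
exceedance probability ≈ 1.

A thin CLI mirrors the experiment drivers
(`delaydcm delay-sweep`, `simulate`, `fit`, `bms`, `sim1`, `sim2`).

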