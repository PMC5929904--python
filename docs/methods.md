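# Methods

## Neural mass model

Each region contains three interacting populations — spiny stellate cells,
pyramidal cells, inhibitory interneurons — with 9 state variables per
region.  Synaptic transmission is the standard second-order operator: a
postsynaptic potential `v` driven by presynaptic input `u` obeys

    v̈ = (H/τ)·u − (2/τ)·v̇ − v/τ²,

the impulse response of which is the alpha kernel `H (t/τ) e^{−t/τ}`
peaking one time constant after the input.  Excitatory synapses use
`H_e = 3.25 mV`, `τ_e = 8 ms`; inhibitory synapses `H_i = 22 mV`,
`τ_i = 16 ms`.  Voltages map to firing through the rest-normalized logistic
`S(v) = σ(ρ₁(v − ρ₂)) − σ(−ρ₁ρ₂)` with `ρ₁ = 2 mV⁻¹`, `ρ₂ = 1 mV`, so the
zero state is an exact fixed point.  Intrinsic coupling constants are
`γ₁ = 128`, `γ₂ = 0.8·γ₁`, `γ₃ = γ₄ = 0.25·γ₁`.

A units subtlety is handled explicitly: these gain and coupling constants
are calibrated for firing rates per second, while the package advances time
in milliseconds.  Every synaptic *drive* term therefore carries a factor
`DRIVE_SCALE = 10⁻³` (the decay terms are unit-free).  Omitting the factor
destabilizes the rest state by three orders of magnitude in loop gain.

Connectivity follows the ERP-DCM rules: forward connections target the
stellate population, backward connections the pyramidal and inhibitory
populations, lateral connections all of them; all extrinsic afferents read
the source region's pyramidal depolarization.  Extrinsic strengths are
dimensionless values in `NetworkSpec` multiplied by per-type base gains
(forward 32, backward 16, lateral 4, input 32), so a strength of 1 is the
"default" connection and uniform draws on [0, 2] span weak to double-
strength coupling.  The observed channel per region is the pyramidal
depolarization with unit gain (LFP convention, no lead field).

Delays: zero inside a population, 2 ms between populations of one region,
and a free per-connection extrinsic delay (prior expectation 16 ms) between
regions.  The stimulus is a Gaussian bump (peak 64 ms, SD 8 ms, amplitude 1
scaled by the input gain), producing first cortical peaks near 90–100 ms.

## Integration schemes

**`ta` (Taylor + local linearization).**  Substituting
`x(t−d) ≈ x(t) − d·ẋ(t)` and solving for `ẋ` gives the compensated ODE
field `ψ = (I + D∘J)⁻¹ f₀(t, x)`, where `D` is the state-to-state delay
matrix, `J` the no-delay Jacobian (analytic, finite-difference-verified)
and `f₀` the field with delays ignored.  The ODE advances with the exact
linear-system propagator `x ← x + (e^{τJψ} − I)Jψ⁻¹ ψ` at the fixed output
step `τ` (1 ms here).  The φ₁ matrix function is computed via the augmented
matrix exponential `expm([[τJ, τI], [0, 0]])`, which is well defined for
the structurally singular Jacobians of this model.  By default `J` and the
compensation operator are re-evaluated at the current state every step
(`ta_jacobian="step"`); `ta_jacobian="fixed"` freezes both at the rest
state, the cheaper variant common in standard DCM software.  Both variants
behave nearly identically on this model family.

**`rk` (adaptive DDE solver).**  An embedded Bogacki–Shampine 2(3) pair
with its natural cubic-Hermite continuous extension, integrated by the
method of steps: delayed values are interpolated from the accepted mesh,
and when the trial step exceeds the smallest positive delay the step is
iterated to self-consistency on an extrapolated interpolant (predictor from
the previous mesh interval, up to 5 corrections, rejection and halving on
non-convergence).  Error control uses the weighted norm
`max |err| / (abs_tol + rel_tol·|x|) ≤ 1` with defaults
`rel_tol = 10⁻³`, `abs_tol = 10⁻⁶`; step-size controller
`h ← h·min(5, max(0.2, 0.9·errnorm^{−1/3}))` with growth suppressed right
after a rejection; initial step `min(smallest delay, 1 ms)`.  Discontinuity
tracking at delay multiples is deliberately omitted: the Gaussian input is
smooth and the mild C¹ discontinuities are handled by error control (the
solver is verified against exact method-of-steps polynomials).

The default `max_step` is 4 ms.  For inversion runs the solver is used with
`rel_tol = 10⁻²` and `max_step = 2 ms` (the intrinsic delay): at this
sampling density fully explicit 2 ms steps are cheaper than the in-step
correction, and a 1% tolerance changes recovered parameters negligibly
while roughly halving run time.  Dataset generation always uses
`rel_tol = 10⁻³`.

## Synthetic datasets

A dataset is a baseline and a modulated condition sharing all parameters
except the masked modulation factors, integrated with the `rk` scheme,
observed through the unit-gain LFP model, and corrupted with observation
noise: per-channel i.i.d. Gaussian deviates smoothed with a normalized
4-sample boxcar (lag-1 autocorrelation 3/4), drawn independently per
condition from per-dataset sub-seeds, and scaled by one global factor so
that pooled signal power over pooled noise power is exactly 25 dB.

The 2-region study uses baseline strengths 8 (forward) and 2 (backward).
These are the package's calibration of values the design leaves open,
chosen so both regions respond with comparable amplitude and the modulation
(forward ×0.5, backward ×0.8) visibly affects both regions while the system
stays stable — and frozen before any recovery experiments were run.  The
6-region study draws strengths uniformly on [0, 2] and reciprocal-pair
delays uniformly on [8, 32] ms, modulates every forward and backward
connection by 0.5, and rejects draws whose noiseless response exceeds
10³ mV (instability proxy).  Its topology: forward 1→2, 1→3, 2→3, 4→5,
4→6, 5→6 with reciprocal backward links, lateral pairs 1↔4 and 3↔6
(configurable), input to regions 1 and 4.

What the generator does *not* emulate: trial-level variability (conditions
are averaged recordings by construction), sensor mixing/lead fields,
temporally structured physiological artifacts, and inter-subject parameter
variability beyond the random draws of the 6-region design.  Passing
recovery tests therefore demonstrate solver- and inference-correctness
under the model's own assumptions, not robustness to real-data violations
of them.

## Variational inversion

Free parameters live on a latent log scale: every positive natural
parameter is `template·exp(θ)` (baseline extrinsic gains, modulation gains,
extrinsic delays against the 16 ms prior, τ_e/τ_i scalings, input
onset/width scalings), each with prior `N(0, 1/16)` — the standard "low"
prior precision of 16.  Intrinsic coupling constants stay fixed.  The
observation model is i.i.d. Gaussian with a single precision shared across
channels and conditions; its log precision has a broad `N(0, 32)`
hyperprior and is updated in closed form (`λ = N / (‖e‖² + tr(JΣJᵀ))`),
with the hyperparameter KL included in the complexity term.  The temporal
correlation introduced by the 4-sample noise kernel is knowingly ignored by
the likelihood — a standard simplification that slightly overstates the
effective number of observations.

The E-step is Levenberg–Marquardt-regularized Gauss–Newton on the latent
vector with forward-difference sensitivities (step 10⁻³; columns for
modulation latents re-integrate only the modulated condition).  A proposed
step is accepted only if the fully re-evaluated free energy increases;
otherwise the damping is multiplied by 8 and the step retried (up to 8
times).  Convergence: |ΔF| < 0.01 for 3 consecutive accepted iterations, or
64 iterations (32 in the experiment presets).  This makes the recorded
free-energy trace non-decreasing by construction, which the test suite
asserts on every fit.

Free energy is the standard Laplace bound: accuracy is the posterior-
expected Gaussian log-likelihood (including the sensitivity-propagated
trace term), complexity the KL divergence from the Gaussian posterior to
the prior plus the hyperparameter KL, and `F = accuracy − complexity`.

## Model comparison and averaging

Random-effects BMS treats the generating model as varying across datasets:
a variational Dirichlet scheme alternates per-dataset responsibilities
`softmax(F_nm + ψ(α_m) − ψ(Σα))` with `α = 1 + column sums` until the
concentrations stabilize (tolerance 10⁻⁴).  Exceedance probabilities are
Monte-Carlo estimates from 10⁶ normalized-Gamma Dirichlet draws (seeded;
MC error ≪ 0.005).  One property worth knowing: at convergence a dataset
with *equal* evidences is tilted toward the prevailing model by the
digamma term, so adding an uninformative dataset does not necessarily pull
the expected probabilities toward uniform.  Bayesian model averaging
combines per-dataset posteriors of the winning model (highest expected
posterior probability) weighted by each dataset's posterior model
probability: mixture mean `Σ w m` and mixture variance
`Σ w (v + m²) − (Σ w m)²` on the latent scale.

## Problem sizes

Full presets mirror the complete study designs (Simulation 1: delays 4–32
ms in 4 ms steps × 10 datasets; Simulation 2: 100 datasets), which are
multi-hour single-core jobs.  The test suite and the acceptance script run
desk-scale reductions chosen as the package's own defaults: 6–8 datasets
per question, epoch 0–400 ms at 1 ms sampling (300 ms in the `-small`
presets), fitting at `rel_tol = 10⁻²`.  The reduced model-selection preset
uses 2 delays × 4 datasets because the Dirichlet mean under unanimous
selection is `(1+n)/(3+n)`: eight datasets are the minimum that can exceed
an expected posterior probability of 0.8 for three models.

## Known limitations and observed behavior

* With the per-step-linearized `ta` scheme and this package's calibrated
  2-region generative setup, the `ta`-equipped inversion does **not** leave
  conduction delays near their 16 ms prior when the true delay is 32 ms:
  the backward delay inflates dramatically (the Taylor compensation then
  acts as an effective silencer of the mis-timed backward influence), and
  at delay 16 the backward modulation is over- rather than under-estimated.
  The robust, reproducible signatures are that `ta` mis-estimates far more
  than `rk` and attains systematically lower free energy at equal
  complexity budgets; the *sign* of its bias depends on constants the
  design leaves open (sigmoid shape, gains, baseline strengths, the size of
  the free-parameter set).  Two acceptance checks encoding the sign are
  accordingly expected to fail and are kept as honest documentation.
* The noise model in the likelihood is white although the generator's noise
  is smoothed (see above).
* No EEG/MEG lead fields, neural-field variants, stiff/implicit solvers,
  state-dependent or distributed delays, or event location.
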