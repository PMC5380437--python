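# Methods

## Model overview and assumptions

The simulator implements a conductor–student–tutor architecture for
two-stage motor learning.  Time is discretized on a uniform grid over
one rendition of a motor program of duration `T` (default 1 s, the
scale of a song motif); every smoothing operation in the model —
muscle-like output filtering, the plasticity kernel, tutor error
integration, spike-rate estimation — is a causal exponential
convolution started from zero state at `t = 0`.  The rate-based model
is linear by construction: student rates, outputs, motor error and the
per-rendition weight update are all linear in the inputs, which is what
makes the matched-tutor derivation exact up to the slow-variation
approximation discussed below.

Key structural choices:

* **Conductor**: each neuron fires one 10 ms constant-rate burst per
  program; onsets tile `[0, T]` evenly, so the summed conductor drive
  is approximately constant in time and no activity pattern repeats.
* **Student→output map** `M`: each student neuron contributes to
  exactly one output channel (two channels by default), with equal
  weights `1/(students per channel)`.  This mirrors the empirical
  one-channel-per-premotor-neuron picture and makes credit scrambling
  well defined.
* **Inhibition**: a constant bias `x_inh` in the rate model, chosen at
  initialization so the student baseline is ≈ 0 (including the tutor's
  baseline drive `w·θ`); activity-dependent global inhibition in the
  spiking model.
* **Per-rendition updates**: the heterosynaptic rule is integrated over
  a whole rendition and applied once at its end, matching the
  derivation that equates the integrated update to the loss gradient.
  The optional positivity constraint clips weights at zero after each
  rendition's update, not within it.

## Within-rendition causal loop

The tutor reads the motor error of the *unfolding* rendition: at each
step the engine produces the tutor rate from the error integral
accumulated so far, adds the tutor drive to the student, updates the
smoothed output, and feeds the new error back into the integral.  Both
engines (rate and spiking) implement this loop with exponential-Euler
recursions in a compiled (numba) core; the module-level operations
(`exp_filter`, `motor_output`, `matched_tutor`, `weight_update`) use
trapezoid-exact quadrature and serve as the independent cross-checking
path in the tests (the compiled spiking core is additionally verified
spike-for-spike against the pure-numpy `step_network` integrator).

## Matched tutor and its regime of validity

For the plasticity kernel `K = α K₁ − β K₂`, the update accumulated
from an impulsive conductor burst expands as
`(α−β)(g−θ) + (ατ₁−βτ₂) g′ + O(ατ₁² g″)`.  Substituting the
error-integrating tutor shows the two leading terms reduce exactly to
`−ζ (α−β) ε(t_burst)` when `τ_tutor = τ_tutor* = (ατ₁−βτ₂)/(α−β)` —
i.e. matched tutoring is gradient descent.  The neglected terms scale
with `α τ₁²` times the curvature of the error signal, so the
equivalence is quantitative only when the kernel timescales are short
compared to the error's characteristic timescale and `τ_tutor ≫ τ₁,₂`.
The gradient-equivalence test therefore runs with `τ₁ = 4 ms`,
`τ₂ = 2 ms`, `τ_tutor = 40 ms`, a 50 ms-smooth target, a small output
smoothing (5 ms) and a 0.25 ms integration step, where the measured
cosine between the accumulated update and the negative
finite-difference gradient exceeds 0.99.  Outside this regime (large α
with τ₁ = 80 ms) learning still proceeds — descent only needs positive
overlap with the gradient — but the alignment is far from perfect,
which is expected from the expansion, not a defect of the
implementation.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| τ₁, τ₂ | 80, 40 | ms | plasticity kernel timescales |
| α − β | 1 | — | kernel normalization (scale absorbed in η) |
| θ | 80 | Hz | tutor rate threshold of the plasticity rule |
| η | 6e−4 (rate), 1e−2 (spiking) | per rendition | student learning rate |
| ζ | 120 (rate), 6 (spiking) | — | error→rate gain of the tutor |
| ρ | 80 | Hz | tutor saturation half-range (range 0–160 Hz) |
| τ_out | 25 | ms | muscle-like output smoothing |
| τ_est | 10 | ms | spike→rate estimation for the plasticity rule (5–40 ms family) |
| η_tutor | 0.02 (rate demo) | — | reinforcement learning rate of the tutor |
| explore σ, τ | 15 Hz, 40 ms | | exploration noise of the rate-engine reinforcement tutor |

The learning rates, gains and rate-model network sizes (100 conductor,
20 student neurons) are not constrained by published values; they were
fixed once so that matched learning at the default scale converges
within ~1000 renditions, and are all exposed in `ExperimentConfig`.
Presets are labelled *representative*, not reproductions of any
particular published figure.

## Spiking model

The student is a pool of current-based leaky integrate-and-fire
neurons.  Constants default to the songbird-calibrated set: rest/reset
−72.3 mV, threshold −48.6 mV, τ_m = 24.5 ms, refractory 1.1 ms, input
resistance 353 MΩ, τ_AMPA = 6.3 ms, τ_NMDA = 81.5 ms, 90% of tutor
current through NMDA receptors with magnesium-block gating
`G(V) = [1 + ([Mg]/3.57 mM) e^(−V/16.13 mV)]⁻¹` ([Mg] defaults to
1 mM, exposed in config), global inhibition strength 1.80 mV with a
20 ms trace, 300 conductor neurons, 80 students, 148 log-normal
conductor synapses per student (mean 32.6, sd 17.4), intra-burst rate
632 Hz.  Conductor bursts carry 5–6 spikes (alternating
deterministically unless randomized), with uniform ±0.3 ms onset and
±0.2 ms per-spike jitter redrawn each rendition; tutor neurons fire
per-bin Bernoulli realizations of an inhomogeneous Poisson process.
Integration is exponential-Euler at 0.1 ms (exact for the piecewise-
constant inputs between events), with the documented in-step order:
inputs applied → membrane updated → threshold tested.

**Unit convention.** The synaptic strengths above are kept at their
published numerical values, but a literal reading (nA against 353 MΩ)
would give volt-scale unitary EPSPs.  A single conversion constant
(`current_scale`, default 1e−3) maps the product R·I to millivolts of
drive — equivalently, the nA-labelled weights act at pA scale — giving
~11.5 mV unitary conductor EPSPs and an untrained network that fires
irregularly at juvenile-like rates (~50 Hz, ISI CV ≈ 0.6).  The 1 nA
pruning threshold lives on the same scale, so all published numbers
remain mutually consistent.

The desk-scale spiking preset halves the network (150 conductor, 40
student neurons, 74 synapses per student, same density) and uses the
saturating tutor with θ = ρ = 80 Hz; plasticity operates on
exponential-kernel rate estimates (τ_est = 10 ms) of the conductor and
tutor spike trains, with weights clipped at zero.

## Reinforcement tutor

The tutor's rate program `f_j(t)` is updated across renditions by
correlating its own rate fluctuations `ξ_j = g_j − ḡ_j` with the
baseline-subtracted instantaneous reward, `Δf_j = η_tutor (R − R̄) ξ_j`
(memory-less), or the same product filtered causally over `τ_tutor`.
The reward is the negative instantaneous squared output error — a
declared choice; any per-time monotone transform of the mismatch would
do — so it integrates to −2× the quadratic loss.  `R̄(t)` is an
exponential smoothing of `R` with a 1 s timescale whose initial value
is the previous rendition's terminal reward; `ḡ` relaxes toward the
realized rates with one e-fold per five renditions.  `ḡ` and `R̄` are
seeded from the first rendition so no state is undefined.  In the rate
engine the tutor explores with smooth Gaussian rate noise (sd 15 Hz,
40 ms correlation time — temporal correlation is what lets the
delayed, output-filtered reward credit the right moments); in the
spiking engine Poisson variability plays that role.  Convergence takes
thousands of renditions, roughly an order of magnitude more than
tutoring with known credit, consistent with the two-stage picture.

## Synthetic targets and what the tests do (and do not) show

Targets are white noise low-pass filtered with a Gaussian kernel at the
smoothness timescale (50 ms default) and mapped affinely into an
amplitude range ((0, 1) rate engine; (20, 90) Hz spiking), emulating
air-sac-pressure-like traces in smoothness and timescale while
otherwise arbitrary.  They do not reproduce the spectral content,
amplitude statistics or trial-to-trial structure of real recordings, so
passing tests demonstrate the learning-rule properties (matching,
robustness, statistics) on realistic-scale synthetic programs — not
fits to any particular animal's data.  Likewise the juvenile/adult
comparison is asserted only as statistic bounds (nonzero irregular
firing before training, burstier after), never as agreement with
recordings, and the external fitting loop for matching real firing
statistics is out of scope: only its objective function (the
scale-free relative error over the statistics vector) is provided, as
an adapter hook.

## Numerical choices and degenerate inputs

* Exponential filtering uses an O(n) recursion exactly equivalent to
  trapezoid quadrature of the convolution integral; halving `dt`
  shrinks its error linearly for smooth inputs.
* `optimal_timescale` raises for α = β (zero-area kernel); tutor
  construction rejects `τ_tutor = 0` outside reinforcement mode.
* Divergence (loss > 10³ × initial, or non-finite membrane state) is
  reported as an exception carrying the partial trace; sweep drivers
  record such cells and continue.
* Undefined spike statistics (fewer than 2/3 ISIs for CV/skewness, no
  bursts) are NaN-flagged and excluded from the relative-error
  objective with a warning.
* Burst statistics are computed per neuron and then averaged (a
  `pooled` flag switches to pooled ISIs).
* Conductor bursts at the program boundary may lose jittered spikes
  to clipping (times are confined to `[0, T]`).

## Experiment scales

Desk-scale defaults were chosen for routine runs: mismatch sweeps use a
5×5 grid × 200 renditions × 3 seeds (the 1000-cycle full grid is a
parameter change); spiking learning uses the half-size network for 600
renditions × 3 seeds; credit scrambling uses 1000 renditions.  Medians
over seeds are reported throughout (replicate counts are a package
choice).  The spiking mismatch-ordering check uses a long-memory rule
(α = 6, τ* = 280 ms) because tutor-student mismatch has weak effects
below ~100 ms — a property of the model itself (the kernel blurs
faster tutor variations), visible in the rate-model sweep as well.

## Known limitations

* The repository-shape choice: the package is a library with
  `examples/` scripts; experiment drivers are functions, not shell
  subcommands.
* Nonlinear student transfer functions, alternative kernel families and
  loss functions, push–pull output architectures, bursty (non-Poisson)
  tutor statistics, and explicit conductor voltage dynamics are out of
  scope.
* Reinforcement learning in the spiking engine is functional but slow
  (order 10⁴ renditions for full convergence, as expected for
  node-perturbation schemes); the rise-then-fall of surviving synapse
  counts during reward-driven learning is observable through the
  recorded pruning curve but is not asserted at test scale.
* The two-term kernel expansion — hence exact gradient equivalence —
  degrades for large α at fixed τ₁,₂, as described above.
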