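# Methods

This note documents the models, estimators and protocols the package
implements, the defaults it ships, and the choices made where the design
was genuinely open.

## The beta-oscillation surrogate

The test bed is a two-population neural mass: an excitatory population
(subthalamic-nucleus-like, the stimulation target) and an inhibitory
population (pallidal-like, the recording site), reciprocally coupled with
a one-sample (1 ms) conduction delay. Each population's mean voltage
passes through a critically damped second-order synapto-dendritic filter
with rate constant γ,

    V_e'' + 2γV_e' + γ²V_e = γ² (drive − g·S(V_i(t−d)) + ξ_e),
    V_i'' + 2γV_i' + γ²V_i = γ² (        g·S(V_e(t−d)) + ξ_i),

with S a logistic rate function of maximum 1, width 0.25 and threshold at
its inflection, ξ white Gaussian drive, and a small constant excitatory
input (`drive = 0.1`) that offsets the operating point slightly above the
inflection. The delayed negative-feedback loop undergoes a supercritical
Hopf bifurcation as the coupling gain g rises; the frequency at onset is
set by γ and the delay. Integration is explicit Euler at dt = 1 ms, which
keeps stimulus pulses aligned to samples; γ = 235 s⁻¹ places the
discrete-time oscillation at 29 Hz.

Two calibrated states ship in `data/defaults.yaml`:

| parameter | naive | dopamine-depleted (DD) |
|---|---|---|
| coupling gain g | 1.1 (below threshold) | 1.6 (above threshold) |
| dynamics | noise-sustained resonance | noisy limit cycle |
| beta-band power | ≈ −24 dB | ≈ −13 dB |

A slow Ornstein–Uhlenbeck modulation of γ (fractional sd 2.4 %,
correlation time 3 s) wanders the instantaneous oscillation frequency by a
fraction of a hertz over seconds. This is the mechanism that broadens the
DD spectral peak to its calibrated −6 dB half-width of ≈ 1.15 Hz. The
choice is deliberate: producing the same width with white-noise phase
diffusion alone would require a diffusion constant (≈ 8 rad²/s) that makes
the rhythm unpredictable beyond a single cycle, and no causal estimator —
including the matched αSWIFT — could then phase-lock stimulation to it.
Slow frequency wander reproduces the long-run linewidth that real
parkinsonian beta shows while keeping the phase predictable over the few
cycles the inner loop needs. The naive state uses the same wander.

DBS pulses are far shorter (90 μs) than the integration step, so each
pulse is integrated to its charge and applied as a voltage step
ΔV = I·t_pw / C_m to the excitatory population (C_m = 1 μF by default;
both are configurable). The recorded LFP is the inhibitory population's
voltage, standing in for a pallidal recording.

### What the surrogate does and does not emulate

It reproduces the printed spectral phenomenology — a 29 Hz peak (34.5 ms
period), ≈ ±1.15 Hz wide at −6 dB, elevated and widened in the DD state,
and suppressed by 130 Hz isochronal stimulation — and a rich, phase-
sensitive response surface for the feedback policies. It does not contain
cortex, thalamus or striatum, firing-rate readouts, plasticity, or
spiking; absolute dB levels and the coordinates of response-surface
minima are properties of this surrogate, not of any published full-scale
model, and the tests treat them only as orderings.

## Real-time phase/power estimation

The SWIFT recursion `X_n(ω) = e^{-1/τ} e^{jω} X_{n-1}(ω) + x[n]` computes
the Fourier coefficient of the signal under an infinite causal exponential
window; the αSWIFT subtracts a second accumulator with τ_fast = τ_slow/5,
which zeroes the window at t = 0 and sharpens the frequency response. The
amplitude response of the exponential window is
|W(f)| = τ/√(1+(2πfτ)²), so the half-amplitude (−6 dB) half-width is
√3/(2πτ): τ_slow = 0.240 s ↔ 1.15 Hz, matching the estimator's bandwidth
to the model's beta peak. (The −6 dB point is read as half *amplitude*;
reading it as half power would give a different, inconsistent pair.)

Conventions chosen here: power is normalized so a unit-amplitude tone at
the center frequency reads 0 dB in steady state; phase 0 is the
oscillation peak and ±π the trough; the estimator's output at sample n
uses inputs up to n−1 inside the closed loop (one-sample feedback
latency). Burn-in is the caller's concern; the closed-loop runner enables
stimulation only after 1 s.

## Stimulation policies and the evoked-response template

Five policies: OFF, isochronal 130 Hz (cDBS), power-gated cDBS,
phase-triggered, and combined phase/power. Phase crossing is detected on
wrapped phase (sign change of the wrapped difference to the trigger
within one sample), with a one-pulse-per-cycle latch cleared on phase
wrap; the combined policy does not re-arm within a cycle when power dips
below threshold and back. 130 Hz does not divide the 1 kHz sample rate,
so trains are scheduled by accumulated phase — intervals alternate 7 and
8 samples and the long-run rate is exactly 130 Hz.

Each pulse also evokes a stereotyped additive transient in the recorded
LFP. Left uncorrected, the narrowband estimator phase-locks to this
stimulus artifact rather than to the oscillation, and instrumented runs
show the commanded-to-achieved phase map then skips the suppressive
half-cycle entirely. The closed-loop runner therefore calibrates a
per-pulse evoked-response template once per parameter set — sparse probe
pulses at ≈ 2.7 Hz, incommensurate with the beta cycle, whose pulse-
aligned LFP average isolates the additive component while the
phase-dependent response averages out — and subtracts it, scaled linearly
with ΔV, from the estimator input stream. This mirrors standard artifact-
rejection practice in closed-loop neurostimulation.

## The outer loop

The objective is the measured biomarker: the running average of the
linear αSWIFT power over the evaluation window, reported in dB (linear
mean, then log — the alternative of averaging dB values weights quiet
epochs more heavily and is not what a running power average computes).
Default protocol per evaluation: apply the parameters, wait a settle
period, then average over a measurement window. The full protocol is
10 s + 10 s; the shipped desk-scale default is 2 s + 3 s, which keeps the
benchmark suite tractable on one CPU while preserving every ordering the
tests check (the full protocol is one configuration flag away).

GP details, in the order they matter:

* Inputs are scaled to the unit box; the phase dimension's distance is
  chordal, sin(π·Δu)/π, an isometric circle embedding that keeps the
  Matérn-5/2 kernel positive definite and makes length scales comparable
  across dimensions. Matérn-5/2 is the standard twice-differentiable
  default.
* The prior mean is learned as the training mean; outputs are centered.
* Hyperparameters (per-dimension length scales, signal variance, noise
  variance) are MAP estimates: marginal likelihood with weakly
  informative log-normal priors — length scales centered on a quarter of
  the box width, noise on var(y)/10, signal on var(y), each one decade
  wide — optimized by L-BFGS-B in log space with analytic gradients.
  Refits happen after every observation, warm-started, with a cold
  restart from the prior median every 15 iterations.
* A jitter of 1e−8 × signal variance stabilizes the Cholesky; posterior
  variance is clipped at zero (tolerance 1e−9).
* Acquisition: GP-LCB with κ_n = ν√τ_n, τ_n = 2 log(n^{d/2+2}π²/3δ),
  ν = 0.25, δ = 0.1. Minimization uses 32 Latin-hypercube starts advanced
  in lockstep by batched projected gradient descent (periodic dimensions
  wrap), then an L-BFGS-B polish of the best candidate; ties break to the
  lowest utility, then the earliest start.
* Runs start from n₀ = 3 uniform-random points. The final recommendation
  is the minimizer of the posterior mean (a κ = 0 search), i.e. the
  setting one would deploy after the run.
* Default bounds: phase [−π, π) (periodic), threshold [−60, 0] dB,
  amplitude [0, 5] mA.

## Benchmarking protocol

Response surfaces tabulate the noise-free objective (single fixed
simulation seed, 8 s window) on a grid — desk default 16 per dimension.
Baselines are bounded Nelder–Mead (out-of-box proposals clipped
coordinate-wise, uniform-random start, initial simplex spanning 15 % of
each box width — a benchmark-scale simplex, since a tiny relative
perturbation of a start near a bound degenerates the method) and DIRECT
(deterministic, first evaluation at the box center), both via scipy with
every evaluation intercepted; early terminations are padded by repeating
the final point.
Regret is computed from the noise-free surface at the visited points;
the noisy measurement only drives the optimizers. Average regret curves
are summarized by nonlinear least-squares fits of α + T₀e^{−T/τ}. The
noise experiment injects ε ~ N(0, σ²) dB into each measurement and
reports the fitted α against SNR = 20·log₁₀(σ_signal/σ_noise), with
σ_signal the sd of the surface values and σ_noise the repeated-measures
sd combined in quadrature with the injected σ. Desk-scale sizes: 50
trials × 100 iterations for the comparison, 20 trials for the noise
experiment, error bars as across-trial standard deviations.

## Numerical and degenerate-input conventions

Explicit Euler with a ring-buffer delay line; non-finite states raise a
blowup error naming the step index. The sigmoid saturates exactly at its
asymptotes under overflow. A zero αSWIFT accumulator reports −∞ dB.
Degenerate GP fits (fewer than two points) fall back to prior medians
with a warning; zero-spread targets drive the noise variance to its
floor. All randomness descends from integer seeds through the legacy
MT19937 generator; the compiled kernel and the pure-Python reference path
produce bit-identical trajectories, which the tests assert.

## Known limitations

* **Biomarker validity.** The landscape the controller optimizes is the
  narrowband (αSWIFT) beta power. In this surrogate, its deep minima
  combine genuine suppression with *detuning and decoherence* of the
  29 Hz rhythm — phase-locked pulses shift and spread the oscillation
  away from the estimator's center frequency — so the band-integrated
  (12–35 Hz Welch) power at the narrowband optimum is not reduced
  commensurately and can even rise. The spectral tests therefore use
  band-integrated power only for the open-loop claims (state contrast,
  cDBS dose response), and the landscape orderings are stated on the
  measured biomarker. This is a real concern for narrowband feedback
  control generally, amplified here by the surrogate's small size.
* The 1 ms Euler step ties pulse timing to the sample grid; sub-sample
  pulse placement is not modeled.
* The evoked-response template is calibrated in the unstimulated state
  and scaled linearly; at the highest amplitudes the true response is
  mildly nonlinear and the residual artifact grows.
* O(n³) GP updates are fine at the ~100-evaluation budgets used here;
  longer horizons would need sparse or windowed variants.
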