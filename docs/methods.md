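# Methods

This note documents the models implemented in `patchforage`, the parameter
choices that matter, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Reward schedules

Each of the three patches runs an independent variable-interval process.
State per patch: the time tᵢ of the most recent press and the active
sampled interval λᵢ. A press at time t is rewarded iff t − tᵢ ≥ λᵢ; in all
cases (rewarded or not) a fresh λᵢ is sampled and tᵢ ← t, so elapsed time
restarts at zero after every press. Time is continuous (64-bit float
seconds) and the simulator is event-driven; cue values can be queried at
arbitrary times.

Interval laws:

* Exponential, rate μⱼ = 1/mean. Hazard h(t) = μⱼ, constant. A premature
  reset resamples from the same memoryless law, so the waiting time to
  availability measured from any origin is unchanged — the package exposes
  `time_to_availability_after_reset` purely to demonstrate this invariance
  (two-sample KS against the reset-free law).
* Gamma, shape a = 10, rate bⱼ = a/mean (shape–rate parameterization, so
  a/bⱼ equals the mean exactly). The hazard f/(1−F) is zero at t = 0 and
  strictly increasing for a > 1; it is computed as exp(logpdf − logsf) so
  the ratio stays finite deep in the upper tail.

Both variants use mean intervals of 7/14/21 s for the fast/medium/slow
patches; the exponential variant inherits the same means so that variant
comparisons isolate hazard structure.

Cue variable X(t) ∈ [0, 1], per variant:

* exponential: X = 1 − e^(−μⱼ(t − tᵢ)) — the cumulative probability that
  reward has become available, a function of patch statistics and elapsed
  time only;
* gamma: X = min((t − tᵢ)/λᵢ, 1) — normalized progression through the
  active interval. The denominator is the active sampled interval λᵢ
  (the run from the last press to the moment availability begins).

X is nondecreasing between presses under both laws.

## Stimulus

Frames are synthesized in the Fourier domain on an N×N grid (default
N = 128) with integer DFT frequencies and DC at (0,0).

* Spatial amplitude envelope: S_A(u,v) = (u² + v²)^(−1/2), S_A(0,0) = 0.
* Temporal dynamics: each coefficient follows
  S_f(t) = ω S_f(t−1) + √(1−ω²) S_B(t) with innovation
  S_B = (R₁ + iR₂) S_A, R₁, R₂ ~ N(0,1), and persistence
  ω(u,v) = exp(−α S_A(u,v)), α = 0.1 by default. As written this makes the
  lowest spatial frequencies decorrelate fastest; because the intended
  direction is a genuine modeling choice, `make_decay(..., inverse=True)`
  selects exp(−α/S_A) instead. The t = 0 state is a pure innovation, which
  is already the stationary distribution.
* Hermitian symmetry. Rather than averaging conjugate pairs after each
  update — which halves the stationary variance of every coefficient and
  breaks the AR(1) law — the field keeps a master half-plane of
  independently evolving coefficients and mirrors their conjugates each
  step. Self-conjugate frequencies (DC and the Nyquist combinations)
  receive real innovations of matching variance. Each coefficient's real
  part is then an exact AR(1) process with stationary variance S_A² and
  lag-k autocorrelation ω^k, which the tests verify directly, and the
  inverse FFT is real to machine precision.
* Cue injection: C = IFFT[S_f + κ e^{iθ} δ_DC]. The cue term is added at
  the DC coefficient only, because the cue is carried by the spatial mean
  color; adding it to all coefficients would instead place an impulse at a
  single pixel. The phase encoding is affine, θ = θ_min + (θ_max − θ_min)X,
  with defaults θ_min = −2π/3, θ_max = +2π/3 — a range that traverses
  blue → red along the CIE Luv hue circle while leaving a gap so that X = 0
  and X = 1 remain visually distinct.
* Color mapping: 256 equally spaced half-open phase bins over [−π, π), each
  mapped to CIE Luv at fixed lightness L = 70 and chroma 60 (hue = bin low
  edge) and converted to sRGB via scikit-image. A phase exactly on a bin
  edge belongs to the bin it opens. The LUT serializes to CSV
  (`phase_bin_low,R,G,B`).
* Decoding: the circular mean of per-pixel phases estimates θ, and the
  mean resultant length R ∈ [0,1] measures coherence. Because κ and the
  texture envelope live on the same spectral scale (√ΣS_A² ≈ 5.5 at
  N = 128), κ values of order 0.5–8 sweep the decoder from near-chance to
  near-exact, which is how κ operationalizes cue reliability.

The radially averaged log-log amplitude slope of texture-only frames is
−1.0, and is invariant to grid size, confirming scale invariance; white
noise gives slope 0.

## Synthetic agents

Agents observe only what a subject could: noisy cue values and binary
reward outcomes — never λᵢ or the availability state.

* `random`: Poisson pressing at `base_push_rate` (default 0.5 s⁻¹; the
  null-calibration sessions use 0.2 s⁻¹ ≈ 180 presses per 15-minute block,
  a realistic overall tempo), uniform patch choice. By construction it
  matches the rate-matched null model and calibrates the normalized
  stay/return metrics at 1.
* `cue_threshold`: every `tick` (0.25 s) the agent reads each patch's cue
  with additive Gaussian noise of sd `cue_noise_sd`/√κ and forms the belief
  that a press would be rewarded. The belief respects the variant's cue
  semantics: under the exponential schedule the cue *is* the reward
  probability, so the belief is the clipped observation; under the gamma
  schedule reward requires progression ≥ 1, so the belief is
  Φ((Â − 1)/σ) — a step at 1 when σ → 0. The agent presses when the
  maximum belief exceeds `cue_threshold` (default 0.5), discounting
  non-current patches by `switch_cost` (default 0.3) and paying
  `travel_time` (default 3 s) to switch. A raw threshold on the cue value
  itself cannot reproduce the observed variant contrast: the exponential
  first-crossing time is −ln(1−c)/μ while the gamma crossing is ≈ cλ, and
  −ln(1−c) > c for every c, so exponential IPIs would always be the longer
  ones. Thresholding the reward-probability belief reverses this for
  c < 1 − 1/e and makes the gamma agent wait out the full interval, which
  is what produces longer gamma IPIs, collapsed self-transitions, and
  fast-directed switching. The switch cost is what produces bursty
  same-patch pressing under the exponential schedule; without it the agent
  round-robins among whichever patches have ripened.
* `rate_matching`: exponentially weighted per-patch reward estimates
  (learning rate 0.1), softmax patch choice (temperature 0.2), Poisson
  timing. It reproduces quality-ordered allocation from reward feedback
  alone but, because its press timing is Poisson, its IPI distributions are
  exponential rather than bimodal; bimodal IPIs are a property of the
  threshold agent's wait/harvest cycle.

Reliability conditions. The cue-noise mapping sd = `cue_noise_sd`/√κ
(default scale 0.4) with condition levels κ = 0.1 (low reliability,
sd ≈ 1.26 — a heavily masked cue, pushing allocation toward chance) and
κ = 4.0 (high reliability, sd = 0.2 — sharp, near-deterministic
allocation) spans the range of behavior from near-chance to tightly
quality-ordered. These levels, and the noise scale, were fixed once when
the generator was designed; sessions default to 900 s.

What the generator does *not* emulate: within-session learning (agents are
stationary, so time-resolved correlations do not rise over a session the
way they do for subjects who must discover patch qualities); internal
interval timing independent of the cue (so a heavily masked cue removes the
gamma variant's switching structure, whereas animals retain it — the
variant contrasts are therefore assessed under high reliability);
individual variability, lapses, and spatial trajectories. Passing tests
show that the analysis pipeline detects the designed structure, not that
the agents are models of any particular subject.

## Analysis pipeline

* Push fractions: per-patch counts over total; quality ranks slow = 1,
  med = 2, fast = 3. The pooled Spearman correlation uses all block×patch
  observations (n = 3 × blocks) with a two-sided asymptotic p. Note the tie
  ceiling: because ranks repeat across blocks, perfectly ordered fractions
  give ρ ≈ 0.943, not 1. Per-block correlations use only 3 observations,
  where asymptotic p-values are invalid; the package reports the exact
  permutation p over the 6 orderings (smallest attainable value 1/3), so
  per-block "significance" in the conventional sense is unattainable and
  per-block ρ values should be aggregated rather than thresholded.
* IPIs: per-patch IPIs are successive differences between presses at the
  same patch, regardless of intervening presses elsewhere (a global-IPI
  option exists). Bimodality is scored by a 2-component Gaussian-mixture
  separation on log intervals.
* Transitions: consecutive press pairs; rows of the 3×3 matrix are
  normalized where the row count is positive. The conditional switch-to-
  fast probability is transitions (M or S)→F over all transitions out of
  M and S.
* Visits: maximal same-patch runs, including the first and last runs.
  Stay time = t_last − t_first within a visit; single-push visits
  contribute stay 0 and are retained (the formula assigns them a value).
  Return time = gap between leaving a patch and the first press upon
  return.
* Null model: surrogates keep the real event count, draw inter-push
  intervals from an exponential law at the empirical mean push rate
  (n−1)/(t_n − t_1), and assign uniformly random patch labels; stay/return
  are computed identically to real data (default 1000 repetitions;
  surrogate duration is implied by the sampled intervals, not clamped).
  Normalized metric = real/null, undefined (flagged nan) where the null
  mean is zero. Ratios are invariant to rescaling all timestamps.
  Condition-level normalization pools visits across blocks (visit-weighted
  on both sides), which is much less noisy than averaging per-block ratios.
* Continuous push rate: r = 1/Δt held piecewise-constant on each
  inter-press interval (the interval is the consecutive difference
  t(i+1) − t(i)), rescaled by the session's time-averaged rate
  ((n−1)/span, the time-weighted mean of the series), then smoothed with a
  centered 60-s moving average on a 1-s grid. Duplicate timestamps are
  clipped to the smallest positive spacing with a warning.
* Time courses: sliding windows of 60 s at 10-s steps on session-relative
  time; windowed fractions are masked where a window contains no presses,
  and masked values propagate. The time-resolved Spearman correlation is
  computed per block from the three patch observations (values in
  {−1, −0.5, 0, 0.5, 1} when untied) and averaged across blocks with SEM.

Determinism: every stochastic component takes an explicit
`numpy.random.Generator` or integer seed; identical inputs and seeds give
identical outputs, and the experiment runner derives per-block seeds from
one master seed via `SeedSequence`.

## Problem sizes

The test battery uses 100,000 draws for moment-recovery and MLE checks,
50,000 draws per arm for the memorylessness KS test, 100 random-agent
blocks × 1000 null repetitions for calibration, 120 seeds per κ level for
the decoder reliability curve, 12,000 steps on a 16×16 grid for the AR(1)
checks, and 50 blocks per condition for the variant contrasts; the full
suite runs in well under a minute on one CPU, so these sizes leave wide
Monte-Carlo margins.

## Known limitations

* Agents are heuristics for generating structured data, not fitted models;
  no normative (MVT/POMDP) solver is included.
* No psychophysical model of color perception and no monitor calibration;
  the Luv LUT asserts perceptual uniformity of spacing only.
* The stimulus decoder is an engineering readout for quantifying effective
  reliability, not a model of the observer.
* Auditory feedback and spatial kinematics are out of scope; the rewarded
  flag is the only feedback represented.
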