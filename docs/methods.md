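# Methods

## Scope and data model

The pipeline analyses multichannel LFP sessions recorded (or simulated)
at 1 kHz from a rectangular electrode grid over a 4 × 4 mm cortical
patch.  The canonical array is 10 × 10 with the four corner sites
offline, leaving 96 active sites ordered row-major (offline sites
skipped); that ordering fixes every downstream feature index.  A session
presents five pure tones (8, 10, 13, 16, 32 kHz by default), each 29 s
long and repeated seven times in a seeded pseudorandom order, interleaved
with 29-s silent gaps (tone, gap, tone, gap, …, trailing gap).

## Synthetic session generator

Each active site s is synthesized as

x_s(t) = Σ_b a_b · g_b(s, tone(t)) · cos(φ_b(t) + ε_{b,s}(t)) + pink_s(t) + burst(t)

- **Latent band phase** φ_b: the integral of an instantaneous frequency
  that wanders slowly (AR(1), correlation 200 ms, SD 5% of the band
  centre) around the band centre (theta 6, alpha 11, beta 22, low-gamma
  35, high-gamma 70 Hz).
- **Phase coupling** ε_{b,s}: a smooth wrapped-normal jitter per site
  (AR(1) field, correlation 150 ms) whose SD is mapped from the coupling
  parameter κ ∈ [0, 1] by σ = √(−2 ln κ), i.e. the circular resultant of
  the jitter equals κ, and κ = 1 means zero jitter and PLV 1.  The
  jitter is deliberately *slow*: broadband (sample-wise independent)
  phase jitter would be removed by the narrowband filter and leave PLV
  pinned at 1 regardless of κ.  Feature-level tests still use von-Mises
  draws directly, where the filter is not involved.
- **Tonotopic gain** g_b(s, tone) = max(0.05, 1 + c_b (B(s, tone) − mean B)):
  B is an activation map in [0, 1] built from Gaussian foci — two foci
  (posterior-dorsal + anterior-ventral) for the low frequencies (8,
  10 kHz), a single central focus for 13 kHz, and a single
  anterior-medial focus for 16 and 32 kHz, mirroring classical tonotopy
  of sustained activity.  The per-band contrast c_b ≥ 0 is the *only*
  route by which tone identity enters the signal, so decodable
  information is controlled by one knob per band; c_b = 0 removes all
  tone information from band b.  The map is mean-centred so average
  power is tone-independent and the decoder must use the spatial
  pattern.
- **Pink noise**: per-site independent 1/f-shaped Gaussian noise
  (flat below 0.5 Hz, no DC), scaled to 15 µV RMS.
- **Bursts**: global events with Poisson onsets (default 2/min) and a
  10× background-SD amplitude, shared by all sites up to a ±5% per-site
  scale; each event is an enveloped 3-Hz transient plus a broadband
  component (so every 100-ms window inside an event is high-SD, not just
  those away from carrier zero crossings).  Events are planted on the
  100-ms lattice on which burst screening is defined (onsets and
  durations are multiples of 100 ms; durations uniform over the lattice
  values inside the configured 150–500 ms range, minimum 200 ms so the
  150-ms persistence rule can always fire).  The generator logs the
  exact intervals as ground truth.

Default amplitudes (theta 10, alpha 8, beta 7, low-gamma 6,
high-gamma 4 µV; peak, at unit gain) put non-burst band RMS at order
10 µV over the 15 µV noise floor — total background SD ≈ 19 µV.  Default
contrasts (theta 0.35, alpha 0.3, beta 0.3, low-gamma 0.4, high-gamma
0.8) and couplings (0.7/0.6/0.5/0.5/0.8) were chosen once so that
five-choice decoding from high-gamma features sits in the 50–65% range
and theta-power decoding in the 40–50% range at desk scale — i.e. the
mid-range regime in which the recordings this emulates are reported to
sit, where perturbation-induced deltas are observable in both
directions.  The high-gamma amplitude is deliberately the smallest: PLV
carries tone information only through the per-site signal-to-noise
ratio, and at in-band SNR ≫ 1 the measured phase saturates at the latent
phase and the tone dependence vanishes.

**Cohorts.**  An animal is a lognormal (~±10% SD) multiplicative jitter
of the base amplitudes and contrasts; its pre-session uses those
parameters and its post-session the same parameters after a
ground-truth "VNS effect" (multiplicative changes to per-band contrast
and coupling, coupling clipped back to [0, 1] with a warning).  All
per-animal randomness derives from the master seed by seed-sequence
spawning, so cohorts are bitwise reproducible and adding animals never
shifts existing streams.

**What the generator does *not* emulate**: biophysics (no compartments,
no spikes), the stimulation pulse train itself, 1/f non-stationarities,
inter-band coupling, movement or line-noise artifacts, and any real
tonotopic map geometry beyond the qualitative two-foci/one-focus layout.
Tests passing on this generator therefore establish that the *pipeline*
recovers planted structure under realistic amplitude/noise/burst
conditions — not that real cortex behaves like the model.

## Burst screening

Per-site SD is computed over consecutive non-overlapping 100-ms windows
(population SD, partial trailing window discarded).  A window is
supra-threshold when strictly more than `site_count_threshold` sites
exceed their per-site threshold; contiguous supra-threshold runs
spanning ≥ 150 ms (two windows on the 100-ms lattice) are emitted as
burst intervals.  Two knobs are not dictated by the analysis tradition
and are documented package choices:

- the SD threshold value: per-site, 3 × the median of that site's
  window SDs over the whole session (a median so the bursts themselves
  cannot inflate it); configurable;
- "more than 24 sites" is read strictly (≥ 25 trigger) and scaled as
  round(0.25 · n_active) when the array is not the canonical 96-site
  one.

Analysis windows tile each tone from onset + 1 s in non-overlapping
1,000-ms steps; candidates overlapping any burst interval are dropped;
exactly `n_per_label` windows per frequency are retained by a
deterministic even-stride thinning of the survivors in acquisition
order (the selection rule is not dictated by the tradition either; the
stride keeps trials balanced and is reproducible).  A shortfall raises
an error naming the label and counts — never silent padding.

## Features

Filtering is a 4th-order Butterworth applied forward–backward (zero
phase, effective 8th order).  Band-pass bands above 30 Hz wider than one
octave are rejected unless explicitly overridden, because instantaneous
phase is only meaningful for narrowband signals.  The filter runs over
the whole recording once and, for PLV, the analytic signal (FFT Hilbert
method) is also taken over the full filtered trace before windows are
cropped — every window therefore has hundreds of ms of real context on
each side and no transform edge artifacts (this supersedes per-window
padding; the two coincide away from session edges).  Degenerate all-zero
windows have no defined phase: they get NaN angles, are excluded from
feature tables, and `plv_matrix` refuses NaN input outright.

Band power is the RMS over the 1,000-ms window, in µV.  PLV is computed
for all unordered site pairs via the Gram matrix of unit phasors
(|Z Z*|/T), numerically clipped to [0, 1], in lexicographic pair order
m < n so feature columns are comparable across sessions and animals; a
naive double-loop implementation is kept as a test oracle.

## Decoder

Multinomial logistic regression with automatic relevance determination:
per-feature precisions α_f on zero-mean Gaussian priors over that
feature's class weights.  The fit alternates (1) L-BFGS minimization of
the penalized negative log-likelihood at fixed α (features standardized
on the training fold only; the transform is stored for test data), (2)
the evidence update α_f ← γ_f / ‖w_f‖², with γ_f = Σ_c h/(h + α_f) the
effective number of well-determined dimensions from the diagonal Laplace
posterior variance, and (3) pruning of features with α > 10⁸, whose
weights are exactly zero thereafter.  The γ factor matters: the naive
update α = 1/w² over-prunes and drives weakly distributed but genuinely
predictive PLV patterns to chance (verified against the L1 route on
identical tables).  Defaults: at most 200 outer iterations, stop when
the active set is stable and the max weight change is < 1e-4 (the
alternating scheme approaches its fixed point sublinearly; tighter
tolerances change accuracies by nothing measurable and are never reached
in 200 iterations).  Non-convergence is recorded on the model and
logged, never silently accepted.  Ties at the argmax go to the
lowest-frequency class, so prediction is deterministic.  An
L1-regularized model (scikit-learn, saga) sits behind the same interface
as an independent cross-check, not as the primary method.

Cross-validation: *periodic* — per label, row j in acquisition order
goes to group j mod k (k = 7), each group held out once, giving
60 training / 10 test rows per label per fold at the full-scale
defaults; *rolling* — expanding chronological windows with block size
b = ⌊n_per_label/(n_folds+1)⌋, training on the first i·b rows per label
and testing on the next b, so no test row ever precedes its training
rows (the block geometry is an interpretation; only the number of runs,
three, is fixed by the tradition).  Two-choice tasks are all C(5,2) = 10
frequency pairs, stratified into difficulty classes by quarter-octave
bins of log₂(f₂/f₁), which yields exactly six classes on the canonical
frequencies.  Reported accuracy is the mean over per-label accuracies
pooled across folds (identical to pooled percent correct at the balanced
defaults).

## Pre/post comparison

Per (layer × band × kind × task) cell, per animal: Δ = post% − pre%.
The two-sided Wilcoxon signed-rank test against zero uses the exact
distribution of the statistic for n ≤ 25: zeros dropped (Wilcoxon's
original treatment), midranks for tied |Δ|, null distribution over all
2ⁿ sign assignments computed by dynamic-programming convolution on the
doubled-rank integer lattice (identical to full enumeration; verified
against brute force).  Cells with fewer than five animals report deltas
without a p-value.  No multiple-comparison correction is applied by
default — each cell reports its own p — with Benjamini–Hochberg
available behind a flag.

## Problem sizes

Full-scale defaults (96 sites, 29-s tones × 7 repetitions, 70 windows
per label) describe the real recording design.  The package's
single-CPU profile for simulation studies (`PipelineConfig.desk_scale`)
uses a 5 × 5 grid (21 active sites, 210 PLV pairs, site-count threshold
round(0.25·21) = 5), 11-s tones × 3 repetitions (30 candidate windows
per label), 21 windows per label, and decoder max_iter = 50; chance
calibration, burst recovery, contrast monotonicity and directional
perturbation recovery were all verified insensitive to these sizes.

## Known limitations

- The exact signed-rank DP is O(n · Σranks); for n > 25 a tie-corrected
  normal approximation is used instead.
- The generator's PLV is controlled jointly by κ and by in-band SNR;
  κ is not the measured PLV itself (the mapping is monotone, which is
  what the recovery tests rely on).
- EDF export is not provided; the session container is HDF5 plus
  plain-text exports (BED-like burst intervals, TSV manifests and
  feature tables, JSON results).
- ARD hyperparameter trajectories are sensitive to near-duplicate
  features (PLV columns are strongly correlated); accuracy is stable
  but the identity of surviving features can differ between nearby
  configurations.
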