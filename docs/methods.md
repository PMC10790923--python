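# Methods

This note records the models, parameter choices and numerical decisions
behind `nirspain`, and what the synthetic-data tests do and do not establish
about real recordings.

## Montage geometry

Optode positions are stored in mm (MNI); separations are their Euclidean
distance / 10, reported in cm with half-even rounding to 2 decimals. The
packaged montage table also stores the separations as printed in the source
table; `load_montage` cross-checks stored against recomputed values with a
0.025 cm tolerance, because one stored value (Channel 2, 3.02 cm) differs
from the coordinate-derived 3.00 cm by more than print rounding. The strict
0.005 cm invariant applies to the recomputed `separation` field itself.

## Modified Beer–Lambert inversion

Per channel, ΔOD at the two wavelengths is modelled as
`ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · DPF` with d the separation
in cm and DPF = 6.0 (configurable; a conventional adult-head value — the
recording description specifies none). Extinction coefficients at 761 and
847 nm are pinned in `preprocess.EXTINCTION_UM_CM`, interpolated from a
standard compiled haemoglobin absorption spectrum; their absolute accuracy
is immaterial to the tests because the simulator uses the same table in the
forward direction, making inversion exact up to float error. The 2×2 system
is solved per sample; a singular extinction matrix is rejected.

## Pipeline order

Stages are mBLL → motion correction → band-pass → CBSI, enforced through
provenance flags (CBSI before filtering, or motion correction after
filtering, raises `StageOrderError`). Motion correction deliberately
precedes the band-pass: a 0.5–2-s step artifact pushed through a
0.01–0.09 Hz filter becomes an oscillatory transient on the order of the
longest pass-band period (~100 s), which no local reconstruction can remove
afterwards. We measured this directly on simulated sessions — correcting
after filtering left the in-band artifact residual essentially unchanged
(0.887 vs 0.894 µM), while correcting before filtering reduced it to
~0.25 µM.

## Motion-artifact detection and reconstruction

The accelerometer magnitude (gravity removed by median subtraction) is
resampled to the fNIRS time base by windowed RMS. Both streams are reduced
to moving standard deviations (MSD): 1 s for the accelerometer, 2 s for
fNIRS — the longer fNIRS window keeps the MSD elevated across the interior
of a step rather than only at its edges. A sample is flagged per channel
only when *both* MSDs exceed their thresholds (defaults: session
mean + 2 sd of each MSD trace; exactly quiescent streams flag nothing);
runs closer than 1 s are merged. Flagged segments are replaced by a straight
line between 2-s pre- and post-segment baseline means, using the available
side alone at the series edges. On simulated cohorts this detector reaches
~95% sample recall on true artifact intervals.

## CBSI

`hbo′ = (hbo − α·hbr)/2`, `hbr′ = −hbo′/α`, with α = sd(hbo)/sd(hbr) per
channel — the minimal construction that renders the chromophores exactly
anti-correlated. Zero-variance channels are rejected by name. Only HbO′
feeds the feature stage.

## Band-pass filter

Chebyshev type-I, order 6, 0.5 dB ripple, edges 0.01/0.09 Hz, realised as
second-order sections and applied forward–backward (`sosfiltfilt`), so the
effective magnitude response is squared: DC and 1 Hz are attenuated by far
more than 40 dB, and pass-band gain stays within [0.9, 1.0] at 0.05 Hz.
Filter tests measure the driven-frequency Fourier coefficient over the
settled middle third of a long record, because raw `max(|y|)` of a finite
record is dominated by edge transients of the zero-phase filter.

## Heart rate from ECG

QRS emphasis by 5–15 Hz Butterworth band-pass; peaks above 40% of the 99th
absolute percentile with a 0.3-s refractory distance; RR intervals outside
0.3–2.0 s discarded; 60/RR linearly interpolated to a uniform 10 Hz series.
This is deliberately generic plumbing: any validated R-peak detector can be
substituted, and simulated sessions can bypass ECG entirely by carrying a
heart-rate series directly.

## Windowing and features

Consecutive non-overlapping 8-s windows; a trailing partial window is kept
when ≥ 4 s, which is exactly the policy that makes a 180-s game yield
23 epochs (22 × 8 s + 4 s). Per window and channel: mean, peak (maximum),
adjusted Fisher–Pearson sample skewness (defined as 0 for zero-variance
windows), unbiased variance, and signed trapezoidal AUC in µM·s. Heart-rate
windows contribute average, median, maximum, minimum, range and sample sd.

Connectivity is computed for all 28 unordered channel pairs. Pearson
correlation uses the window samples directly. Wavelet coherence uses an
analytic Morlet (ω₀ = 6) CWT implemented by FFT (Torrence–Compo
normalisation), 12 voices per octave over 0.04–0.5 Hz. The smoothing
operator is a boxcar spanning three scale lengths in time and 0.6 octave
across scales; without smoothing coherence is identically 1, and the 3×
width was chosen so that independent white-noise pairs average ≈ 0.4
coherence while self-coherence stays at 1 and a one-sample delay loses
< 0.1%. Coherence is computed on the full game-length series — an isolated
8-s window cannot resolve 0.08 Hz — and the map is then averaged inside each
window over 0.08–0.3125 Hz, excluding the cone of influence (e-folding time
√2·scale from either edge); windows whose band cells are entirely inside the
cone fall back to the unmasked average.

## Dataset construction

The demand task pools all game windows of the four game conditions,
labelled Easy vs Hard. The pain tasks compare game+pain vs game-only within
one demand level, duration-matched per participant: immersion starts with
the game, so both sessions contribute the first T seconds of their game,
T = that participant's immersion duration (clipped, with a warning, to the
no-pain game length). Matching re-windows the truncated segment, so the
partial-window policy applies to T, not to the full game. Matched classes
span equal wall-clock time by construction; SMOTE (synthetic points uniform
on segments between a minority sample and one of its k = 5 nearest minority
neighbours) equalises any residual imbalance beyond a 1.1 ratio, and is
applied only to training partitions after the outer split — balancing before
the split would leak synthetic neighbours of test samples into training.

## ReliefF, k-rule, elbow

ReliefF is the deterministic full-pass variant (every sample a reference;
no sampling seed), with Manhattan distances on min–max-normalised features
and k nearest hits/misses; for binary labels the class-prior miss weight is
identically 1. k defaults to round-half-even(√p), bumped to odd — 3 for the
6 heart-rate features — with an explicit override (the fNIRS analyses use
k = 15, which the rule cannot produce from 96 features). The cut-off is the
elbow of the sorted weight curve: the point of maximum perpendicular
distance from the chord between first and last weight; when that point lies
below the chord (the first weight of the flat tail) the cut is placed just
before it, which matches the intended "keep the cliff, drop the tail"
reading. Near-collinear curves keep all positive-weight features.

## Cross-validation and chance correction

The outer loop is a repeated (10×) participant-level 60/40 holdout — all
windows of a participant fall on one side, so evaluation is
subject-independent. Within each repeat: z-scoring, SMOTE and ReliefF are
fit on the training partition only (a SHA-256 hash of the test rows is
verified untouched); hyperparameters come from an inner 10-fold grid search
maximising accuracy, grids ordered simple-to-complex so ties resolve toward
the simpler model (SVM RBF with C ∈ {0.1, 1, 10, 100},
γ ∈ {0.001, 0.01, 0.1, 1}; kNN neighbours 3–15; RF fixed at 500 trees with
max-features ∈ {√p, p/3, p/2}; NB untuned). Metrics: accuracy, F1, TPR,
TNR, trapezoidal ROC AUC, with positive class = {Hard, pain}; aggregates are
mean (sd) over repeats. Degenerate single-class partitions are resampled
with a logged seed change.

Observed accuracies are compared to the corrected chance level — the
smallest k/n with binomial CDF(k; n, ½) ≥ 0.95 — computed both for the
realised test sizes of each run and for the reference sample sizes n = 400
(demand) and n = 160 (pain), which give 0.54 and 0.5625. The source
analyses' ANOVA across folds is intentionally replaced by this direct
threshold comparison.

## Synthetic cohort: what it emulates, and what it does not

Each participant carries a log-normal amplitude gain (sd 0.2) and a
baseline heart rate ~N(70, 5). A game session is 90 s baseline + 180 s game
+ 15 s post. Activation per channel is a sustained boxcar (half amplitude)
plus Poisson game events (4/min) convolved with a double-gamma HRF (peak
7 s, undershoot ratio 1:6, 30-s support, unit peak); Easy amplitude 0.5 µM,
Hard adds `demand_effect` (default 0.3 µM); frontal channels respond more
strongly than central-parietal ones. Noise: cardiac 1.1 Hz (0.08 µM),
respiratory 0.25 Hz (0.15 µM), Mayer 0.1 Hz (0.3 µM), white (0.3 µM),
random linear drift (0.1 µM/min sd). HbR = −HbO/3 + independent noise.
These amplitudes put the in-band (0.01–0.09 Hz) effect-to-noise ratio near
1 at the default demand effect, so default cohorts land in the
"barely-classifiable" regime rather than at ceiling. OD is built by the
forward mBLL; motion steps (8 µM HbO-equivalent, 0.5–2 s, random sign,
2/min) are injected into OD only inside matching 5-Hz accelerometer bursts.
Heart rate adds a smooth game elevation (+3 bpm, +`demand_effect_hr` when
Hard), a smooth immersion elevation (`pain_effect_hr`, default 5 bpm), and
filtered variability. Immersion durations come from the calibrated censored
log-normal; a no-game cold-pressor session and a resting baseline complete
each participant. One RNG stream per (participant, condition) —
`SeedSequence(seed, spawn_key)` — makes any single session reproducible
independent of cohort size; participant-stable quantities use a dedicated
stream.

The tolerance model fixes σ² = ln(1 + (sd/mean)²) from the target
coefficient of variation and solves µ by Brent's method so the *censored*
mean (closed form under right-censoring at 180 s) equals the behavioural
target; the censored sd is then somewhat below the target sd — only the
mean is calibrated.

What passing tests show: the pipeline inverts its forward model, removes
the artifacts it defines, recovers in-band activation (mean correlation
≈ 0.85 against the filtered ground truth at default SNR), stays at chance
on null cohorts and detects a 3×-noise demand effect above corrected
chance. What they do not show: performance under real optode-coupling
drift, systemic physiology correlated with task, non-step artifact shapes,
or real inter-individual variability in HRF shape — the generator's
participant heterogeneity is a single amplitude gain.

## Problem sizes

Cohort-level tests run 8–12 participants with the Easy/Hard game pair, 5
outer repeats, 5 inner folds and compact grids; the analysis drivers default
to the full 20-participant design and full grids, with `--quick` mirroring
the test-scale settings. The acceptance script's tolerance means use 10⁵
draws.

## Known limitations

* The SNIRF writer/reader covers the subset of the format this package
  produces (time series, measurement lists, probe wavelengths), not
  arbitrary third-party SNIRF files.
* Motion reconstruction is linear baseline interpolation; spline or
  wavelet-based reconstruction is out of scope.
* The ReliefF implementation is binary-class only, matching the tasks.
* `hr_from_ecg` is a generic detector, not a validated clinical algorithm.
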