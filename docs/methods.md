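# Methods

This note records the models, conventions, parameter choices and known
limitations of the gait-emotion pipeline, in the order the data flow
through it.

## Data model and file format

A recording is one subject walking for one minute under one emotion
condition (neutral, happy, angry) with the accelerometer at one wear
site (wrist, ankle), sampled at 5 samples/s: 300 (x, y, z) triples in
m/s². Recordings are stored long-form (one row per sample, header
`subject_id,site,emotion,sample_index,x,y,z`, optional
`# sampling_rate=5` comment line). Floats are written with shortest
round-trip precision and read back with a round-trip parser, so
write∘read is exact identity — the suite asserts byte-identical
re-serialisation. Emotion and site vocabularies are closed; unknown
tokens are errors, not warnings, because silently corrupted labels would
invalidate every downstream recognition rate. Wrist and ankle series
are modelled as independent recordings and never aligned, since
simultaneous capture at both sites cannot be assumed.

## Preprocessing

**Moving average.** `out[i] = (1/w) Σ_{j=0}^{w-1} in[i+j]` — a forward
window in "valid" mode: no padding, no centering, no edge
extrapolation; the output is shorter by `w − 1`. The benchmarked widths
are w = 3 and w = 5; any `w ≥ 1` is accepted (w = 1 is the identity).
The whole one-minute series is filtered first and segmented second;
filtering per-segment would process the overlapped samples twice.
The implementation is a cumulative-sum rolling mean, pinned in the test
suite to a naive re-summation oracle within 1e-9.

**Segmentation.** Windows of 128 samples stepped by 64 (50% overlap),
offsets 0-based; the trailing remainder (< 128 samples) is discarded,
after filtering. Count law: `floor((L − 128)/64) + 1` for filtered
length L, so a 300-sample minute gives 3 segments at L = 300, 298
(w = 3) and 296 (w = 5) alike. A recording shorter than one window
yields zero segments with a logged warning rather than an error, so
degenerate synthetic inputs flow through.

## Features (38 per axis, 114 per segment)

All moments are population moments (divisor n, no Bessel or bias
correction): skewness `m₃/m₂^{3/2}`, kurtosis `m₄/m₂²` (non-excess —
a Gaussian scores ≈ 3), standard deviation `√m₂`. Correlation is the
population Pearson coefficient; the three pairwise correlations fill the
per-axis slots by the fixed mapping x ← corr(x,y), y ← corr(y,z),
z ← corr(x,z).

Zero-variance channels make skewness, kurtosis and correlation 0/0; the
kernels raise a degenerate-feature signal which the extractor maps to 0
with a logged warning, so constant-axis edge cases don't abort a cohort
run.

The spectral features use the unnormalised DFT
`X_k = Σ_j x_j e^{−i2πkj/n}`: the temporal-frequency block keeps the
first 32 amplitude moduli |X_k| (k = 0…31, DC included, phase
discarded); the frequency block summarises the raw one-sided
periodogram `P[k] = |X_k|²/(n·f_s)`, k = 0…n/2 (65 bins at n = 128),
by its mean and population standard deviation. The periodogram is
computed directly from this definition — deliberately *not* via a
library periodogram, which doubles interior bins for one-sided
normalisation — with no Welch averaging, detrending or tapering: the
minimal estimator consistent with a 128-sample window, and the
estimator sits behind a single function seam (`psd_summary`) if a
different one is ever wanted. Both spectral kernels are pinned to an
O(n²) direct-summation DFT oracle, with a Parseval identity check on
the full transform.

Feature order is part of the contract: axes x, y, z; within an axis
skewness, kurtosis, std, correlation, psd_mean, psd_std,
fft_00…fft_31.

## PCA selection

Features are z-scored with population σ before PCA. The features mix
unitless shape statistics with m/s² amplitudes and (m/s²)²/Hz power
densities, so covariance-matrix PCA would be dominated by the
large-scale features; correlation-matrix PCA (z-scoring) treats them
symmetrically and makes "factor loading" well defined as the
correlation between an original feature and a component score, bounded
by 1. Constant columns are mapped to 0 after centering (they carry no
information) rather than erroring, except when *all* columns are
constant.

The retained prefix is the smallest m whose cumulative
explained-variance share reaches the threshold (default 0.95; the
suite asserts minimality on both sides). Component signs are fixed so
each component's largest-|loading| entry is positive — PCA signs are
otherwise arbitrary and determinism requires a rule. The loading
report lists features with |loading| ≥ 0.71 per retained component
(≥ ~50% of the feature's variance captured), sorted by |loading|, each
tagged with its family so the dominant feature kinds per component can
be read off.

**Leakage control.** Two selection modes are first-class: the default
fits PCA inside each cross-validation training fold and applies it to
the test fold (no information from test rows reaches the fit);
`paper_mode` fits once on the full dataset, which is how a single fixed
per-dataset feature count is most plausibly obtained and is the mode to
use when comparing retention counts across datasets.

## Classification

Four frozen configurations, realised as scikit-learn estimators:
SVM with RBF kernel (C-SVC, C = 1, γ = 1/n_features — the LibSVM
defaults), with fold-internal standardisation of the PCA scores since
the RBF kernel is scale-sensitive; a pruned decision tree
(min 2 samples per leaf, cost-complexity pruning α = 0.01 as the
pruning-strength analogue of confidence-threshold 0.25 pruning); a
10-tree random forest; and an unpruned randomised tree (min 1 sample
per leaf, √d features per split). The tree surrogates approximate the
WEKA J48/RandomTree behaviours in spirit, not in mechanism —
equivalence with WEKA outputs is expressly not claimed or asserted.

Cross-validation is stratified k-fold (default 10) with seeded
shuffling; if the smallest class has fewer members than k, the fold
count is reduced with a warning. `Q = Σ n_correct / Σ n_total` is
computed exactly from the pooled per-fold counts, and the per-fold
counts and summed confusion matrix are retained in every result. Ties
in prediction resolve toward the lexicographically first class label
(scikit-learn's argmax over sorted class labels), which keeps reruns
identical. Segments are pooled across subjects, so two segments of one
recording can land in train and test — see Limitations.

The experiment grid is 4 tasks (three pairwise contrasts + three-way)
× w ∈ {3, 5} × 2 sites × 4 classifiers = 64 cells; a cell whose data
are missing is marked absent and the run continues.

## Synthetic cohort generator

Each axis is a sum of three gait harmonics plus noise:
`a(t) = Σ_{h=1..3} A_h cos(2π h f t + φ_h) (+ 9.81 on z) + ε`,
`ε ~ N(0, noise_sd²)`.

Parameters (defaults; m/s² and Hz):

* Neutral cadence f = 0.7 Hz; harmonic amplitudes per axis
  x (1.2, 0.5, 0.2), y (0.9, 0.35, 0.15), z (1.2, 0.45, 0.2);
  noise_sd 0.35; between-subject multiplicative sd 0.08 (log-normal on
  amplitude and cadence).
* Happy: +10% cadence, +20% amplitude. Angry: +15% cadence, +35%
  amplitude, +50% noise.
* Ankle recordings scale the vertical (z) amplitudes by 1.5, making the
  site dimension of the grid non-trivial.
* Cross-axis coupling: y and z lag x by arccos(ρ) per harmonic
  (ρ_xy = 0.5, ρ_xz = 0.3), using corr(cos θ, cos(θ+δ)) = cos δ; the
  y–z correlation is implied, not separately controlled.
* `effect_scale` interpolates every profile parameter linearly toward
  the neutral profile; at 0 the three conditions are statistically
  identical.

A 5 Hz bracelet undersamples real gait (step rates ~2 Hz with strong
harmonics), so the generator places the fundamental and all harmonics
below the 2.5 Hz Nyquist limit instead of simulating fast gait and
decimating; the 0.7 Hz neutral cadence keeps even the angry profile's
third harmonic (3 × 0.805 = 2.415 Hz) unaliased. This is sufficient to
exercise every pipeline formula, which is the generator's purpose. A
configured fundamental at or above Nyquist is an error; harmonics that
would cross Nyquist under extreme custom configs are dropped. Default
amplitudes are sized so the deterministic gait envelope stays below
6 m/s² on every axis even for the largest (angry, ankle) profile — the
plausible dynamic range of ordinary walking — while the vertical axis
carries the full +9.81 m/s² gravity offset, as a real accelerometer
does; features other than the DC spectral bins are unaffected by the
offset.

**Trait/state split.** Amplitude and cadence multipliers *and* the
harmonic/cross-axis phase structure are drawn once per subject (a gait
signature, stable across sites and conditions); each recording adds
only a random gait-cycle origin — a global time shift, to which
amplitude-spectrum features are essentially invariant — and a fresh
noise realisation. This matters for calibration: if phases were drawn
per recording, each recording would carry a label-free fingerprint
shared by its segments, and under segment-pooled cross-validation a
classifier could match a test segment to its training-set siblings and
read off their label, lifting the `effect_scale = 0` null visibly above
chance. With the trait/state split the null sits inside the 99%
binomial band around chance (measured medians ≈ 0.54 two-class,
≈ 0.36 three-class over 10 seeds).

Seeding uses spawn-keyed seed sequences per (subject, site, emotion),
so cohorts are byte-reproducible and any sub-cohort is stable under
changes elsewhere.

**What the generator does not emulate:** biomechanical realism (double
support, ground reaction, asymmetry), autoregressive or non-stationary
noise, sensor drift and quantisation, and — deliberately — any claim
about the real effect sizes of emotion on gait, which are unknown.
Passing recovery tests on this cohort shows the pipeline can detect the
structure it is pointed at and is honest under the null; it says
nothing about how separable real emotional gait is.

## Problem sizes and determinism

The statistical checks use wrist cohorts of 40 subjects (120
recordings, 360 segments, 240 rows for a pairwise task), medians over
10 seeds, with w = 3 and 10-fold cross-validation; the analysis scripts
run the same cohort size over both sites. These sizes give stable
medians (observed seed-to-seed ranges of a few points) while keeping a
full suite run in well under a minute per check. End-to-end pipeline
runs with a fixed config and seed produce byte-identical output files;
the suite asserts this at the pipeline level.

## Known limitations

* **Segment pooling.** Overlapping segments of one recording share 64
  samples, and segments of one subject appear in both training and test
  folds. This segment-pooled design inflates
  absolute recognition rates relative to a subject-held-out protocol;
  the residual ~2–4-point elevation of the null above exact chance has
  the same cause. Grouped folding is the stricter alternative and can
  be layered on by splitting at the subject level before assembly.
* **WEKA fidelity.** The tree surrogates and the SVM wrapper differ in
  detail from the WEKA implementations the four configurations name;
  absolute rates are not comparable across toolkits.
* **PSD estimator.** A raw length-128 periodogram is a high-variance
  spectral estimate; its mean/std are used as coarse descriptors, not
  as a calibrated spectrum.
* **Retention counts.** The number of PCA-retained components depends
  on the dataset (and, in default mode, on each training fold);
  cross-dataset comparisons should use `paper_mode`.
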