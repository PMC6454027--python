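# Methods

`wavemeg` re-implements, as a tested pipeline, an analysis that links
multilevel Haar-wavelet descriptors of visual stimuli to time-resolved
MEG decoding: descriptor extraction, per-timepoint pairwise-SVM decoding
RDMs, RSA time-courses, and cluster-corrected permutation/bootstrap
latency statistics. Real recordings are out of scope; every stage is
validated against synthetic data with injected, recoverable ground
truth. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
show.

## Wavelet descriptors

Each grayscale stimulus is decomposed with the separable 2D Haar
transform: per level, low/high-pass filtering along both axes plus
dyadic downsampling yields the approximation band A and the horizontal /
vertical / diagonal detail bands H, V, D; levels recurse on A. The
filter pair is the orthonormal Haar pair (coefficients `1/sqrt(2)`), so
one analysis level conserves energy and inverts exactly on even-sided
inputs — both properties are tested. We deliberately use the orthonormal
filter-bank normalisation rather than an explicit `1/sqrt(MN)`
prefactor: all downstream dissimilarities are Pearson correlations,
which are invariant to global rescaling (a property test certifies
this), and orthonormality buys testable conservation laws.

Odd side lengths use half-sample symmetric padding with output length
`floor((n+1)/2)`; this reproduces the canonical size chain
175 → 88 → 44 → 22 → 11 → 6 for five levels on a 175 × 175 image.

Per level the flattened A, H, V, D grids plus the concatenation
`ALL = [H | V | D]` give five descriptors; five levels give 25
(`W1`…`W25`, level-major, band order A, H, V, D, ALL). "Horizontal
detail" means the band maximal for horizontal *stripes* (the band
computed by high-pass filtering across rows); a `gradient` convention
switch swaps the H/V labels for users who prefer the edge-orientation
reading. Grayscale conversion uses BT.601 luminance weights
(0.299/0.587/0.114). Stimuli are not intensity-normalised before
decomposition; Pearson-based RDMs make per-stimulus affine intensity
changes irrelevant.

The filter bank is executed by PyWavelets (`haar`, symmetric mode),
which matches the conventions above exactly; the test suite verifies
every coefficient against an independent brute-force oracle (direct
inner products with translated 2×2 Haar atoms on the symmetrically
extended image) to 1e−10.

## Synthetic data

The generator defines the study conditions for all recovery tests.

**Stimuli** are sums of oriented sinusoidal gratings — horizontal,
vertical, diagonal stripes — whose contrasts are set by an
`OrientationProfile`, plus low-frequency noise, affinely mapped to
[0, 1]. Horizontal/vertical gratings are drawn at periods of 4–8 px
(well inside the level-1/2 detail pass-band). Diagonal gratings are
drawn near an axis period of 2.0–2.5 px, because the diagonal Haar atom
is a 2×2 checkerboard: a *smooth* 45° sinusoid at 4–8 px puts most of
its detail energy into the H and V bands (measured shares ≈ 0.45/0.45),
whereas near the checkerboard scale the D share is 0.8–1.0. Without
this choice a diagonal-dominant profile cannot dominate the D band.

**Epochs.** Condition-mean sensor patterns realise a target model RDM
through a correlation-geometry embedding: the Gram matrix
`G = ones − s·RDM` (pairwise pattern correlation decreasing affinely in
the target dissimilarity; `s` maps the largest dissimilarity to a 0.5
correlation drop; a ridge `ε·I` restores positive semi-definiteness) is
eigen-factored and rotated into channel space by a seeded random
orthonormal map chosen orthogonal to the constant channel vector. Every
pattern then has zero channel mean and equal norm, so the 1 − Pearson
dissimilarity between patterns equals `(ε + s·RDM)/(1 + ε)` — a
*rank-exact* copy of the target — and squared pairwise distances
`2(ε + s·RDM)` retain a large relative spread, so pairwise decodability
varies across pairs. We evaluated classical MDS of the RDM first; it
reproduces distances but not the 1 − Pearson geometry (pattern norms
vary), recovering the target only to Spearman ≈ 0.65, and was rejected.
An all-equal RDM embeds as a regular simplex (equal distances to
1e−15), which is also tested.

The temporal envelope is a compact-support Gaussian: nominal FWHM
`signal_width_ms`, with the value at `|t − peak| = width` subtracted
and rescaled, zero outside `peak ± width` (effective FWHM ≈ 0.96 ×
nominal). A pure Gaussian leaks ≈ 6% of its peak into the pre-stimulus
interval when `peak = width = 100 ms`; the compact support keeps the
baseline exactly silent whenever `peak ≥ width`, which the baseline and
envelope tests rely on. Sensor noise is i.i.d. Gaussian per
trial/channel/sample.

`generate_multicomponent_epochs` sums several (RDM, peak, width,
amplitude) components with independent channel embeddings, letting one
recording carry several latency-localised geometries;
`random_orthogonal_rdms` supplies mutually rank-uncorrelated targets so
the components' RSA time-courses do not cross-talk. Each subject gets
its own random channel rotation (inter-subject pattern variability)
while sharing the injected geometry.

What the generator does *not* emulate: realistic forward models and
sensor covariance, head movement, 1/f and line noise, autocorrelated
artifacts, trial-count imbalance. Passing recovery tests therefore
demonstrates the *correctness of the analysis chain*, not expected
effect sizes on real recordings. An optional rank-1 frontal-dominant
blink injector exists solely to test the preprocessing projector.

## Preprocessing

Per trial and channel the mean over the full pre-stimulus interval
`[t_start, 0)` is subtracted. Trials whose worst-channel peak-to-peak
range strictly exceeds 6,000 fT are flagged invalid (strict `>`, so a
trial spanning exactly the threshold is kept); flagging uses the raw
range, so it commutes with baseline correction. Smoothing is a 4th-order
Butterworth low-pass at 30 Hz applied forward–backward (zero phase) —
peak latency is a headline quantity, so the filter must not bias it.
Eyeblink handling detects excursions of the mean frontal signal using a
robust z-score (median / 1.4826·MAD; a blink occupying a sizeable
fraction of the epoch inflates a plain SD enough to mask itself, which
we observed as `|z|` saturating near 2.8) and projects the first
principal component of the blink-segment data out of all channels;
blink-free trials pass through bit-identically. Default threshold
`z = 4`.

## Decoding

For each subject, condition pair and timepoint, a linear soft-margin SVM
(C = 1, no feature scaling) is trained on pseudo-trials — averages of
`group_size` randomly partitioned raw trials (defaults K = 4 groups of
10) — with leave-one-pseudo-trial-per-class-out cross-validation over
the K groups. The full permute / average / cross-validate cycle repeats
`n_reps = 100` times with fresh partitions; accuracy is averaged over
all K folds and repetitions (a single-fold-per-repetition variant is a
flag). If a condition has fewer than `K × group_size` valid trials, the
group size shrinks to `floor(n/K)` (minimum 1); below K trials the
condition is excluded and its RDM row/column is NaN.

Every (repetition, fold, timepoint) is an independent 6-sample QP, so
the default engine solves them in batch: an SMO-style pairwise
coordinate-descent solver for the SVM dual, vectorised over problems,
with the bias recovered from free support vectors. It agrees with
`sklearn.svm.SVC(kernel="linear")` (prediction-identical on hundreds of
random problems, decision values to ~1e−3) and is orders of magnitude
faster at these problem sizes; sklearn remains available as
`engine="sklearn"` and serves as the reference in tests. Each
(subject, pair) work unit is seeded as `SeedSequence([seed, subject, i,
j])`, making results bit-identical regardless of execution order or
parallelism.

## RDMs and RSA

Descriptor RDMs are `1 − Pearson r` between descriptor vectors (values
in [0, 2], diagonal NaN; zero-variance vectors yield flagged-missing
cells). RDM comparison is Spearman rank correlation over the vectorised
strict upper triangle (the lower half and diagonal carry no extra
information), average ranks for ties, pairwise exclusion of missing
cells, and a hard error below 3 usable pairs. RSA correlates each model
RDM with each subject's decoding RDM at each timepoint; the grand
average is the plain mean of ρ over subjects (per-subject time-courses
are required by the sign-permutation test; Fisher-z averaging is not
applied, matching the plain-correlation reporting convention). A
constant model triangle is rejected; a neural triangle that is constant
at an isolated timepoint (possible pre-stimulus, where accuracies are
quantised) is flagged and scored ρ = 0 so downstream statistics stay
finite.

## Statistics

**Sign permutation.** Under the null, each subject's time-course is
symmetric around zero; the group-mean statistic is recomputed under
`n_perm = 1000` random per-subject sign flips. Two-sided p is the
proportion of flips with `|statistic| ≥ |observed|`, the observed
statistic counted among them, so `p ≥ 1/(n_perm+1)` and p = 1 exactly
on all-zero data.

**Cluster correction.** Candidate clusters are maximal runs of
`p < 0.05` (cluster-defining threshold). The null statistic is the
*maximum cluster size* (count of contiguous supra-threshold timepoints
— size, not mass, following the method's literal description) over the
same sign-flip permutations, each permutation's p-map obtained by
ranking it within the permutation distribution. A cluster is significant
when the fraction of null maxima at least as large is ≤ α = 0.05.
Family-wise error on null data is verified ≤ 0.075 over 500 simulated
runs.

**Bootstrap latencies.** Subjects are resampled with replacement
`n_boot = 1000` times; per draw the subject-average is formed and the
latency extracted: peak = argmax within the search window (default
(0, 600) ms, excluding baseline and epoch edges; first occurrence on
ties), onset = first timepoint of the earliest significant cluster at or
after stimulus onset, *recomputed per draw* (draws without a significant
cluster are recorded as missing and reported as a fraction). The
distribution supplies mean ± SEM and the percentile 2.5/97.5 CI (linear
interpolation between order statistics, as in the 5% outlier trim).
Bootstrap and permutation are two separate procedures sharing the
subject sample, not nested.

**Summaries.** Peak-latency samples can be trimmed (top/bottom 5%,
values strictly outside the percentile bounds removed) and restricted to
latencies ≤ 150 ms (boundary inclusive). `count_significant` tallies
significant timepoints per descriptor and sums them per detail
orientation across levels — the quantity behind the oblique-effect
comparison.

## Pipeline defaults and fixture scale

Configuration defaults equal the published analysis values wherever one
is printed: 5 levels, K = 4 × 10, 100 SVM repetitions, 1,000
permutations and bootstrap samples, thresholds 0.05/0.05, 5% trim,
150 ms cutoff, epoch (−150, 1000) ms at 1 ms. The default synthetic
fixture is deliberately desk-sized (8 subjects, 12 conditions, 12
trials, 32 channels, (−100, 400) ms at 5 ms) so a full `simulate →
report` run completes in minutes; the full 16/92/40/306 scale remains
configurable. The recovery suites use 10 subjects, 10–12 conditions, 24
trials, 48 channels at 5 ms resolution — chosen so that decoding
accuracies sit in their dynamic range (ceiling-level SNR makes every
pair perfectly decodable and erases the RDM's graded geometry) and the
grand-average ρ curves resolve 10 ms latency differences.

## Known limitations

- The batched SVM solver targets the tiny, balanced two-class problems
  this pipeline produces; it is not a general-purpose SVM.
- Blink removal is a single-PC projection per trial, not a full SSP/ICA
  treatment; it assumes one dominant artifact direction.
- Onset bootstrap re-runs the cluster test per draw with a reduced
  permutation count (default 200) for tractability; onset CIs are
  correspondingly coarser than peak CIs.
- `1 − Pearson` RDM cells for near-constant descriptor vectors are
  numerically fragile; they are flagged missing rather than imputed.
- Decoding RDMs at pre-stimulus timepoints can be exactly constant
  (quantised accuracies), where ρ is defined as 0 by convention.
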