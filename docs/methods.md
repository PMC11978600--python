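# Methods

This note documents the models, conventions and design choices behind
`cogtraj`, in the order the pipeline runs them.

## Synthetic cohort model

**Study structure.** Three overlapping assessment waves with sizes 211, 503
and 113. Of the wave-3 participants, 99 were previously seen in waves 1 and 2
and 10 in wave 1 only; 136 wave-2 participants were seen in wave 1. This is
the unique reading of the printed overlap counts that yields
211 + (503 − 136) + (113 − 99 − 10) = 582 unique participants, and it fixes
the membership groups exactly: 99 three-visit participants, 37 + 10 two-visit,
436 single-visit. Visit ages are drawn uniformly inside wave-specific windows
(57–59, 61–67, 66–68 years), sequentially constrained to be strictly
increasing (minimum gap 0.25 y where windows overlap).

**Latent trajectories.** Each participant belongs to one of four archetypes
drawn from mixing weights proportional to 69/256/65/136. Latent cognition is
linear in age: $c_i(t) = \beta_a + \gamma_a (t - 57) + b_i$, with archetype
levels $\beta$ = −4.5 (low-stable), −1.5 (low-declining), +1.5 (high-lower),
+4.5 (high-upper) on the z-scale, slopes $\gamma$ = 0, −0.06, −0.02, 0 per
year, and participant intercepts $b_i \sim N(0, 0.15^2)$. Linearity is the
simplest form consistent with stable-vs-declining courses; curvature would be
a config extension.

*Why these values.* Two structural facts constrain them. First, 63 % of the
cohort has a single visit, for which a slope is unidentifiable — archetype
recovery for those participants must come from level separation, so the level
band each archetype sweeps over 11 years (at most 0.66 z for the decliner)
must stay well inside the gaps between neighbouring levels (3 z). Second,
Davies-Bouldin model-order selection only resolves four groups (rather than
the high/low super-groups) when the worst adjacent-pair ratio
$(S_i + S_j)/M_{ij}$ falls below the ≈ 0.5 that two merged, equally spaced
pairs produce; that requires equally spaced levels and within-group scatter
(score noise plus nuisance factors, see next paragraph) below about a quarter
of the adjacent-level separation. The defaults satisfy both margins with room
to spare; they encode a cohort in which the four trajectory phenotypes are
real, separated structures, which is the regime the clustering method is
designed to detect.

**Observed scores.** A fixed loading matrix maps the rank-r latent vector
(signal $c_i(t)$ plus r − 1 standard-normal per-visit nuisance factors) to 77
named battery scores: `score = intercept + a·c + B·z + ε`,
$\varepsilon \sim N(0, 0.25^2)$, signal loadings $|a_j| \sim U(0.6, 1.0)$,
nuisance loadings totalling 0.12² variance per score. Latency/error-type
scores (trail-making times, reaction times, error counts — a fixed list
derivable from the score names) carry negative signal loadings, so worse
cognition raises them; the same flag list drives the composite score used for
archetype naming.

**MRI.** 35 regions with literature-plausible baseline volumes, tagged
ventricle/CSF (growing ≈ 1.5 %/y, faster for decliners), neocortical
(shrinking 0.4 %/y at baseline, ×2 for the declining archetype, ×0.8 for
high-upper), subcortical and other. Archetype level factors encode atrophy
accrued before age 57 (e.g. neocortex ×0.985 for low-stable vs ×1.015 for
high-upper). Per-participant ICV ~ N(1.5 × 10⁶, 1.2 × 10⁵) mm³ is constant
across visits; per-region subject effects (SD 5 %) are constant in time so
within-participant change reflects the slope; multiplicative visit noise is
1 %.

**EEG.** Each participant-visit yields a 64-channel, 2 kHz recording:
spectrally shaped 1/f background (5 µV RMS at snr = 1) plus sinusoids at 8
and 36 Hz. Tone amplitude = band base (2 µV alpha, 1 µV gamma) × region gain
(occipital 1.5 … frontal 0.7) × archetype gain (0.6/0.8/1.0/1.2 for
low-stable/low-declining/high-lower/high-upper; parietal and temporal
channels carry the full gain, other regions its square root, so the group
effect concentrates temporoparietally) × log-normal variability at the
participant (SD 0.5), visit-region (SD 0.45) and band (SD 0.1) levels. The
regional variability keeps between-region contrasts from identifying the
group noise-free; amplitude magnitudes were chosen so the modality ordering
of classification accuracy is cognitive > MRI > EEG, matching the generated
effect sizes. Recordings are produced lazily (one at a time) so a full
cohort's EEG never resides in memory.

**Risk factors.** Drawn independently per participant given archetype, with
defaults calibrated to the printed per-group count tables: binary factors
(alcohol use 65/69 … 128/136, smoking, illness, four familial conditions),
father's education in the three printed categories, father's occupation in 20
ordered categories with a group-dependent exponential tilt (no counts are
printed for it; the tilt is a one-time choice), and Gaussian school years, IQ
and BMI (BMI has no printed moments; means 26–27.2 were chosen once).
Cross-factor correlation is not modelled because only marginals are printed.

**Missingness.** MCAR at the participant-visit level (whole scan sessions
disappear, as with scanner absence), default rates 0.5 for MRI and 0.35 for
EEG; no dropout model is implied by the study description.

## Preprocessing

Fixed order: coverage → constancy → IQR → empty-participant removal. The
coverage rule counts non-missing participants per *administered* visit (a
visit where a test was never given does not disqualify it). "Constant within
the [5, 95] percentile band" is operationalized as: the multiset of pooled
values with rank inside the band contains a single distinct value. Quantiles
use linear interpolation throughout. The 5×IQR fence pools visits per
variable (a per-visit flag exists); fewer than four finite values disables
flagging with a warning. ICV normalization divides by the participant's ICV
and excludes non-positive/missing ICV with a log entry. Nothing is imputed.

## Autoencoder summary

Architecture: input → round(0.8 · input) → latent (encoder), mirrored
decoder; tanh on hidden layers, linear latent and output. Exact widths and
activation are free choices exposed in `AutoencoderSpec`. Training is
full-batch Adam (lr 10⁻², 300 epochs by default) on the masked MSE — the loss
sums over observed entries only, which avoids biasing reconstruction by
missingness; at encoding time missing standardized inputs are set to 0 (the
variable mean) and the imputation count logged. Visits pool as independent
rows. Determinism: Glorot initialization and batch order derive from the
spec seed. With linear activations the optimum is the truncated SVD, which
the tests use as an optimization oracle (within 5 %). Latent-size selection
is tenfold CV of held-out masked MSE with the one-standard-error rule; the
default latent fraction 0.65 (50 of 77) is used without CV in the standard
pipeline.

## Trajectory clustering

Dependent multivariate DTW: one alignment path over the joint feature
vectors, local cost squared Euclidean, distance = √(accumulated cost).
Sequences have at most three points, so no warping-window constraint is
applied, and ages never enter the alignment (visits align ordinally — the
method compares shapes "regardless of time-point differences"); missing
visits shorten the sequence rather than being imputed. A brute-force
enumeration of all monotone paths serves as the test oracle.

Centroids are fixed-length (L = 3) sequences updated by DBA: align all
members to the centroid, replace each centroid point by the mean of its
aligned member points; the summed squared-DTW objective is non-increasing.
Standalone DBA initializes from the medoid (subsampled at > 60 members),
stretched to length 3 by linear interpolation; inside k-means the current
centroid warm-starts the update. k-means uses k-means++-style seeding on DTW
distances, lowest-index tie-breaking, farthest-point repair of emptied
clusters, and best-of-10 restarts by inertia; `inertia` is the sum of
*squared* DTW distances (the quantity the algorithm actually minimizes, and
the one whose per-iteration monotonicity is asserted). Because sequences are
short, assignment and DBA run vectorized over all participants (a padded
(n, 3, d) array with per-cell dynamic programming and batched backtracking);
this is what keeps a 7-value Davies-Bouldin scan of a 582-participant cohort
under ten seconds.

The Davies-Bouldin index uses unsquared DTW distances for both scatters and
centroid separations; coincident centroids return +∞ with a warning. k is
selected as the DB argmin over 2–8, ties to the smaller k. Archetype naming:
order the four clusters by mean composite level (direction-corrected mean
z-score, higher = better); the bottom two form the low pair; within each
pair the more negative mean within-participant slope (least-squares per
participant, averaged) is named "declining" (low pair) or "lower" (high
pair). Other k get generic level-rank names.

## EEG measures

Welch PSD with 2 s Hann segments and 50 % overlap: 0.5 Hz resolution puts
both 8 and 36 Hz exactly on bins; density scaling keeps Parseval within 5 %.
Spectra are multiplied by frequency (zeroing DC) to flatten the 1/f
background, the maximum within ±0.5 Hz of each stimulation frequency is the
channel's peak power, channel peaks average within five fixed scalp regions
(10-20 prefixes; midline Z-channels to central, mastoids to temporal), and
the ten region×band values are log-transformed and z-scored across all
participant-visits (pooled across visits; a flag switches the log off).
Artifact handling, referencing and filtering are out of scope — recordings
are assumed clean.

## Group statistics

Two-sided tests throughout: Wilcoxon rank-sum (midrank ties; exact
enumeration when the combined sample is ≤ 10 without ties, otherwise the
tie-corrected normal approximation *without* continuity correction — the
continuity-corrected variant cannot agree with the two-group Kruskal-Wallis
test, which the suite asserts to 10⁻⁶), Kruskal-Wallis with tie correction,
Fisher's exact (two-sided by probability mass; zero margins yield p = 1 with
an undefined-OR flag), Pearson chi-square without Yates correction (expected
counts < 5 warn). No multiple-testing correction by default; a
Benjamini-Hochberg column is available by flag. Trajectory summaries report
mean, SD, n and 1.96·SD/√n per (group, visit); the error bar is the 95 % CI
of the mean (the alternative mean ± SD reading is selectable), with n = 1
cells reporting a missing half-width.

## Decline classification

Clusters merge as {high-upper, high-lower} → high, {low-stable,
low-declining} → low; "low" is the positive class. Features are each
participant's earliest visit with any data for the modality, mean-imputed
within that visit (count logged). Logistic regression uses a small ridge
penalty (10⁻⁴ on standardized features) so separable data remain fitted
deterministically; zero-variance features are dropped with coefficient 0.
AUC defaults to in-sample (no train/test split is described for the original
analysis, and in-sample is the optimistic convention those headline numbers
imply); a k-fold cross-validated variant is a flag. AUC is computed as the
Mann-Whitney rank statistic with half credit for ties and is verified to
equal the trapezoidal area under the stored ROC curve to 10⁻¹²; the
univariate scan reports direction-corrected AUC ≥ 0.5 per cognitive score.
Raw scores (not latents) are the default cognitive features.

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → summarize → cluster, then
optionally eeg → stats → classify, persisting every stage's outputs as
long-format CSV plus a JSON manifest of row counts and SHA-256 output hashes;
identical config + seed reproduces identical hashes. A single global seed
fans out to fixed per-stage offsets so stages are reproducible in isolation.
The simulate–cluster trunk is mandatory in this entrypoint; externally
supplied tables enter through `cogtraj.io.read_long_table` and the
stage-level APIs.

## Problem sizes and what the tests show

The test-suite and acceptance script run the full default cohort (582
participants, 827 visits, 77 scores) end to end; the multi-seed model-order
check uses 20 cohort replicates, statistical calibration 1000 null
simulations per family, and EEG checks 40–60 s of synthetic signal. These
sizes were chosen so the whole suite completes in a few minutes on one CPU
while leaving the acceptance margins (ARI ≥ 0.9, ≥ 80 % of seeds selecting
k = 4, 5 % type-I ± 1.5 points) comfortably resolved.

Passing on synthetic data demonstrates internal correctness — that each
stage implements its stated contract and that the chain recovers structure it
was designed to detect — not field validity. Real cohorts differ in ways the
generator deliberately omits: non-linear and heteroscedastic trajectories,
informative dropout, correlated risk factors, test-retest effects, EEG
artifacts and volume-conduction structure, scanner drift. Where those
features matter, the corresponding stage (MCAR missingness, independent
factors given archetype, clean recordings) is the first thing to revisit.

## Known limitations

- DTW with ≤ 3 points per sequence is closer to set alignment than to
  elastic time warping; the method's value here is uniform handling of
  unequal lengths, not warping per se.
- The Davies-Bouldin criterion prefers merged super-groups whenever
  within-group scatter is large relative to within-pair separation; on data
  without clearly separated phenotypes, `select_k` will legitimately return
  2 — that is a property of the criterion, not a defect of the search.
- In-sample AUC on 77 features is optimistic by construction; use the CV
  flag for honest generalization estimates.
- The autoencoder is a shallow nonlinear compressor; its latent coordinate
  system is not orthonormal, so latent-space Euclidean geometry (and hence
  DTW) is a distorted image of score-space geometry. The distortion is mild
  in practice here but is the main reason clustering quality should be
  validated against ground truth or stability checks rather than assumed.
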