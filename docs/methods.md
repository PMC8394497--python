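# Methods

## T2 estimation

The forward model is mono-exponential transverse decay,
`S(TE) = S0 · exp(−TE/T2)`, sampled at two echo times (PD-weighted at
TE_a, T2-weighted at TE_b). Two points determine the exponential exactly,
so the map is the closed form `T2 = (TE_b − TE_a)/(ln Sa − ln Sb)` and the
refit residual (`t2_fit_quality`) is identically zero wherever the
solution was not altered afterwards. Three voxel classes carry no physical
T2 and are masked invalid rather than imputed: non-positive signal in
either echo, and `Sa ≤ Sb` (apparent growth with echo time, which noise
produces in low-signal voxels). Valid estimates are clamped to a
physiological window, default (1, 3000) ms, and remain valid; without the
clamp, near-equal echo pairs produce arbitrarily large values that would
dominate every regional histogram. Invalid voxels are excluded from all
regional statistics. Default echo times in examples and the phantom are
TE_a = 10 ms, TE_b = 110 ms, typical of dual fast spin-echo protocols;
both are configurable everywhere.

## Rigid registration

Segmentation labels are defined on the anatomical image; within-session
head motion is small and rigid. Registration maximises Mattes mutual
information (32 bins) over a versor rigid transform with a regular-step
gradient-descent optimiser (learning rate 4.0, minimum step 1e-6, up to
1000 iterations, relaxation 0.6) across a 3-level shrink/smooth pyramid,
with full metric sampling at the default desk-scale volumes. The T2 map
is always the *fixed* image so the quantitative values are never
resampled; labels move with the anatomical image under nearest-neighbour
interpolation, which guarantees the output label set is a subset of the
input's plus background. When most of the T2 map is invalid (air
background dominating the field of view), the metric is steadier on the
raw T2-weighted echo intensity, which shares the map's grid;
`registration_image` switches to it above a 50% invalid fraction. Visual
quality control is replaced by an automated per-region Dice report
against ground truth on phantoms (the phantom misalignment-recovery
check passes at < 0.5 mm / < 0.5° error and per-region Dice ≥ 0.90).

## Feature registry

Each region yields 38 features: 1 volume, 28 signal-distribution, 9
texture. The signal set is: mean, SD, ICV (intensity coefficient of
variation, σ/µ), skewness, excess (Fisher) kurtosis, histogram entropy
and energy, values at percentiles 0.01/1/5/25/50/75/95/99/99.99, central-90%
mean/SD/ICV (values within [P5, P95]), precision range (P95 − P5),
min/max/range, median absolute deviation, and one-sided mean-centred tail
probabilities P(v < µ−2σ), P(v < µ−3σ), P(v > µ+2σ), P(v > µ+3σ). Entries
carry a `documented` provenance flag separating the canonical core from
the symmetric counterparts that complete the set; the registry is
configurable and versioned with the package.

Conventions that matter at regional sample sizes: percentiles interpolate
linearly between order statistics; moment statistics use the population
(ddof = 0) normalisation; histograms use 64 equal-width bins over the
region's own [min, max] with entropy in bits and energy Σp²; a constant
region is defined to have entropy 0, energy 1, and zero skewness/kurtosis
(numerically constant samples, as produced by noiseless simulations, take
the same branch to avoid catastrophic cancellation in the moment ratios).

The texture set works on the full 3D voxel cloud with T2 values as
intensity weights: the six unique components of the mass-scatter tensor
`M_ab = Σ I·(a−c_a)(b−c_b)/ΣI` (mm², about the intensity-weighted
centroid; YY is the anterior–posterior component), a face-counting
surface-area estimate, compactness `36π·V²/A³` (1 for a perfect sphere
with exact surface area; face counting overestimates A, so digital shapes
score below 1) and sphericity (its cube root). Mass scatter is a *central*
moment, hence translation-invariant, and the intensity weights are
relative, so a global intensity scale cancels. A 2D projection-image
variant of the texture block is a possible registry extension; the 3D
weighted-moment reading keeps every component well-defined in mm².

Regions with fewer than `min_voxels = 10` valid voxels return the
all-missing sentinel (NaN) for signal/texture features; volume is always
computed from the raw label mask. Per-region failures degrade to NaN and
never abort a subject.

## Contralateral folding and the analysis table

For every left/right pair and each of the 37 signal/texture features, the
table carries the arithmetic pair mean and the absolute difference. The
pair mean is the mean of the two per-side feature values, not a feature
recomputed on the pooled voxel set — the reported statistics are per-side
quantities, and folding must commute with the per-region definitions.
Volumes pass through per region, unfolded. With the full 83-region atlas
(40 pairs + brainstem, corpus callosum, third ventricle) and the default
registry this yields 37 × 2 × 40 = 2960 contralateral columns + 83
volumes + 8 neuropsychological scores. If either member of a pair is
missing a feature, both derived values are missing. Columns missing in
more than 20% of subjects can be dropped before statistics
(`drop_sparse_columns`); remaining missing values are median-imputed
*inside training folds only* during the benchmark, never globally.

## Univariate screening

Each feature column is compared between groups with the two-sided
Wilcoxon rank-sum test: the exact null distribution when both groups have
at most 10 subjects and the pooled sample is tie-free, otherwise the
normal approximation with tie and continuity corrections; the mode used
is recorded per feature. Benjamini–Hochberg step-up q-values are computed
*within feature family* (neuropsychological, volumes, signal/texture),
mirroring how the families are reported and keeping the imaging
correction burden away from the eight clinical scores; whether volumes
should share the imaging pool is ambiguous in principle, so it is
configurable and defaults to separate. Significance is declared at
q < 0.05. The multivariate selection pool takes the lowest-p fraction per
family — 5% of signal/texture columns, 15% of volumes, all
neuropsychological scores (counts are floor(fraction × family size), at
least 1) — rather than a fixed p cutoff, which would make the pool size
noise-dependent. Demographic comparability uses Wilcoxon for age and
education and a Yates-corrected chi-squared test for the 2×2
sex-by-group table.

## Benchmark

Model comparison uses repeated stratified holdout: by default 100
independent 80/20 splits (subjects can recur across validation sets; no
coverage guarantee is attempted, since independent splits keep repeats
exchangeable). Every method is a leakage-safe sklearn pipeline — median
imputation, standardisation, optional feature selection, classifier —
fitted on the training split only; all methods share the identical
splits, so comparisons and the two-experiment increment
(neuropsychological-only vs neuropsychological + screened imaging) are
paired. The progressing group is the positive class. Metrics come from
the *pooled* out-of-sample predictions: accuracy, sensitivity,
specificity and balanced error `1 − (sens + spec)/2` from the pooled
confusion matrix (class decisions are each pipeline's own `predict`,
i.e. threshold 0.5 on scores), ROC AUC as the midrank statistic over
pooled scores, and 95% CIs by percentile bootstrap (default 2000 draws)
resampling *subjects* with their pooled predictions attached, which
respects the dependence between repeats.

The selection filters return deterministic rankings: Wilcoxon and
Student-t p-values; |Kendall τ-b| with the class; greedy mRMR with
relevance |τ-b(x, y)| and redundancy the mean |τ-b| against already
selected features; order of entry along an L1-logistic regularisation
path; random-forest permutation importance; single-tree impurity
importance; univariate IDI (discrimination-slope gain of a one-feature
logistic score over the intercept-only model) and univariate NRI (net
reclassification at threshold 0.5 against the intercept-only rule).
Constant features always rank last. The default selection size is 10
features, matching the order of magnitude models of this size actually
use.

Stage-wise model selection is represented by a documented surrogate, not
a reimplementation of any proprietary routine: bootstrapped forward
stepwise logistic selection with B = 20 resamples, entry by
likelihood-ratio p < 0.1, and retention of features selected in ≥ 30% of
resamples (falling back to the single best feature if none qualifies).
The inner logistic fits use Newton-IRLS with a 1e-6 ridge so perfect
separation cannot blow up the Hessian. The ensemble is a majority vote of
the other arms, with the positive-vote fraction as its score — how member
scores should be combined is underdetermined, and the vote is the
simplest rule consistent with majority behaviour.

Selection frequency counts how often each feature enters a *final trained
model* across repeats (selector support, intersected with nonzero
coefficients for linear models and used splits for trees), per method and
with top-6 summaries.

## The phantom

The generator emulates the data conditions the pipeline was designed for:
paired-echo volumes obeying mono-exponential decay with additive Gaussian
noise per echo (magnitude-Rician noise is deliberately not the default —
additive Gaussian keeps the zero-noise recovery tests exact and the 1%
noise regime is far from the Rician floor), a mirrored multi-region
atlas, a known rigid misalignment between echo and anatomical spaces, and
group-dependent regional effects. Regions are ellipsoids on a lattice:
left-hemisphere ellipsoids are mirrored voxel-exactly across the
mid-sagittal plane (grid centre along x; left = lower x), midline regions
are centred on the plane and flip-symmetric. The default desk-scale
layout is a 64×64×48 grid at 2 mm isotropic with 6 pairs + 1 midline
region; the full 40-pair + 3-midline layout is a configuration preset
used for manifest-count checks. Default tissue parameters: baseline
regional T2 spread over 75–115 ms (midline up to 180 ms), S0 ~
N(1000, 50) per voxel, noise SD 10 (1% of mean S0), misalignment
(3° about z, 2 mm in x and y). Progressor subjects receive per-pair
additive T2 shifts with a right-side asymmetry increment (default: +6 ms
mean, +10 ms asymmetry in the first pair, the hippocampus analog); group
sizes default to the 22 stable / 18 progressing of the target study
design. Neuropsychological scores are Gaussian with group-shifted means
for the memory summary score and ADAS-11 only, mimicking a cohort where
those two tests separate the groups; all parameters live in the spec.
Subject i draws from the independent stream `default_rng([seed, i])`, so
cohorts are bit-reproducible and insensitive to generation order.

What the phantom does *not* model — realistic anatomy, partial-volume
mixing at region boundaries, bias fields, Rician magnitude statistics at
low SNR, multi-site scanner effects, correlated feature noise — bounds
what passing tests show: they validate the estimators, the folding
algebra, the statistics, and the benchmark harness against known truth,
not clinical effect sizes. Headline tabulated results on clinical
cohorts require the original external data and are out of scope; the
quantities recomputed by `scripts/acceptance.py` are the structural
counts, the printed worked examples (which are pure arithmetic on
published counts), and the phantom ground-truth recovery measurements.

## Numerical and design notes

- Wilcoxon exact/asymptotic switchover: exact only when both n ≤ 10 and
  no pooled ties; recorded per feature.
- BH q-values: step-up `min_{j≥i} p_(j)·m/j` capped at 1, mapped back to
  input order; validated against an independent brute-force oracle and
  statsmodels on random vectors.
- Registration determinism: fixed sampling seed; the optimisation trace
  (metric per iteration) is returned for QC, and a near-zero final
  mutual information raises instead of returning a silent identity.
- Percentile, histogram and ddof conventions are frozen in the registry
  documentation above because they change values at n < 100.
- Problem sizes in the test suite (desk-scale grids, 10–25 benchmark
  repeats, reduced filter grids) were chosen so the whole suite validates
  every contract in well under half an hour on one CPU; all thresholds
  are the ones stated here, not tuned per run.

## Known limitations

- Two-point T2 estimation has no redundancy: it cannot flag B1 errors,
  stimulated echoes, or multi-compartment decay; multi-echo least squares
  is out of scope.
- The 28 + 9 feature registry reconstructs a documented core and
  completes it with symmetric counterparts; `documented` flags make the
  provenance explicit, and alternative registries plug in.
- GLCM/GLRLM/wavelet radiomics and full IBSI compliance are not included.
- With 40 subjects, repeated-holdout CIs are wide and pooled metrics are
  sensitive to a few subjects; conclusions should rest on the paired
  experiment comparison, not absolute metric values.
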