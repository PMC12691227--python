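# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `wsiprog`.

## Problem setting

A whole-slide image (WSI) of an H&E-stained resection specimen is far too
large to feed to a network directly. The pipeline compresses it in two
complementary ways:

1. **Macro scale.** The slide is tiled into non-overlapping patches (224 x
   224 px at 20x by convention), each patch is assigned one of eight tissue
   categories (tumor, necrosis, fibrosis, lymphocyte aggregates, normal
   parenchyma, hemorrhage, debris, background) by a pluggable patch
   classifier, and the resulting label grid is expanded into an 8-channel
   indicator map — one spatial channel per category. This map encodes
   *tissue architecture*: where the necrosis sits, whether fibrosis wraps
   the tumor or permeates it.
2. **Micro scale.** Slide-level category proportions `r_z` are computed
   over the label grid, a fixed budget of N = 27 patches is apportioned
   across categories as `n_z ~ r_z * N`, the patches are drawn by
   stratified sampling within each category, and their RGB tiles are
   stacked into a 27-slot tensor consumed as an 81-channel image. This
   preserves *cellular morphology* in proportion to what the slide actually
   contains, rather than sampling only tumor or sampling blindly.

Each representation feeds a convolutional encoder ending in a K-dimensional
feature (K = 2048 for the reference backbones), a fully-connected +
batch-norm + ReLU projection to a 32-dimensional embedding, and a linear
risk head. The fused model drops both branch heads, concatenates the two
embeddings (64-dim) and predicts a patient-level risk through a small MLP
(hidden widths 64 and 32). All three models are trained with the Cox
negative log partial likelihood

    L = - sum_{i: d_i=1} [ s_i - log sum_{j: t_j >= t_i} exp(s_j) ]

with Breslow handling of tied event times and a numerically stable
log-sum-exp. The loss depends on risk scores only through differences, so
it is exactly invariant to adding a constant to all scores; concordance
depends only on ranks.

## Apportionment of the patch budget

`r_z * N` is non-integer in general. Slots are assigned by Hamilton
(largest-remainder) apportionment: floor quotas first, remaining slots to
the largest fractional remainders (ties toward larger `r_z`, then lower
category index). When a category has fewer available patches than its
quota, the allocation is clipped and the shortfall is reassigned one slot
at a time to the category where it least increases the total deviation
`sum_z |n_z - r_z N|`, with ties again toward larger `r_z` — so dominant
tissue types absorb the compensation. This procedure provably attains the
minimum total deviation among all feasible allocations (the per-category
objective is convex in `n_z`, so greedy marginal-cost assignment is exact);
the test suite checks it against both an independent greedy oracle and an
exhaustive dynamic program.

Slots are ordered category-ascending, then draw order, so the channel
semantics of the 81-channel input are stable across patients. Sampling
within a category is uniform without replacement.

## Neural-network engine

The risk models run on a compact NumPy engine written for this package:
2-D convolution via im2col (optionally grouped), batch normalization,
ReLU, global average pooling, fully-connected layers, residual bottleneck
blocks, and Adam with classic L2 weight decay. Everything is float64 on
the CPU with explicitly seeded initialization and permutation streams, so
training runs are bit-reproducible — a property the determinism tests rely
on. Backward passes are hand-derived and verified against central finite
differences in the test suite.

Two backbones sit behind `EncoderSpec`:

* `tiny_test` — a two-stage CNN (stride-2 convs + BN + ReLU + global
  average pooling) used by the test suite and the synthetic benchmarks.
* `reference_large` — a residual bottleneck encoder in the ResNet-50
  family, four stages of widths 256/512/1024/2048 (one block per stage, a
  deliberate depth reduction for CPU use) ending in a 2048-dim pooled
  feature. The micro variant uses grouped 3x3 convolutions (cardinality
  32), ResNeXt-style. First layers are built at the branch's channel count
  (8 macro, 81 micro) with fresh random initialization.

## Training protocol

`TrainConfig` defaults to Adam with initial learning rate 1e-4, weight
decay 1e-5, at most 100 epochs, and a plateau schedule that multiplies the
learning rate by 0.1 when the validation C-index has not improved by more
than 1e-4 for 10 epochs; the best-validation checkpoint is returned. These
defaults suit reference-scale encoders on real cohorts. The synthetic
benchmarks with the tiny backbone use learning rate 1e-2 (a scale-
appropriate choice fixed once), full-batch risk sets, and 8-30 epochs.
Batches with zero events emit a skip signal rather than a NaN. Mini-batch
training uses batch-local risk sets — a standard approximation whose bias
is documented rather than corrected.

Cross-validation is patient-level, stratified by event indicator, with the
same seeded splits shared by every compared model. Per fold the package
reports Harrell's C-index (risk ties count 0.5), the IPCW integrated Brier
score (Breslow baseline cumulative hazard from the training fold,
`S_i(t) = exp(-H0(t) e^{s_i})`, censoring distribution by the Kaplan-Meier
estimator of the censoring process, trapezoid integration normalized by the
grid span), and the IPCW mean absolute error between observed and
predicted median survival times. Times are divided by the cohort's maximum
follow-up before the MAE so the score is scale-free in [0, ~1]; reported
values of that magnitude in the literature imply the same normalization,
but the exact convention there is not stated, so this one is fixed and
documented here. Fold statistics use t-based 95% intervals with
df = folds - 1, paired t-tests on fold-wise scores, and one-way
repeated-measures ANOVA with folds as subjects.

Risk stratification splits at the median risk score (ties to the low-risk
group) and compares the groups with a two-group log-rank test; the
implementation is checked against lifelines to 1e-6.

## Interpretability

**Occlusion sensitivity.** A window (default 16 cells, stride 8) slides
over the tissue map; all 8 channels inside it are set to zero — the
natural ablation, since zero means "no tissue" in an indicator map — and
the map records risk(original) - risk(occluded) averaged over covering
windows, so positive values mark risk-elevating regions. On a linear
channel-sum model the map equals the analytic window average exactly.

**Structural parameters.** Tumor support is the morphological closing of
tumor-labeled cells with holes filled (enclosed necrosis counts as tumor
when locating the margin — one of the genuinely open design points,
resolved this way because necrotic cores are inside the lesion). The
margin band collects cells within `band_thickness / 2` of the support
boundary on each side (distance transform; default thickness 10 cells,
configurable); the interior is the support minus the inner ring. N-ratio
is the necrosis fraction of all tissue; FIB-center and FIB-edge are the
fibrosis fractions of the interior and the band. Naming follows the
hazard directions consistently reported for these regions (interior
fibrosis adverse, HR > 1; marginal fibrosis protective, HR < 1). A
multivariable proportional-hazards fit of survival on the three parameters
(lifelines' Newton-Raphson solver) reports Coef / Se_Coef / HR / CI /
p-value per covariate.

A caveat the tests document explicitly: when a dense fibrous capsule
replaces the boundary tumor cells, the label-derived support boundary sits
at the capsule's inner edge, so the symmetric band covers only about half
of the capsule and the FIB-edge *estimate* is diluted toward ~0.5 of the
capsule density. The generator's ground truth is measured against the
exact core geometry and is unaffected; parameter-recovery claims are made
against that truth.

**Nuclear morphometrics.** Nuclei are segmented on the stain-intensity
proxy (1 - grayscale) by adaptive thresholding, small-object removal and
watershed splitting on the distance transform. Per nucleus the extractor
measures area, perimeter, orientation, eccentricity, extent (area /
bounding-box area), max and mean staining intensity, and GLCM variance and
angular second moment (distance 1, four directions, 32 gray levels); per
tile each measure is aggregated as mean, median and SD. This is a compact
extractor covering the discriminative feature families — intensity, GLCM
texture, shape variability — not a re-creation of a 732-feature
morphometry suite; externally produced feature CSVs can be ingested
directly by the selection step.

**Dual-criterion selection.** Features must have (1) a nonzero Lasso
coefficient at the cross-validated penalty (binary group label as
response, features standardized) and (2) a Benjamini-Hochberg-adjusted
Mann-Whitney p < 0.05; the intersection is reported. BH correction is this
package's choice where the convention is unstated.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study
conditions for every benchmark.

* **Label grids.** An elliptical tissue region (outside = background,
  masked out) filled with normal parenchyma plus ~5% scattered
  lymphocyte/hemorrhage/debris; an elliptical tumor core (semi-axes 22-34%
  of the grid); fibrosis placed cell-wise Bernoulli in the margin band
  (probability `p_edge` ~ U(0.05, 0.9)) and interior (`p_center` ~
  U(0, 0.5)); necrosis blobs grown inside the interior until a per-patient
  target fraction of tissue (Beta(2, 8): mean 0.2, SD 0.12) is necrotic.
  Grids must be at least 16 cells on a side. True structural parameters
  are measured against the exact generated geometry.
* **Tiles.** Procedural: a category-colored background with dark
  elliptical nuclear blobs. For tumor tiles, nucleus density, staining
  depth ceiling and shape dispersion all increase monotonically with a
  latent malignancy level in [0, 1] — enough signal for the micro branch
  and the morphometry pipeline, deliberately not photorealistic H&E. No
  stain-normalization artifacts, folds, blur or scanner variation are
  simulated, so passing tests demonstrate algorithmic correctness, not
  robustness to real-slide artifacts.
* **Survival.** Event times are exponential with rate
  `baseline_hazard * exp(h)` (Weibull optional), where the log-hazard `h`
  is the configured linear function of the true structural parameters and
  optionally the latent malignancy. Default coefficients (+2.4 N-ratio,
  +1.4 FIB-center, -2.5 FIB-edge) keep the adverse/adverse/protective
  direction pattern reported for these regions at fraction-scale
  magnitudes that give realistic hazard ratios across the observed
  parameter ranges. Baseline hazard 0.02/month puts the median event time
  near three years, matching long-term hepatocellular-carcinoma follow-up.
  Censoring is an independent exponential whose rate is calibrated by
  bisection on a 10,000-draw pilot so the realized censoring fraction
  matches the configured target (default 0.3). All randomness flows from
  integer-seeded per-patient streams; there is no time-based seeding.

## Benchmark study conditions

Fixed in `wsiprog.benchmarks` and reported by `scripts/acceptance.py`:

* *Learnability*: 120 patients, no censoring, single-factor hazard with
  coefficient 16 on the necrosis fraction (Beta(2, 10) targets; log-hazard
  SD ~ 1.6, oracle C-index ~ 0.75), maps resized to 32 x 32, tiny backbone,
  Adam 1e-2 for 30 epochs, 40-patient validation split; the reported
  validation C-index is the median over three model initializations, and
  occlusion contrast (necrosis minus normal cells) is measured under the
  best of them on five slides.
* *Null calibration*: 200 patients, all hazard coefficients zero, 5-fold
  cross-validation, pooled over five cohort seeds.
* *Sign recovery*: 20 replicate cohorts of 1000 patients under the default
  coefficients; a fit counts as a success only if all three signs are
  correct simultaneously.
* *Feature selection*: 100 tiles, 20 features, one feature shifted by 2 SD
  between groups; 50 replicates for the planted and permuted-label cases.
* *Apportionment*: 200 random Dirichlet proportion vectors with
  availabilities in [0, 40]; agreement means attaining the oracle's
  optimal total deviation (multiple optima are common, so objective values
  are compared, not allocations).

Problem sizes were chosen so each study gives stable rates at desk scale;
the tiny backbone and 32 x 32 maps are the package's reference
configuration for synthetic work.

## Known limitations

* The reference backbones are depth-reduced relatives of their families,
  not literal reproductions; no pre-trained weights ship with the package.
* The patch classifier is pluggable but no trained tissue classifier is
  bundled; synthetic grids bypass classification, and the noisy-oracle
  classifier only models label flips, not correlated classifier error.
* Mini-batch Cox risk sets are batch-local (biased for small batches).
* The IPCW metrics truncate contributions where the censoring survival
  estimate reaches zero, with a warning.
* Headline concordance values on real WSI cohorts are out of scope here;
  all quantitative claims are about synthetic cohorts with known truth.
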