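# Methods

This note records the models, parameter choices, numerical decisions and
known limitations of the package, in the spirit of a statistical methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The maturity model

The central construct is an age-regression "maturity index": a random
forest (500 trees by default, p/3 candidate features per split — the
regression convention) is trained to predict postmenstrual age (PMA, birth
gestational age + chronologic age, in weeks) from the feature profiles of
the *appropriate-growth* infants only. The forest's prediction for any
sample is its *microbiota age* (or *metabolic maturity age*). Three derived
quantities are reported per sample:

- **relative maturity** (weeks): predicted age minus a reference smoothing
  spline evaluated at the sample's true PMA. The spline is a cubic
  smoothing spline of the reference group's out-of-bag predicted ages
  against PMA, with the smoothing parameter chosen by generalized
  cross-validation; evaluation outside the training PMA range clamps to the
  boundary value, because scored cohorts (growth failure, validation)
  extend past the reference range and polynomial extrapolation of a spline
  is meaningless there.
- **for-age Z (MAZ)**: (predicted age − median reference predicted age in
  the sample's PMA bin) / SD of reference predicted ages in the bin. Bins
  are half-open one-month intervals [−∞, 30), [30, 34), [34, 38), [38, ∞)
  weeks, so the integer-week phrasing <30 / 30–33 / 34–37 / ≥38 partitions
  real-valued PMA. The SD is the sample SD (n−1). A bin with fewer than two
  reference samples or zero spread is a hard error, not a NaN.
- **predicted age** itself, for plotting against PMA.

**Out-of-bag scoring of the reference group.** When reference and
non-reference groups are compared, the reference samples are scored by
their out-of-bag predictions (`maturity.reference_scores`), not by running
them back through the fitted forest. In-sample predictions track true age
more tightly than predictions for unseen samples; scoring the two groups
asymmetrically inflates the apparent group difference and, under a null
with no group effect, raises the false-positive rate of downstream rank
tests well above nominal. With out-of-bag reference scoring the type-I
rate is at the nominal level (checked by simulation in the acceptance
suite).

**Feature selection.** A full-model fit ranks features by impurity-based
importance (ties broken lexicographically by feature id, making the ranking
deterministic). Cross-validation over a descending grid of subset sizes
(shrink factor 0.75, always containing p and 1) refits the top-k features
per fold and records held-out MSE; folds group samples by infant (default
`min(100, n_infants)` folds, degrading to leave-one-infant-out) so repeated
measures never straddle a fold — sample-level folds would leak within-infant
correlation and flatter the model. The sparse size is the smallest grid
size whose CV-MSE is within 5% of the minimum ("little impact on model
error"; the tolerance is exposed). Impurity importance is used rather than
permutation-based %IncMSE because only the rank order is consumed, it is
deterministic given the seed, and it is orders of magnitude cheaper inside
the CV loop; the two rankings agree well on the synthetic cohorts at the
top of the list, which is all selection uses.

**Significance.** The sparse model's out-of-bag MSE is compared with
refits under permuted ages (the feature set held fixed; re-selection per
permutation is available). p = (1 + #{null ≤ observed}) / (1 + n_perm),
1000 permutations by default. The statistic is MSE because selection
optimized MSE.

## Longitudinal differential abundance

Per feature, a GCV cubic smoothing spline of normalized abundance against
time (study week or PMA) is fit per group, with duplicate time points
collapsed to weighted means. The difference curve on a ≥100-point uniform
grid over the common time range is segmented into maximal sign-consistent
runs where |d(t)| exceeds a threshold (default 0; a small positive value
suppresses run-merging through near-zero stretches). Each run's signed
trapezoid area is the effect summary. The null permutes group labels at the
*infant* level — all samples of an infant move together, preserving
within-infant autocorrelation — and records the maximum absolute run area;
per-run p-values against this max-null are family-wise valid within a
feature. Benjamini–Hochberg adjustment is applied across features. The
GCV smoothing parameter is re-chosen on each permuted dataset: scipy's
spline interface does not expose the selected parameter for reuse, and
re-running GCV keeps the null statistic exchangeable with the observed one.

## Community structure

Jensen–Shannon divergence uses natural logarithms (values in [0, ln 2]);
the metric square root is available. Principal coordinates are the
classical-scaling eigendecomposition of the double-centered −d²/2 matrix;
negative eigenvalues are reported and their axes discarded, and the
retained "most significant" axes are the leading ones explaining ≥80% of
the positive-eigenvalue mass (configurable). PAM runs BUILD then
best-improvement SWAP on Euclidean distances over the retained coordinates
(raw-dissimilarity input is supported); both phases break ties toward the
lowest sample index, so results are deterministic and row-order invariant.

The number of clusters comes from the gap statistic with B uniform-box
reference draws over the observed coordinate ranges. The selection rule is
**globalSEmax** — the smallest k whose gap is within one standard error of
the global maximum of the gap curve. The original one-step rule (smallest k
with Gap(k) ≥ Gap(k+1) − se(k+1)) is available as `method="tibshirani"`,
but on well-separated clusters the gap curve is flat (with small wiggles)
below the true k and jumps only there, so the one-step rule terminates at
k=1; globalSEmax handles both that geometry and the single-cluster null
(where the gap curve is maximal at k=1).

Cluster–covariate association fits, per cluster, a binary logistic model of
membership on time and group, with inference by infant-level cluster
bootstrap (999 resamples; two-sided p from the sign-crossing fraction of
bootstrap coefficients). This honors within-infant correlation without a
GEE implementation; clusters perfectly separated by a predictor are flagged
with no estimate.

## Preprocessing conventions

- Sparse-OTU filter: keep an OTU iff its count strictly exceeds 10 in at
  least ⌈0.10 · n_samples⌉ samples ("more than 10" is strict; "at least
  10%" rounds up). Samples with fewer than 50 reads are dropped; the OTU
  filter runs first (the order both operations are exposed).
- Rarefaction: multivariate-hypergeometric subsampling (without
  replacement) to 5000 reads, once per analysis with a recorded seed;
  under-depth samples are dropped and reported, not padded.
- CSS: the per-sample scaling factor is the sum of the smallest
  ⌈q · m⌉ positive counts (m = number of positive counts, q = 0.5 by
  default), normalized value = count / factor × 1000. This form is
  scale-equivariant and reduces to the full column sum at q = 1. An
  adaptive mode scans quantiles for the point where per-sample cumulative
  count profiles diverge from the median profile (relative deviation
  > 0.1).
- Shannon diversity uses natural log (the ecology convention and the
  default of the common R implementations).
- Metabolite filters: a metabolite undetected in strictly more than 25% of
  samples is removed; a sample detecting strictly fewer than 50% of
  metabolites is removed. Measured zeros (below LOD) are distinct from
  missing values; zeros become half the minimum *positive* value per
  metabolite before log2. Pareto scaling divides the centered row by the
  square root of its sample SD. The GC-MS chain is log2 → per-batch
  mean-centering → KNN imputation → Pareto; the targeted chain has no
  batch step. KNN imputation (k = 10, capped at n−1) averages the k
  nearest samples under a Euclidean distance over shared observed
  metabolites rescaled by the number of shared dimensions.

## The synthetic cohort generator

The generator emulates the study design and is the package's test bed; its
defaults are the study conditions: 58 infants (36 growth failure), birth
gestational ages 23–27 weeks, samples at study week 0 (first postnatal
week) and weeks 1–9 after reaching full enteral feeding (4–6 chronologic
weeks after birth), library sizes log-normal around the study's median read
depth of 42,546 with log-SD 0.55 (matching the printed IQR), 100 taxa of
which 21 are age-discriminatory, a 45-metabolite acylcarnitine-style panel
with 8 age-discriminatory members, five metabolomics batches.

Age-discriminatory taxa follow logistic log-abundance trajectories in PMA
(saturating colonization, alternating rising and falling, midpoints spread
over 27–41 weeks); compositions are softmax of the log-abundances; counts
are Dirichlet-multinomial with concentration `dispersion × composition`
(default 50, realistic overdispersion for infant stool profiles).
Age-discriminatory metabolites are linear in PMA on the log2 scale with
slopes ±0.12–0.30 (so an 8-week window spans ~1–2.5 log2 units, the scale
of the acylcarnitine trends), Gaussian noise (SD 0.5 log2 units), centered
per-batch offsets (SD 0.3), censoring to zero below each metabolite's 5%
quantile, and missing-at-random masking of 5% of samples' entire panels
(the insufficient-serum-volume mechanism; per-entry missingness is the
GC-MS pattern that the KNN imputation chain handles, and tests exercise it
with explicit masks).

The maturation delay is a horizontal time shift: growth-failure samples are
generated from the appropriate-growth trajectory evaluated at
PMA − delay_weeks. The default delay is 3 weeks — the paper-scale effect is
not printed anywhere, and 3 weeks is the magnitude a clearly separated
maturity gap implies; with delay 0 the two groups share one generating
distribution by construction, giving an exact null. All randomness derives
from one integer seed through named sub-streams per table, so any table is
byte-reproducible alone.

What the generator does *not* emulate: antibiotic perturbations, batch
structure in the 16S data, zero-inflation beyond what the
Dirichlet-multinomial induces, correlated taxa–metabolite couplings, or
clinical covariates beyond group and weight-z. Passing tests therefore show
the estimators recover the planted structure under realistic noise, not
that they are robust to every feature of real cohorts.

## Statistical conventions and numerical details

- Fisher's exact test (two-sided) sums the probabilities of all tables with
  the observed margins whose probability does not exceed the observed
  table's. Probabilities are compared through their integer numerators
  C(r, a)·C(N−r, c−a), so ties are handled exactly with no floating-point
  gate; the returned p is the correctly-rounded float of the exact
  rational. Odds ratios apply the Haldane +0.5 correction only when a zero
  cell is present.
- Wilcoxon rank-sum comparisons use the two-sided Mann–Whitney U; a
  variable constant across both groups short-circuits to p = 1.
- Permutation p-values are always (1 + #{null at least as extreme}) /
  (1 + n_perm), never 0.
- Growth classification: growth failure iff the term weight percentile is
  strictly below 3. Catch-up growth: strictly positive change in weight-z
  between an infant's consecutive *collected* samples regardless of gaps;
  the first sample is unlabeled.
- Forests sort samples by id before fitting, making every fit invariant to
  input row order under a fixed seed.
- Model archives are versioned joblib payloads; loading a corrupted or
  version-mismatched archive raises instead of mispredicting.

## Test and acceptance scales

The simulation-based suites run at reduced sizes chosen as the package's
own verification scale: delay recovery on 40-infant cohorts over the delay
grid {0, 1.5, 3} weeks with 5 seeds; the zero-delay false-positive check
and the permutation-calibration check at 40 replicates with 199
permutations each; interval detection at 40 null and 20 power replicates
(30 infants, a smooth bump effect on weeks 2–6, detection threshold 0.1);
gap-statistic recovery over 20 seeded runs of six 15-point clusters with
B = 20 reference draws. Binomial bounds on rejection counts are the exact
95% critical values for the nominal 5% rate.

## Known limitations

- The SS-ANOVA-style interval analysis fits splines per group without
  covariates or explicit random effects; infant structure enters only
  through the permutation scheme.
- The cluster-association bootstrap is percentile-based and can be
  conservative for small infant counts.
- CSS's adaptive quantile heuristic is a simplified form of the published
  instability scan; the fixed 0.5 quantile is the default.
- Out-of-bag predictions are undefined for samples never left out; with
  very small cohorts and few trees those samples are dropped from the
  reference spline fit (a warning would surface via scikit-learn).
- The validation-cohort path (closed-reference mapping) aligns features and
  reports losses but no re-normalization beyond rarefaction is attempted.
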