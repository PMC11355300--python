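# Methods

## The problem and the pipeline

During a protracted second stage of labor, four geometric parameters can be
measured by transabdominal intrapartum ultrasound: the asynclitism degree
(AD, mm — lateral tilt of the fetal head), the angle of progression (AoP,
degrees — head descent relative to the pubic symphysis), the head-symphysis
distance (HSD, mm) and the midline angle (MLA, degrees — head rotation).
The AIDA (Artificial Intelligence Dystocia Algorithm) approach codes each
parameter into a traffic-light risk zone, counts the parameters outside the
green zone to obtain an AIDA class 0–4, and trains standard classifiers on
the raw parameters to predict the binary outcome: intrapartum cesarean
delivery (ICD, which includes cesarean after a failed vaginal attempt)
versus non-ICD (operative vaginal or spontaneous delivery).

The package implements the full analysis: zoning and class computation,
pairwise decision-tree cut-off derivation, a seeded 70–30 prediction
harness, Pearson correlation reporting, class-stratified NA-aware
evaluation, and a synthetic cohort generator. The original per-patient
cohort (135 patients from three hospitals) is not deposited; its published
summaries — descriptive statistics, correlation table, cut-off table,
per-class confusion matrices, and three per-patient prediction tables —
ship as packaged fixtures and anchor all exact tests.

## Zone scheme

Zones are half-open intervals `[lo, hi)`, so a red band is closed at its
lower threshold (`AD >= 70.5 mm -> RED`). Defaults:

| parameter | green | yellow | red |
|---|---|---|---|
| AD (mm) | [0, 65.5) | [65.5, 70.5) | [70.5, inf) |
| AoP (deg) | [101.5, 144.5) | — | [0, 101.5) and [144.5, inf) |
| HSD (mm) | [0, 19.5) | — | [19.5, inf) |
| MLA (deg) | [0, 65.5) | — | [65.5, inf) |

Only AD carries a published yellow (cut-off) band; the other parameters
default to two-zone schemes. The MLA red threshold is not published in this
cut-off family at all; the 65.5 deg default sits near the cohort's MLA mean
(62.6 deg) so that both zones are populated, and is meant to be overridden
via configuration (`default_zone_scheme(mla_red_threshold=...)` or a YAML
scheme) when a clinically validated value is available. Values outside the
observed study ranges (e.g. AD > 95 mm) are still zoned but logged as
extrapolation. The AIDA class is the count of non-green parameters; classes
1 and 2 follow the same counting rule even though the published analysis
covers only classes 0, 3 and 4.

## Cut-off derivation

The published thresholds (67 / 70.5 / 65.5 mm for AD, 101.5 / 144.5 deg for
AoP, 19.5 mm for HSD) came from shallow classification trees grown on one
parameter pair at a time. The procedure is implemented from first
principles because its conventions are the point: Gini impurity, candidate
thresholds at midpoints of consecutive distinct sorted values (hence the
`.5` endings), ties broken toward the smaller threshold (and, across
features, toward the first feature of the pair), depth limited to 2 (the
published AoP band rule needs exactly depth 2), minimum leaf size 1, no
pruning, majority leaf labels with ties to non-ICD. Growth is fully
deterministic. sklearn's CART is used in the test suite as an independent
cross-check, never as the implementation.

The published thresholds themselves cannot be re-derived without the raw
cohort; they ship as constants in the default zone scheme and in the
cut-off fixture, while the derivation is validated by parameter-recovery
tests on synthetic cohorts (a hard `AD >= 70 mm` rule is recovered to
within one inter-point gap at n = 135).

## Synthetic cohort generator

The generator emulates the study conditions, not any richer structure:

* **Geometry** is a Gaussian copula over (AD, AoP, HSD, MLA). Each marginal
  is a truncated normal on the published [min, max] whose latent
  location/scale are solved (moment matching via `scipy.stats.truncnorm`)
  so that the *realized* distribution has the published mean and SD — the
  published moments are sample statistics of bounded data. Latent pairwise
  correlations are solved by Gauss–Hermite quadrature (NORTA-style) so the
  realized Pearson correlations equal the configured ones (0.36 AD–AoP,
  0.18 AD–HSD, 0.14 AD–MLA; unpublished pairs default to 0) despite the
  attenuation of the monotone marginal transforms. The target matrix is
  repaired by eigenvalue clipping if a user configuration makes it
  indefinite.
* **Apgar scores** share the latent copula with AD (0.8 between the two
  scores, −0.2 / −0.19 with AD) and are rounded to integers and clipped to
  [0, 10]. Rounding attenuates the realized integer-scale correlation to
  roughly 0.76; the continuous pre-rounding scores
  (`sample_apgar(..., rounded=False)`) carry the configured 0.8 and are
  what the recovery checks measure.
* **Outcome** follows a logistic model in the AIDA class k:
  `logit P(ICD) = -3.89 + 2.49 k`. The intercept is `logit(0.02)` so class
  0 is almost always non-ICD; the slope was calibrated once against the
  default model's class distribution so the expected cohort-wide ICD
  fraction is ~0.578 (the published 78/135), which puts
  P(ICD | class 4) ≈ 0.998 — the gradient visible in the published
  per-class tables, where class 0 contains no ICD and class 4 only ICD.
  Positive draws split ICD : ICD-after-failure 56:22, negative draws OVD :
  spontaneous 31:26.
* **Asynclitism type** is anterior with probability 50/135; demographics
  are independent truncated normals with published means/SDs and plausible
  clinical bounds (bounds are not published).

Randomness uses named substreams (`geometry`, `apgar`, `outcome`,
`asynclitism`, `demographics`) of a single root seed, so adding a sampler
never perturbs existing streams and every draw is reproducible.

What the generator does **not** emulate: any dependence beyond pairwise
Pearson coefficients (no tail dependence, no interactions), measurement
error, within-hospital clustering, or the real relationship between
geometry and outcome beyond the class-gradient logistic. Tests that pass on
synthetic cohorts therefore validate the *machinery* (zoning, trees,
harness, metrics), not clinical performance on real patients; the only
clinical-performance claims reproduced are the published fixture tables.

## Prediction harness

`make_split_plan` partitions indices once per seed (default seeds 1, 0,
250, 500, 750), with the train size rounded half-up (95 of 135, leaving 40
for testing; five seeds give 200 predictions per learner). Splits are
simple random partitions without stratification. The learner
hyperparameters are deliberately small standard settings, all exposed:
RF 100 trees; SVM RBF, C = 1, gamma = "scale"; MLP one hidden layer of 8
units with the lbfgs solver (deterministic and reliable at n = 95, no
early stopping), iteration cap 1000; plus DT, LR and GBT variants. Kernel,
linear and neural learners see z-scored features with the scaler fitted on
the training fold only; tree learners see raw features. The harness seed
drives learner-internal randomness; the split-plan seeds label the
partitions. Exact reproduction of the original per-patient predictions is
not expected — the original tooling's seed-to-partition mapping is
proprietary — so exact evaluation claims are made only on the packaged
prediction tables.

Per-patient predictions are aggregated with repetition counts
(`n_predictions` = number of test sets drawing the patient); rows merge
only when every learner predicted identically in each repetition, matching
the layout of the published tables (where one patient can span two rows
with different MLP labels). Feature importances use impurity importance
for tree learners, absolute standardized coefficients for LR, and
permutation importance on held-out data for SVM/MLP.

## Evaluation

Confusion matrices take ICD as positive and, by default, expand rows by
their repetition counts (the published per-class totals 68/50/31 are
expanded counts). Metrics are computed as exact rationals
(`fractions.Fraction`) on the counts; a metric is NA exactly when its
denominator is zero, and F1 is NA when PPV or recall is NA or when they sum
to zero (this reproduces the published pattern where a row can have PPV
0.00 but F1 NA because recall is undefined). Comparison against the
published table rounds the exact value to each cell's printed precision
with half-up rounding; display rounding never feeds back into a
comparison. The full reproduction check rebuilds all nine
(class, algorithm) rows from the per-patient tables and matches counts
exactly and metrics at printed precision, including all 14 NA cells.

## Correlation reporting

Pearson coefficients come from `scipy.stats.pearsonr` (two-sided t-test
p-values, n − 2 degrees of freedom). Strength bands are half-open on |r|
(0.20 / 0.40 / 0.60 / 0.80 boundaries — so −0.20 is "weak" and −0.19 "very
weak", matching the published labels), and significance stars use strict
thresholds 0.05 / 0.01 / 0.001; an underflowed p = 0.0 is treated as below
every threshold.

## Numerical choices and limitations

* Interval membership and class counting are exact; the half-open
  convention makes every admissible value receive exactly one label.
* Tree tie-breaks (smaller threshold, earlier feature, non-ICD leaf) are
  fixed so derivation is reproducible; impurity comparisons use a 1e-12
  tolerance to avoid float noise reordering ties.
* Moment matching and latent-correlation solving are cached per marginal
  pair; quadrature uses a 64-node probabilists' Gauss–Hermite rule,
  accurate to well below the Monte-Carlo noise at n = 10,000.
* Problem sizes in the test suite: exact table reproduction uses the
  fixtures as-is; Monte-Carlo recovery checks use n = 10,000 draws;
  harness checks use the study-sized n = 135 with the five published
  seeds. These sizes keep every recovery check comfortably inside its
  tolerance while the whole suite runs in seconds.
* The package does not attempt ROC/AUC analysis, bootstrap intervals,
  image-based measurement of the parameters, or any re-derivation of the
  published thresholds and importance rankings — those depend on the
  unreleased raw cohort and are honored as configuration constants and
  structural checks.
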