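# Methods

This note documents the statistical model behind `cartsurv`, the synthetic
cohort generator and its calibration, the numerical choices, and the design
decisions taken where the procedure left room for interpretation.

## 1. Data model

A cohort is one row per patient: overall survival in months from CRCLM
resection (`os_months` > 0), a death indicator, five binary
clinicopathological risk factors (primary-tumor-to-metastasis interval
< 12 months, nodal positivity, metastasis diameter > 5 cm, multiple
metastases, serum CEA > 200 ng/ml), systemic-therapy and primary-site
labels, and per-marker ordinal IHC scores — intensity (negative/weak/
moderate/strong) and frequency (0–25 / 26–50 / 51–75 / 76–100% positive
cells) — for the metastasis and optionally the matched primary tumor.

Exclusion rules, applied before any survival analysis: unknown survival
(time or event) or survival < 2 months. Three-year analyses additionally
exclude patients censored before 36 months (their three-year label is
undefined); a death at exactly 36.0 months counts as died-within-36 (the
boundary direction is a package convention). Classifier analyses exclude
patients missing a required marker score on its selected channel.
"High" expression means score ≥ threshold with threshold ∈ {1, 2, 3};
cutpoints sit between adjacent ordinal categories, oriented so that high
expression of a risk marker carries the elevated hazard.

## 2. Screening: Monte-Carlo cross-validated cutoffs and HRRs

Each of `n_splits` (default 500) iterations draws a random train/validation
partition (2/3 vs 1/3, stratified on event status; the split fraction is a
package choice, configurable). On the training set the cutoff is chosen by
a time-dependent ROC analysis at the 36-month horizon: sensitivity and
specificity of "score ≥ c" for death by the horizon are estimated with
Kaplan-Meier survival inside the high/low groups,

    Sens(c) = (1 − S_hi(t)) p_hi / (1 − S(t)),
    Spec(c) = S_lo(t) (1 − p_hi) / S(t),    S = p_hi S_hi + (1 − p_hi) S_lo,

which reduces to the empirical fractions when there is no censoring. The
threshold maximizing **|J| = |Sens + Spec − 1|** wins (ties go to the lowest
threshold). The absolute value makes the criterion direction-agnostic:
protective markers (high expression anticipating longer survival — SLC2A1,
CEA, KCNQ1, HIF1A in the calibration tables) produce negative J on the
case-oriented ROC, and signed maximization would choose their cutoffs
essentially at random, badly attenuating their screening HRRs.

On the validation set the dichotomized marker enters a univariate Cox model
and a multivariate Cox model over the five clinical factors with stepwise
backward elimination (largest Wald p removed while p > .1; the marker is
never removed). Cox fits use an internal Newton-Raphson solver on the Efron
partial likelihood (tie correction active only at tied death times;
generated survival times are continuous). The solver is validated against
lifelines to ~1e-6 in the test suite and exists because the screening and
permutation loops perform tens of thousands of small fits.

Splits with a degenerate validation dichotomy (empty high or low group), no
validation events, or non-convergent fits (monotone likelihood/separation)
are dropped from numerator and denominator; their reasons are logged, and
fewer than 50% valid splits is an error. HRR_av is the arithmetic mean of
the valid validation HRRs (a literal average on the HRR scale). The
opposite-direction proportion is the fraction of valid splits whose HRR
lies on the other side of 1 from HRR_av (HRRs exactly 1 count in neither
direction). Per marker, the channel (intensity vs frequency) with larger
|log HRR_av| is kept; candidates are markers with opposite-direction
proportion ≤ .10 — a threshold consistent with the nine-marker candidate
set of the calibration tables (proportions ≤ .09 pass, ~.20 fail).

A property worth knowing: the opposite-direction proportion is a
*dataset-level* statistic. All Monte-Carlo splits of one finite cohort
share that cohort's realized chance association, so on null cohorts the
proportion does not concentrate at 0.5 — it spreads over roughly [0.1, 0.5]
across cohorts (median ≈ 0.37 at n = 1000 in our simulations) while still
essentially never crossing the ≤ .10 candidate threshold. More splits
reduce Monte-Carlo noise, not this dataset-level spread.

## 3. Tree construction and prognostic classes

The classifier is a CART tree over dichotomized candidate markers
predicting the binary three-year outcome. Growth is by Gini impurity with
minimum leaf size 10; zero-gain splits are admissible (an XOR-type
interaction has zero marginal gain; pruning removes unhelpful splits).
The weakest-link cost-complexity sequence is computed, each pruning level
is scored by stratified 10-fold cross-validated misclassification
(evaluated at midpoints between consecutive pruning alphas), and the level
with minimal CV error is selected, ties toward the smaller tree (not the
1-SE rule — "lowest misclassification rate" is read literally). Because
all features are binary, growth, pruning and CV operate on aggregated
feature-pattern count tables; scikit-learn's tree is the independent
oracle in the tests (identical training errors and selected partitions),
not the implementation — the pattern form is what makes the permutation
correction computationally feasible.

Leaf classes are labelled A, B, C, … by depth-first, low-branch-first
traversal. Per-class hazard ratios come from a Cox model with class
indicators, reference = the class with the highest Kaplan-Meier survival
at 36 months (ties: lexicographically first); classes without events are
reported non-estimable and omitted from grouping with a warning. Classes
with HRR < 2.0 join the reference in prognostic class I; HRR ≥ 2.0 forms
class II (equality goes to II; the boundary side is a package convention).
A one-sided grouping is flagged non-discriminative, and the pipeline then
reports no classifier HRR.

With the calibrated fig1 generator (below) the first split is AURKA and
the published A–D structure is recovered in ≥ 80% of cohorts at n = 1000;
the main alternative outcome is an AURKA→MMP9→PTGS2 split order, which
changes leaf identity but usually not the I/II partition, so the grouped
hazard ratio is robust to it.

## 4. Inference

Kaplan-Meier curves and the k-sample logrank test come from lifelines. The
classifier HRR is the Cox coefficient of class II vs I, crude or adjusted
(stepwise backward over the clinical factors, class term forced).
Model comparison against the clinicopathological model is an analysis of
deviance between nested Cox fits — clinical-only vs clinical + classifier —
with chi-square = difference in −2 log partial likelihood; the added
degrees of freedom are computed from the design ranks, so a collinear
classifier column yields df = 0 and a degeneracy flag.

**Permutation correction.** The outcome pair (time, event) is permuted
jointly across patients, covariate and marker columns fixed — this
preserves the marker/covariate dependence structure. For each of `n_perm`
(default 10000) permutations the full construction is re-run: three-year
labelling, CART growth and CV pruning, class HRRs, grouping, logrank of II
vs I. The corrected p-value is the literal fraction of permuted
uncorrected p-values smaller than the original (the add-one variant
(c+1)/(B+1) is reported alongside). Screening cutoffs are *not*
re-optimized inside permutations by default: re-running 500-split
screening inside 10000 permutations is computationally disproportionate,
and the selection step being corrected is the tree construction.

For the permutation distribution to be exchangeable the construction must
yield a statistic from every dataset, observed or permuted. Two fallbacks
guarantee this: if CV pruning selects the bare root, the best non-trivial
pruned subtree is used instead; if the ≥ 2.0 grouping is one-sided, the
class with the highest estimable HRR is split off against the rest (with
the lowest-HRR class as reference). Both fallbacks apply identically to
observed and permuted datasets. Datasets with no admissible classifier at
all (a single class, or no events) contribute p = 1, a conservative
convention. Under this construction the corrected p-value is empirically
uniform on null cohorts (Kolmogorov-Smirnov test in the acceptance suite);
without the fallbacks the atom of degenerate constructions at p = 1
destroys uniformity, which is why "degenerate ⇒ p = 1" alone is not a
viable rule for the observed side.

**Subgroups.** The classifier is applied as fitted (no refit) within
systemic-therapy and primary-site strata; per-stratum HRRs require ≥ 2
events per group, and the corrected p is obtained by re-running the
permutation machinery within the stratum — a package assumption, since the
within-stratum permutation scheme is not otherwise determined.

## 5. Primary-tumor transfer

Pearson correlations (ordinal scores treated as numeric 0–3, the
field-standard convention for these tables) are computed over complete
matched pairs on each marker's screening-selected channel; < 3 pairs
leaves the p-value undefined. Markers whose pair correlation is
non-positive or non-significant (p ≥ .05) do not transfer: their splits
are collapsed (children merged; leaf classes separated only by the pruned
marker coalesce, e.g. B∪C when MMP9 is removed from the published tree).
The remaining classes are re-grouped by HRRs re-estimated on the
metastasis outcomes, and the reduced classifier is applied to dichotomized
primary-tumor scores. When the re-grouping boundary coincides with a
single marker split the reduced rule is reported as such — on the
calibrated matched profile, omitting MMP9 yields "class II iff AURKA
high", the single-marker reduction.

## 6. Synthetic cohorts and calibration

The generator emulates the statistical structure the analysis assumes:

* **Scores.** Per marker, a 4-dimensional Gaussian latent (intensity and
  frequency × metastasis and primary) with Kronecker covariance: channel
  correlation 0.5 within a lesion, per-marker pair correlation ρ between
  lesions, product across both. Thresholding at the quantiles of the
  category probabilities yields the ordinal scores. Marginal category
  probabilities are not empirically known and default to the uniform-ish
  (.2, .3, .3, .2) — an explicitly arbitrary choice giving P(high) = 0.5
  at the default true cutoff of 2.
* **Survival.** Exponential baseline hazard (the Cox machinery is
  baseline-agnostic; constant hazard is the simplest proportional-hazards
  truth) times exp(linear predictor) from dichotomized marker effects,
  clinical-factor effects, and/or a tree-class term. Independent
  exponential censoring plus an administrative cap at 120 months.
  Defaults (baseline 0.012/month, censoring 0.004/month) give a five-year
  survival near 40% and ~50% three-year death, matching the motivating
  cohort's survival level.
* **Missingness.** Per-channel missing-completely-at-random dropout
  (default 5% in the marker-effect profile); the source study reports
  exclusions but no missingness mechanism.
* **Copula calibration.** `implied_ordinal_correlation(ρ, probs)` computes
  the Pearson correlation of the thresholded ordinal pair from bivariate
  normal rectangle probabilities; `calibrate_pair_correlation` inverts it
  by root bracketing, so a target *ordinal-scale* r (what correlation
  tables report) can be specified directly.

Two calibration profiles encode published effect sizes as generative
truth:

* **paper2015** — the nine prognostically relevant markers carry log-HRR
  equal to the log of their published multivariate HRR_av (AURKA 1.66,
  PTGS2 1.59, EGFR 1.54, VEGFA 1.50, MMP9 1.34, KCNQ1 0.81, HIF1A 0.77,
  SLC2A1 0.65, CEA 0.63); the other nine markers are inert. Clinical
  factors carry modest hazards (1.3–1.7). The matched variant calibrates
  each marker's latent ρ to the published ordinal pair correlations
  (AURKA 0.34, MMP9 −0.04, …). Screening recovery is attenuated ~5–10%
  toward 1 by cutoff-selection noise and by non-collapsibility across the
  other marker effects — an inherent property of the estimand, inside the
  ±20% recovery band the acceptance checks use.
* **fig1** — hazards driven by the tree-class structure (AURKA high →
  PTGS2 / MMP9 branch): class II (C ∪ D) carries log 2.79 in the
  unadjusted variant; the adjusted variant uses the conditional effect
  log 3.57 with active, independent clinical confounders and a baseline
  lowered to 0.0055/month so the overall three-year death fraction stays
  near one half (the active clinical effects multiply the average hazard
  ~2.2×, and without compensation every tree node's death rate exceeds ½,
  making misclassification-based pruning degenerate). High-expression
  prevalences: AURKA 0.55, PTGS2 0.50, MMP9 0.35, chosen to keep all four
  classes populated and the AURKA→PTGS2→MMP9 Gini ordering identifiable.
* **fig1, matched** — adds primary-tumor scores and a primary-AURKA hazard
  term for the transfer analysis: class effect ln 2.4, primary-AURKA
  effect ln 2.0, AURKA latent ρ 0.7, PTGS2 ρ 0.25, MMP9 ρ 0 (uncorrelated,
  so the correlation screen removes it), MMP9 high-prevalence 0.75. These
  constants were derived from the hazard-mixture algebra so that (i) the
  generative primary-score AURKA hazard ratio sits at ≈ 2.6, and (ii) the
  merged B∪C class re-estimates above the 2.0 grouping threshold after the
  MMP9 collapse, which is what reduces the grouping to the AURKA-only
  rule.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: tissue-core sampling and staining
variability, inter-observer scoring disagreement, non-proportional or
time-varying hazards, informative censoring or missingness, and real
inter-marker biological correlation (markers are independent given the
class structure). Recovery results on these cohorts validate the
machinery, not the biology.

## 7. Numerical choices and reproducibility

* Newton Cox solver: step-halving line search, convergence at max |Δβ| <
  1e-10, |β| > 15 flagged as separation, ridge fallback on a singular
  information matrix. Two-group fits are cross-checked in the tests
  against an independent Brent-root solution of the score equation
  (agreement < 1e-8 on the HRR scale) and against lifelines.
* Tree tie-breaks: equal Gini gain → lowest feature index; equal CV error
  → larger pruning alpha (smaller tree); majority ties in a leaf predict
  survival.
* Seeds: a single master seed spawns named substreams (per screening
  split, per permutation, per pipeline stage) via `numpy` SeedSequence, so
  any split or permutation is reproducible in isolation and results are
  byte-identical across runs of the same configuration; every pipeline
  artifact carries a hash of the configuration (output paths excluded).
* Simulation sizes in the test suite are the package's own choices, scaled
  to keep the default run at a few minutes: e.g. logrank null calibration
  uses 500 replicates of n = 200, screening-recovery checks average five
  n = 500 cohorts of 500 splits each (one such cohort has ~15%
  dataset-level spread in realized effects; averaging checks recovery
  rather than single-cohort noise), and the permutation-uniformity check
  uses 200 null datasets × 200 permutations at n = 300.

## 8. Known limitations

* The reported HRRs are not corrected for selection optimism (only the
  p-values are); they can be somewhat overestimated by construction.
* Marginal screening ahead of tree building can drop interaction-only
  markers (MMP9's marginal effect is weak when its risk contribution is
  confined to one branch); this is a faithful property of the procedure,
  not an implementation artifact.
* The CART consumes dichotomized scores (consistent with cutoff screening
  feeding it); ordinal-input trees are not implemented.
* No surrogate splits: a patient missing a marker queried on their path is
  excluded rather than rerouted.
* The strict-mode permutation (`strict_scores` / `permtest --strict`)
  re-optimizes each marker's ROC cutoff on every permuted dataset before
  rebuilding the tree; it does not repeat the full 500-split Monte-Carlo
  screen per permutation, which would be computationally disproportionate
  to its effect on the null. Strict mode is intended for reduced `n_perm`.
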