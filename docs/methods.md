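# Methods

This note documents the models, algorithms and design choices behind
`ieto-automl`, the parameters that matter, and what the synthetic-data
experiments do and do not establish.

## Problem setting

The package targets binary risk prediction of *healthcare-seeking delay* —
an interval longer than 14 days between symptom onset and first professional
medical contact — from an 18-variable tabular survey schema: demographics
(age, gender, education, occupation), socioeconomics (Chinese communication,
financial difficulty), healthcare accessibility (distances in km to village
clinic, township health center, county hospital), clinical history (chronic
disease, self-rated severity, two 0–10 facility quality ratings) and five
binary symptom domains. The record-level survey data behind the published
study (1,879 residents of Tibetan regions, 41.99% delayed) are not public;
the package therefore ships a synthetic-cohort generator that reproduces the
published marginal structure and plants a known risk mechanism, so that
every downstream stage can be validated by parameter recovery.

## The IETO meta-optimizer

All optimizers minimize a scalar objective over a box, clip to the box, and
keep a monotone best-so-far trajectory (elitism). The Improved
Exponential-Trigonometric Optimization (IETO) algorithm extends the ETO
baseline with three devices:

1. **Logistic-chaotic initialization.** Each (individual, dimension) cell
   runs an independent chain of the fully chaotic logistic map
   `x ← 4x(1−x)`, seeded uniformly away from the map's fixed points and
   burned in for 30 steps, then mapped affinely onto the box. The r=4
   regime has the arcsine (Beta(1/2,1/2)) invariant density, verified by a
   Kolmogorov–Smirnov test in the suite.
2. **Spiral exploration + Cauchy mutation.** With probability
   `p(t) = 1 − t/T` (the adaptive schedule, linear by design) an individual
   takes a logarithmic-spiral step around the incumbent best,
   `x' = |best − x| · e^{bl} · cos(2πl) + best` with `l ~ U(−1,1)` drawn
   *per coordinate* (a shared scalar `l` collapses whole individuals onto
   the best whenever `cos(2πl) ≈ 0` and drains population diversity — with
   the scalar variant the improved algorithm loses its edge over the
   baseline); otherwise it takes the exponential-trigonometric local step.
   After each generation the incumbent best is perturbed once by a
   heavy-tailed Cauchy mutation with scale `0.1→0.01` of the box range
   (linear decay), accepted greedily so elitism survives.
3. **Greedy selection everywhere.** A move is kept only if it improves the
   individual's fitness; non-finite objective values are mapped to +inf and
   never become the incumbent.

The ETO baseline used for comparison is a documented exponential-decay
sine/cosine update, `x' = x + 2e^{−4t/T} · trig(r₁) · |r₂·best − x|`, with
the same greedy selection — the original publication's exact update
equations were not available, so the baseline is a faithful member of the
exponential-trigonometric family rather than a bit-exact replica. WOA and
PSO comparators use their standard textbook parameterizations (WOA with
`a: 2→0`; PSO with `w = 0.729`, `c₁ = c₂ = 1.49445`, velocity clamped to
half the range).

**Benchmark suite.** The comparison experiment runs on 12 analytic
shifted/rotated functions (sphere, Rastrigin, Rosenbrock, Ackley, Griewank,
rotated hyper-ellipsoid, Levy, Zakharov, four hybrid sums) on
`[−100,100]^D` with seeded shifts in the central 60% of the box and seeded
random orthogonal rotations. This is a *stand-in* with the same comparative
logic as competition suites: every function's optimum is known in closed
form and no external data files are needed. Absolute fitness values are not
comparable to any published competition numbers. The default experiment is
scaled down (D=10, population 30, 200 iterations, 10 seeded repeats; the
full 500-iteration, 30-repeat protocol is behind `--full`), sized so the
comparison completes in seconds on one CPU while leaving the IETO-vs-ETO
median ordering stable across base seeds.

## Search-space encoding

A solution is a 0–1 vector with three segments: one bit per candidate
feature, a 3-bit learner selector (modulo-5 wrap over
{LR, KNN, AdaBoost, XGBoost, LightGBM}; three learners receive 2/8 of the
selector mass instead of 1/8 — accepted for the simplicity of a total
mapping), and a shared hyperparameter field sized for the largest learner
(24 bits). Scalar hyperparameters use 8-bit fixed-point fractions
`f = int/(2^8−1)` mapped onto their published ranges — log10-linearly for
the regularization strength `C ∈ [10⁻³, 10³]` — giving ~0.4%-of-range
resolution; integers round half-away-from-zero; categoricals use minimal
bit width with modulo indexing. An all-zero feature mask is repaired to the
single feature with the highest univariate training AUC. The continuous
optimizer runs on `[−4, 4]^L` and positions are binarized through a
stochastic sigmoid transfer.

## AutoML loop

Fitness is `1 − mean 5-fold stratified CV ROC-AUC` on the training set.
Folds are fixed once per search, so fitness is a pure function of the bit
vector; a byte-keyed cache enforces that and avoids refits. A learner that
fails on a fold scores the uninformative 0.5 for that fold (scoring 0 would
teach the search to avoid whole regions for the wrong reason). The winning
solution is refit on the full training set. During the search the boosted
learners' tree counts can be capped (`boosting_estimator_cap`) — a budget
control for the search phase only; the final refit uses the decoded values.
Baseline comparators are fitted with library defaults on all features, since
no settings are published for them. The evaluator is constructed from
training data only; nothing in the search path can touch a test set.

## Evaluation

Point metrics follow the confusion-matrix definitions with classification
at probability 0.5 (no threshold is published); zero denominators are
flagged rather than silently NaN. ROC-AUC is the Mann–Whitney pair-ordering
probability with ties credited one half; PR-AUC is average precision.
Decision-curve analysis reports `NB(t) = TP/n − FP/n · t/(1−t)` on the
0.01–0.99 grid against treat-all (`π − (1−π)t/(1−t)`) and treat-none (0)
references. Fold-averaged reports note that the averaged F1 need not equal
the harmonic mean of averaged precision and sensitivity exactly (Jensen
gap); on balanced, well-powered data the gap is below 10⁻³.

## Shapley interpretation

Attributions satisfy local accuracy: per sample, base value plus
contributions equals the model's margin (log-odds for tree models and
linear models; probability for models without a margin). Three routes:

- **LightGBM / XGBoost:** native tree-path contribution algorithms
  (`pred_contrib` / `pred_contribs`), exact in margin space.
- **Exact interventional enumeration** (any model, ≤12 features): the value
  function `v(S)` is the background-averaged prediction with features in S
  fixed to the explained sample; attributions use the exact Shapley weights
  over all 2^p subsets. On enumerable toy trees this path is checked against
  a from-scratch coalitional (permutation) oracle — the module's hard
  correctness anchor.
- **Monte-Carlo permutation averaging** (larger p): marginal contributions
  along seeded random permutations; additivity is preserved *exactly*
  because each permutation's contributions telescope.

Interaction tensors are symmetric with diagonals defined so each row sums
to the feature's attribution; XGBoost uses its native path-dependent
interactions (symmetrized against float32 noise), other tree models use
exact interventional enumeration of the Shapley interaction index (feature
count capped at 12). Non-tree models raise an explicit unsupported error.

The audit side mirrors the published comparison: mean-|SHAP| ranking vs the
model's intrinsic importance and an L1-regularized logistic (LASSO)
reference with penalty chosen by 5-fold CV deviance on standardized
columns, summarized by Cohen's κ on top-k membership indicators over the
full feature universe (k = 5; the published analysis never defines its κ,
so top-k membership is the documented choice).

## Preprocessing

8:2 random split with `|train| = floor(0.8·n)` (simple random by default;
outcome-stratified behind a flag — the published split is not described as
stratified). "Outlier rectification" is Tukey-fence winsorization
(`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`) with fences learned on training data only
— rectification (correction) rather than removal matches a cohort size that
never changes. One-hot encoding learns its vocabulary on training data;
binary variables stay single columns; unseen categories at apply time
encode as all-zero with a warning. Missing values are completed by
MissForest-style iterative random-forest imputation (median/mode
initialization, variables cycled by ascending missingness, stop when the
change criterion stops decreasing or after 10 sweeps), repeated over m=5
seeds and pooled per cell (mean/mode) into the single completed table the
pipeline consumes. The imputation forests use 50 trees with a 5-sample leaf
floor: with largely uninformative predictors an unregularized forest chases
noise and loses to a median fill, which defeats the purpose.

## Cohort statistics

Continuous variables: pooled-variance (Student) two-sample t-test —
verified to reproduce the published age comparison (t = 1.057) where the
Welch variant gives ≈ 0.98. Categorical variables: Pearson chi-square on
2×2 counts *without* continuity correction — the corrected gender statistic
would be ≈ 0.86 against the published 0.977. Entry points accept printed
summaries (mean/SD/n, 2×2 counts) directly, so published baseline tables
can be reproduced without record-level data.

## Synthetic-cohort generator

Continuous variables are truncated normals at the pooled published
moments (age 48.38 ± 11.45 on [25, 72]; distances 1.07 ± 0.27,
4.05 ± 1.22, 21.60 ± 5.90 km, positive; quality scores 8.1 ± 2.4 and
9.2 ± 3.0 on [0, 10] — the county score is heavily right-truncated, so its
realized mean sits below the nominal value, consistent with a skewed
bounded rating). Binary variables are Bernoulli at the pooled published
proportions; the one symptom domain without a published row
(`other_symptoms`) is a synthetic choice at 0.15. The outcome is Bernoulli
through a logistic link on z-scored covariates with planted standardized
coefficients

    age +1.0 · county_quality −0.7 · dist_county +0.55 ·
    chinese_communication −0.5 · township_quality −0.35 ·
    background ±0.1 (symptom domains ±0.05)

and the intercept calibrated by bisection so the expected prevalence equals
41.99%. The binary Chinese-communication indicator deliberately carries a
larger coefficient than the continuous township quality score: binary
features pay a discreteness penalty in tree-model importance (one split
point versus many), and with the magnitudes swapped the planted top-5 set
is not reliably recoverable. The published study itself orders these two
features inconsistently between its importance figure and its comparison
table, so either assignment is equally faithful; recovery experiments
target the top-5 *set*. Covariates are independent by default; an optional
Gaussian-copula mode correlates age with chronic disease (+0.3) and each
distance with its facility quality (−0.3), with binary indicators taken
from the upper latent tail so correlation signs survive dichotomization.

MCAR missingness injection masks covariate cells at 3.2% overall with a 5%
per-variable cap; the outcome is never masked.

**What the generator does not emulate:** the real survey's covariance
structure (unknowable from published marginals), nonresponse, measurement
error, and any nonlinearity or interaction in the true delay mechanism.
Passing recovery tests therefore show the pipeline can find planted
log-linear signal at realistic sizes and prevalence — not that it would
reproduce the published real-data AUCs (0.9563 train / 0.9196 test), which
are out of reach without the survey data.

## Problem sizes and numerical choices

- Optimizer comparison: D=10, population 30, 200 iterations, 10 repeats —
  the scaled-down default; the improved-vs-baseline median ordering (at
  least 8 of 12 functions) is stable across base seeds at this size.
- Recovery experiments: cohorts of n=1,000–2,000, search population 8,
  10 iterations, boosted learners capped at 60 trees during the search.
  These sizes keep a 10-seed experiment in minutes while leaving a ≥4/5
  feature-recovery margin.
- A known statistical caveat: a baseline table over 18 covariates on a
  random split of a single cohort is 18 simultaneous true-null tests, so at
  least one p < 0.05 appears in roughly 60% of splits (1 − 0.95¹⁸). The
  published baseline table, where all rows exceed 0.05 with a minimum of
  0.052, is a single draw, not a reproducible property; the per-split
  property that *is* stable is that ≥90% of variables are non-significant.
- Risk bands in the decision-support interface (<0.3 / 0.3–0.6 / >0.6) are
  an interface convenience with no clinical calibration claimed.
- Seeds flow top-down: every public entry point takes a seed and derives
  all internal generators from it; identical seeds give bit-identical
  outputs.

## Known limitations

- The ETO baseline is a documented family member, not the original
  publication's exact equations; comparative results characterize this
  implementation.
- Exact interventional Shapley costs O(2^p · |background|) predictions per
  sample and is capped at 12 features; beyond that the permutation
  estimator's attributions carry Monte-Carlo noise (additivity still
  exact).
- The LASSO reference reports standardized coefficients from one CV-chosen
  penalty; no stability selection across resamples.
- Interaction enumeration for non-XGBoost trees shares its value table
  with the attribution path, so the row-sum identity is a construction for
  the diagonal and an independent check only against the native XGBoost
  route.
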