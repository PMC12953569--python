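# ieto-automl

Metaheuristic-driven AutoML for tabular clinical risk prediction, built
around the problem of **healthcare-seeking delay** — whether a patient
waits more than 14 days between symptom onset and first professional
medical contact. The motivating application is delay risk among residents
of Tibetan regions, where geography (distances to village clinic, township
health center and county hospital), language (ability to communicate in
Chinese), and perceived facility quality jointly shape care-seeking; the
toolkit is generic for any cohort following the 18-variable survey schema.

## What it does

At the core is **IETO** (Improved Exponential-Trigonometric Optimization),
a population metaheuristic extending the exponential-trigonometric family
with logistic-chaotic initialization, a spiral-exploration + Cauchy-mutation
balanced search, and an adaptive linear exploration schedule. IETO drives a
**sequential-cooperative AutoML loop**: it proposes 0–1 encoded solutions
`[feature mask | learner selector | hyperparameter bits]`, the pipeline
decodes each into a concrete model over {LR, KNN, AdaBoost, XGBoost,
LightGBM} with its hyperparameters, scores it by 5-fold stratified
cross-validated ROC-AUC on the training set, and feeds `1 − AUC` back as
minimization fitness:

    maximize   AUC_cv(S, m, θ)   over  S ⊆ features, m ∈ pool, θ ∈ Θ_m

Around the search the package provides:

- preprocessing (8:2 split, Tukey-fence winsorization, one-hot encoding,
  MissForest-style random-forest multiple imputation),
- evaluation (PRE/SEN/SPE/ACC/F1, ROC-AUC, PR-AUC, decision-curve analysis
  with treat-all/treat-none references),
- Shapley interpretation with the additivity guarantee (native tree-path
  contributions for gradient boosters; exact interventional enumeration
  otherwise), interaction tensors, a LASSO audit and top-k ranking
  concordance (Cohen's κ),
- baseline cohort statistics (pooled t-tests, Pearson χ² without
  continuity correction) that reproduce published baseline tables from
  their printed summaries,
- a synthetic-cohort generator with the published marginal structure and a
  plantable logistic risk mechanism, so the whole pipeline is testable
  without the (undeposited) survey data,
- a CLI (`ieto-automl`) with `simulate`, `preprocess`, `benchmark`,
  `search`, `evaluate`, `explain`, `cohort-stats` and `predict`
  subcommands, including single-patient risk computation from the five key
  predictors.

## Worked example

```python
from ieto_automl import automl, metrics, preprocess, schema, simulate
from ieto_automl import explain as interpretation

cohort = simulate.generate(simulate.GeneratorConfig(n=1879, seed=7))
split = preprocess.split(cohort.table, seed=7)                 # 1503 / 376

model = preprocess.PreprocessModel().fit(split.train)
X_train, names = model.transform(split.train)
y_train = split.train[schema.OUTCOME].to_numpy()

config = automl.SearchConfig(population_size=10, iterations=12, seed=7,
                             boosting_estimator_cap=60)
result = automl.search(X_train, y_train, names, config)
bundle = automl.fit_final(result.best_solution, X_train, y_train, names,
                          seed=7, preprocess=model)

X_test, _ = model.transform(split.test)
y_test = split.test[schema.OUTCOME].to_numpy()
report = metrics.report_from_scores(bundle.predict_proba(X_test), y_test)
attr = interpretation.shap_attributions(bundle, X_test, seed=7)
print(interpretation.global_importance(attr).top(5))
```

With these (deliberately small) search budgets the run prints:

```
prevalence: 0.422
split: 1503 376
best learner: LR
best CV AUC: 0.8314
test ROC-AUC: 0.8021 PR-AUC: 0.7631
top-5 importance: ['age', 'county_quality', 'dist_county',
                   'chinese_communication', 'chronic_disease']
```

The generated cohort has the configured 42% delay prevalence; the search
selects a model whose cross-validated AUC (0.83) transfers to held-out
records (0.80), and the Shapley ranking recovers four of the five planted
top predictors (age, county hospital quality, distance to county hospital,
Chinese communication) — at larger search budgets and cohort sizes the
full planted set is recovered in the large majority of seeds (see the test
suite).

Single-patient risk from the command line, given a fitted bundle trained on
the five key features:

```sh
ieto-automl predict --model run/model.joblib \
    --age 63 --county-quality 4.5 --dist-county 38 \
    --township-quality 5 --no-chinese
```

which prints a JSON risk report: probability, band (low/moderate/high) and
the signed per-feature attributions that sum, with the base value, to the
model's margin output.

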