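"""Sequential-cooperative AutoML loop driven by the IETO metaheuristic.

The optimizer proposes continuous positions that are binarized into
(feature mask, learner, hyperparameters) solutions; each solution is scored
by 5-fold stratified cross-validated ROC-AUC on the training set (folds
fixed per search, solutions cached by bit pattern), and 1 - AUC is fed back
as the minimization fitness. The winning solution is refit on the full
training set into a serializable ``ModelBundle``.

The evaluator never sees the test set; final generalization is measured
separately by the evaluation module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from ieto_automl import codec, metrics
from ieto_automl.codec import DecodedSolution, EncodingLayout, LearnerSpec
from ieto_automl.optimize import Bounds, OptimizerSettings, binarize, run_optimizer

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "FitnessEvaluator",
    "AutoMLResult",
    "ModelBundle",
    "build_estimator",
    "cv_auc",
    "search",
    "fit_final",
    "baseline_comparators",
]


def predict_proba_1(model, X: np.ndarray) -> np.ndarray:
    """Positive-class probabilities, silencing the spurious feature-name check."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        return np.asarray(model.predict_proba(X), dtype=float)[:, 1]


@dataclass(frozen=True)
class SearchConfig:
    """Search-budget and reproducibility knobs for one AutoML run."""

    population_size: int = 30
    iterations: int = 50
    seed: int = 0
    cv_folds: int = 5
    position_bound: float = 4.0  # box half-width of the continuous encoding
    boosting_estimator_cap: int | None = None  # cap n_estimators during search


def build_estimator(solution: DecodedSolution, seed: int = 0,
                    boosting_cap: int | None = None):
    """Instantiate the decoded learner with its decoded hyperparameters."""
    hp = dict(solution.hyperparams)
    if solution.learner == "LR":
        return LogisticRegression(
            C=hp["C"],
            l1_ratio=1.0 if hp["penalty"] == "l1" else 0.0,
            solver="liblinear",
            max_iter=500,
            random_state=seed,
        )
    if solution.learner == "KNN":
        return KNeighborsClassifier(n_neighbors=hp["n_neighbors"], weights=hp["weights"])
    if solution.learner == "AdaBoost":
        n = hp["n_estimators"]
        if boosting_cap:
            n = min(n, boosting_cap)
        return AdaBoostClassifier(
            n_estimators=n, learning_rate=hp["learning_rate"], random_state=seed
        )
    if solution.learner == "XGBoost":
        from xgboost import XGBClassifier

        n = hp["n_estimators"]
        if boosting_cap:
            n = min(n, boosting_cap)
        return XGBClassifier(
            max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"],
            n_estimators=n,
            tree_method="hist",
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
            random_state=seed,
        )
    if solution.learner == "LightGBM":
        from lightgbm import LGBMClassifier

        n = 100
        if boosting_cap:
            n = min(n, boosting_cap)
        return LGBMClassifier(
            num_leaves=hp["num_leaves"],
            learning_rate=hp["learning_rate"],
            feature_fraction=hp["feature_fraction"],
            n_estimators=n,
            n_jobs=1,
            verbosity=-1,
            random_state=seed,
        )
    raise ValueError(f"unknown learner {solution.learner!r}")


class FitnessEvaluator:
    """Caches bit-vector fitness over fixed stratified folds.

    Within one search the fold assignment never changes, so the fitness is a
    pure function of the bit vector; the cache enforces that and saves
    repeated model fits.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        layout: EncodingLayout,
        pool: Sequence[LearnerSpec],
        seed: int = 0,
        cv_folds: int = 5,
        boosting_cap: int | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        self.layout = layout
        self.pool = tuple(pool)
        self.seed = seed
        self.boosting_cap = boosting_cap
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        self.folds = list(skf.split(self.X, self.y))
        self.cache: dict[bytes, float] = {}
        self.fallback_feature = self._best_univariate_feature()
        self.evaluations = 0

    def _best_univariate_feature(self) -> int:
        aucs = []
        for j in range(self.X.shape[1]):
            col = self.X[:, j]
            try:
                a = metrics.roc_auc(col, self.y)
            except ValueError:
                a = 0.5
            aucs.append(max(a, 1.0 - a))
        return int(np.argmax(aucs))

    def decode_bits(self, bits: np.ndarray) -> DecodedSolution:
        return codec.decode(bits, self.layout, self.pool, self.fallback_feature)

    def cv_auc_bits(self, bits: np.ndarray) -> float:
        key = np.asarray(bits, dtype=np.int64).tobytes()
        if key in self.cache:
            return self.cache[key]
        value = cv_auc(self.decode_bits(bits), self)
        self.cache[key] = value
        return value


def cv_auc(solution: DecodedSolution, evaluator: FitnessEvaluator) -> float:
    """Mean held-out ROC-AUC over the evaluator's fixed stratified folds.

    A learner that fails to fit on a fold contributes the uninformative 0.5
    (logged), so the search continues rather than avoiding the region.
    """
    mask = np.asarray(solution.feature_mask, dtype=bool)
    X = evaluator.X[:, mask]
    y = evaluator.y
    fold_aucs = []
    for tr, va in evaluator.folds:
        try:
            model = build_estimator(solution, seed=evaluator.seed,
                                    boosting_cap=evaluator.boosting_cap)
            model.fit(X[tr], y[tr])
            scores = predict_proba_1(model, X[va])
            fold_aucs.append(metrics.roc_auc(scores, y[va]))
        except Exception as exc:
            logger.warning("fold fit failed for %s: %r; scoring 0.5", solution.learner, exc)
            fold_aucs.append(0.5)
    evaluator.evaluations += 1
    return float(np.mean(fold_aucs))


@dataclass
class AutoMLResult:
    best_solution: DecodedSolution
    best_cv_auc: float
    history: pd.DataFrame  # iteration, best fitness (1 - AUC), mean fitness
    selected_features: list[str]
    evaluator: FitnessEvaluator = field(repr=False, default=None)
    optimum: object = field(repr=False, default=None)


def search(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    config: SearchConfig = SearchConfig(),
    pool: Sequence[LearnerSpec] | None = None,
) -> AutoMLResult:
    """Run the IETO-driven joint search over features, learner and hyperparameters."""
    pool = tuple(pool) if pool is not None else codec.default_pool()
    X = np.asarray(X, dtype=float)
    layout = codec.make_layout(X.shape[1], pool)
    evaluator = FitnessEvaluator(
        X, y, layout, pool, seed=config.seed, cv_folds=config.cv_folds,
        boosting_cap=config.boosting_estimator_cap,
    )
    transfer_rng = np.random.default_rng(config.seed + 1)
    best: dict = {"bits": None, "auc": -np.inf}

    def objective(position: np.ndarray) -> float:
        bits = binarize(position, transfer_rng)
        auc = evaluator.cv_auc_bits(bits)
        if auc > best["auc"]:
            best["bits"], best["auc"] = bits.copy(), auc
        return 1.0 - auc

    bounds = Bounds.cube(-config.position_bound, config.position_bound, layout.total_bits)
    settings = OptimizerSettings(
        algorithm="ieto",
        population_size=config.population_size,
        max_iterations=config.iterations,
        seed=config.seed,
    )
    optimum = run_optimizer(objective, bounds, settings)
    solution = evaluator.decode_bits(best["bits"])
    mask = np.asarray(solution.feature_mask, dtype=bool)
    history = pd.DataFrame(optimum.trajectory.to_records())
    return AutoMLResult(
        best_solution=solution,
        best_cv_auc=float(best["auc"]),
        history=history,
        selected_features=[n for n, m in zip(feature_names, mask) if m],
        evaluator=evaluator,
        optimum=optimum,
    )


@dataclass
class ModelBundle:
    """Fitted final model plus everything needed to apply and explain it."""

    estimator: object
    feature_mask: np.ndarray
    feature_names: list[str]
    preprocess: object = None  # optional fitted PreprocessModel
    background: np.ndarray | None = None  # masked-feature training sample for attribution
    version: str = "1"

    @property
    def selected_features(self) -> list[str]:
        return [n for n, m in zip(self.feature_names, self.feature_mask) if m]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = predict_proba_1(self.estimator, X[:, self.feature_mask])
        return np.clip(p, 0.0, 1.0)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        return joblib.load(path)


def fit_final(
    solution: DecodedSolution,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    seed: int = 0,
    preprocess: object = None,
    background_size: int = 100,
) -> ModelBundle:
    """Refit the winning learner on the full training set with masked features."""
    X = np.asarray(X, dtype=float)
    mask = np.asarray(solution.feature_mask, dtype=bool)
    estimator = build_estimator(solution, seed=seed)
    estimator.fit(X[:, mask], np.asarray(y).astype(int))  # fit failure propagates
    rng = np.random.default_rng(seed)
    sub = rng.choice(X.shape[0], size=min(background_size, X.shape[0]), replace=False)
    return ModelBundle(
        estimator=estimator,
        feature_mask=mask,
        feature_names=list(feature_names),
        preprocess=preprocess,
        background=X[np.sort(sub)][:, mask],
    )


_DEFAULT_COMPARATORS = ("LR", "KNN", "AdaBoost", "XGBoost", "LightGBM")


def _default_estimator(name: str, seed: int):
    if name == "LR":
        return LogisticRegression(max_iter=500, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "SVM":
        from sklearn.svm import SVC

        return SVC(probability=True, random_state=seed)
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed)
    if name == "XGBoost":
        from xgboost import XGBClassifier

        return XGBClassifier(n_jobs=1, verbosity=0, eval_metric="logloss", random_state=seed)
    if name == "LightGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(n_jobs=1, verbosity=-1, random_state=seed)
    raise ValueError(f"unknown comparator {name!r}")


def baseline_comparators(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    automl_bundle: ModelBundle | None = None,
    comparators: Sequence[str] = _DEFAULT_COMPARATORS,
    seed: int = 0,
) -> pd.DataFrame:
    """Library-default comparators on all features, evaluated on the test set.

    Returns one metric row per comparator plus an ``AutoML`` row when a
    fitted bundle is supplied, mirroring the published comparison layout.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    rows = {}
    for name in comparators:
        model = _default_estimator(name, seed)
        model.fit(X_train, np.asarray(y_train).astype(int))
        scores = predict_proba_1(model, X_test)
        rows[name] = metrics.report_from_scores(scores, y_test).as_dict()
    if automl_bundle is not None:
        scores = automl_bundle.predict_proba(X_test)
        rows["AutoML"] = metrics.report_from_scores(scores, y_test).as_dict()
    table = pd.DataFrame(rows).T.drop(columns=["undefined"])
    table.index.name = "model"
    return table
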