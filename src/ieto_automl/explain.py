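"""Post-hoc model interpretation: Shapley attributions, interactions, LASSO audit.

Attributions carry the local-accuracy (additivity) guarantee: per sample the
base value plus the feature contributions equals the model's margin output.
Gradient-boosted models are explained exactly through their native
tree-path contribution algorithms; every other model is explained with an
interventional Shapley estimator over a seeded background sample — exact
subset enumeration when the feature count permits, Monte-Carlo permutation
averaging (which preserves additivity exactly, telescoping per permutation)
otherwise.

The audit side benchmarks the Shapley ranking against the model's intrinsic
importance and an L1-regularized logistic (LASSO) reference, summarized by
Cohen's kappa on top-k membership.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from math import factorial
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.preprocessing import StandardScaler

from ieto_automl.automl import ModelBundle

__all__ = [
    "AttributionMatrix",
    "ImportanceRanking",
    "ConcordanceResult",
    "UnsupportedModelError",
    "shap_attributions",
    "global_importance",
    "interaction_values",
    "lasso_reference",
    "rank_concordance",
    "render_reports",
]


class UnsupportedModelError(TypeError):
    """Raised when an explanation method does not apply to the model class."""


@dataclass
class AttributionMatrix:
    values: np.ndarray  # n x p
    base_value: float
    feature_names: list[str]

    def additivity_residual(self, margins: np.ndarray) -> np.ndarray:
        return margins - (self.base_value + self.values.sum(axis=1))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame["base_value"] = self.base_value
        return frame


@dataclass
class ImportanceRanking:
    importance: dict[str, float]  # feature -> mean |attribution|
    order: list[str]  # descending importance, names break ties

    def top(self, k: int) -> list[str]:
        return self.order[:k]


@dataclass
class ConcordanceResult:
    kappa: float
    top_a: list[str]
    top_b: list[str]
    note: str = "Cohen's kappa on top-k membership indicators"


def _is_lightgbm(model) -> bool:
    return type(model).__module__.startswith("lightgbm")


def _is_xgboost(model) -> bool:
    return type(model).__module__.startswith("xgboost")


def _is_tree_model(model) -> bool:
    if _is_lightgbm(model) or _is_xgboost(model):
        return True
    mod = type(model).__module__
    name = type(model).__name__
    return mod.startswith("sklearn") and any(
        key in name for key in ("Tree", "Forest", "AdaBoost", "GradientBoosting", "Bagging")
    )


@contextmanager
def _quiet_feature_names():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        yield


def margin_function(model):
    """The output the attributions decompose: raw margin where available."""
    if _is_lightgbm(model):
        def _lgb_margin(X):
            with _quiet_feature_names():
                return np.asarray(model.predict(X, raw_score=True), dtype=float).ravel()

        return _lgb_margin
    if _is_xgboost(model):
        import xgboost

        booster = model.get_booster()
        return lambda X: np.asarray(
            booster.predict(xgboost.DMatrix(X), output_margin=True), dtype=float
        ).ravel()
    if hasattr(model, "decision_function"):
        def _df_margin(X):
            with _quiet_feature_names():
                return np.asarray(model.decision_function(X), dtype=float).ravel()

        return _df_margin

    def _proba_margin(X):
        with _quiet_feature_names():
            return np.asarray(model.predict_proba(X), dtype=float)[:, 1]

    return _proba_margin


def _native_tree_contrib(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    if _is_lightgbm(model):
        with _quiet_feature_names():
            contrib = np.asarray(model.predict(X, pred_contrib=True), dtype=float)
    else:
        import xgboost

        booster = model.get_booster()
        contrib = np.asarray(
            booster.predict(xgboost.DMatrix(X), pred_contribs=True), dtype=float
        )
    return contrib[:, :-1], float(contrib[0, -1])


def _subset_value_table(f, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """v[s] = E_b f(x on subset-bits of s, b elsewhere) for all 2^p subsets."""
    p = x.size
    n_sub = 1 << p
    B = background.shape[0]
    rows = np.tile(background, (n_sub, 1))
    subset_bits = ((np.arange(n_sub)[:, None] >> np.arange(p)) & 1).astype(bool)
    take = np.repeat(subset_bits, B, axis=0)
    rows[take] = np.broadcast_to(x, (n_sub * B, p))[take]
    out = f(rows)
    return out.reshape(n_sub, B).mean(axis=1)


def _shapley_from_table(v: np.ndarray, p: int) -> np.ndarray:
    w = np.array(
        [factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)]
    )
    phi = np.zeros(p)
    sizes = np.array([bin(s).count("1") for s in range(1 << p)])
    for s in range(1 << p):
        if sizes[s] == p:
            continue
        ws = w[sizes[s]]
        for i in range(p):
            if not s & (1 << i):
                phi[i] += ws * (v[s | (1 << i)] - v[s])
    return phi


def _enumeration_attributions(f, X, background) -> tuple[np.ndarray, float]:
    p = X.shape[1]
    base = float(np.mean(f(background)))
    values = np.vstack(
        [_shapley_from_table(_subset_value_table(f, x, background), p) for x in X]
    )
    return values, base


def _permutation_attributions(f, X, background, n_permutations, rng) -> tuple[np.ndarray, float]:
    n, p = X.shape
    B = background.shape[0]
    base = float(np.mean(f(background)))
    values = np.zeros((n, p))
    perms = [rng.permutation(p) for _ in range(n_permutations)]
    for i, x in enumerate(X):
        acc = np.zeros(p)
        for perm in perms:
            # cumulative hybrids along the permutation, batched over background
            rows = np.tile(background, (p + 1, 1))
            for step in range(1, p + 1):
                cols = perm[:step]
                rows[step * B : (step + 1) * B, cols] = x[cols]
            vals = f(rows).reshape(p + 1, B).mean(axis=1)
            acc[perm] += np.diff(vals)
        values[i] = acc / n_permutations
    return values, base


def shap_attributions(
    bundle,
    data: np.ndarray,
    background: np.ndarray | None = None,
    method: str = "auto",
    seed: int = 0,
    max_enum_features: int = 12,
    n_permutations: int = 32,
    max_background: int = 64,
    feature_names: Sequence[str] | None = None,
) -> AttributionMatrix:
    """Per-sample signed feature contributions with the additivity contract.

    ``bundle`` may be a fitted :class:`ModelBundle` (data given on the full
    feature set; the mask and stored background are applied) or any fitted
    binary classifier (data given on its own feature space). ``method`` is
    ``"tree"`` (native tree-path contributions), ``"interventional"`` or
    ``"auto"``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 0:
        raise ValueError("empty data")
    if isinstance(bundle, ModelBundle):
        model = bundle.estimator
        X = data[:, bundle.feature_mask]
        names = bundle.selected_features
        if background is None:
            background = bundle.background
    else:
        model = bundle
        X = data
        names = list(feature_names) if feature_names is not None else [
            f"x{i}" for i in range(X.shape[1])
        ]
    if method == "auto":
        method = "tree" if (_is_lightgbm(model) or _is_xgboost(model)) else "interventional"
    if method == "tree":
        if not (_is_lightgbm(model) or _is_xgboost(model)):
            raise UnsupportedModelError(
                "native tree-path contributions require a LightGBM or XGBoost model"
            )
        values, base = _native_tree_contrib(model, X)
        return AttributionMatrix(values, base, names)
    if method != "interventional":
        raise ValueError(f"unknown method {method!r}")
    if background is None:
        background = X
    background = np.atleast_2d(np.asarray(background, dtype=float))
    rng = np.random.default_rng(seed)
    if background.shape[0] > max_background:
        background = background[
            np.sort(rng.choice(background.shape[0], max_background, replace=False))
        ]
    f = margin_function(model)
    p = X.shape[1]
    if p <= max_enum_features:
        values, base = _enumeration_attributions(f, X, background)
    else:
        values, base = _permutation_attributions(f, X, background, n_permutations, rng)
    return AttributionMatrix(values, base, names)


def global_importance(attr: AttributionMatrix) -> ImportanceRanking:
    """Mean |attribution| per feature, ranked descending (names break ties)."""
    if attr.values.shape[0] < 1:
        raise ValueError("need at least one explained sample")
    imp = {
        name: float(np.mean(np.abs(attr.values[:, j])))
        for j, name in enumerate(attr.feature_names)
    }
    order = sorted(imp, key=lambda k: (-imp[k], k))
    return ImportanceRanking(imp, order)


def _interactions_from_table(v: np.ndarray, p: int) -> np.ndarray:
    """Symmetric off-diagonal Shapley interaction indices (split evenly)."""
    phi_ij = np.zeros((p, p))
    if p < 2:
        return phi_ij
    w2 = np.array(
        [factorial(s) * factorial(p - s - 2) / factorial(p - 1) for s in range(p - 1)]
    )
    sizes = np.array([bin(s).count("1") for s in range(1 << p)])
    for s in range(1 << p):
        for i in range(p):
            if s & (1 << i):
                continue
            for j in range(i + 1, p):
                if s & (1 << j):
                    continue
                delta = (
                    v[s | (1 << i) | (1 << j)]
                    - v[s | (1 << i)]
                    - v[s | (1 << j)]
                    + v[s]
                )
                phi_ij[i, j] += w2[sizes[s]] * delta
    phi_ij = phi_ij + phi_ij.T
    return phi_ij / 2.0  # split evenly over the (i,j)/(j,i) cells


def interaction_values(
    bundle,
    data: np.ndarray,
    background: np.ndarray | None = None,
    seed: int = 0,
    max_enum_features: int = 12,
    max_background: int = 64,
) -> np.ndarray:
    """n x p x p symmetric interaction tensor for tree-based models.

    Diagonal cells absorb the main effects so each row sums to the feature's
    attribution. XGBoost models use the native tree-path interactions; other
    tree models use exact interventional enumeration (feature count capped).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if isinstance(bundle, ModelBundle):
        model = bundle.estimator
        X = data[:, bundle.feature_mask]
        if background is None:
            background = bundle.background
    else:
        model = bundle
        X = data
    if not _is_tree_model(model):
        raise UnsupportedModelError("interaction values require a tree-based model")
    if _is_xgboost(model):
        import xgboost

        booster = model.get_booster()
        tensor = np.asarray(
            booster.predict(xgboost.DMatrix(X), pred_interactions=True), dtype=float
        )[:, :-1, :-1]
        # exact symmetry (the native float32 computation is symmetric only to ~1e-7)
        return 0.5 * (tensor + tensor.transpose(0, 2, 1))
    p = X.shape[1]
    if p > max_enum_features:
        raise UnsupportedModelError(
            f"exact interaction enumeration capped at {max_enum_features} features (got {p})"
        )
    if background is None:
        background = X
    background = np.atleast_2d(np.asarray(background, dtype=float))
    rng = np.random.default_rng(seed)
    if background.shape[0] > max_background:
        background = background[
            np.sort(rng.choice(background.shape[0], max_background, replace=False))
        ]
    f = margin_function(model)
    tensors = []
    for x in X:
        v = _subset_value_table(f, x, background)
        phi = _shapley_from_table(v, p)
        t = _interactions_from_table(v, p)
        np.fill_diagonal(t, phi - t.sum(axis=1))
        tensors.append(t)
    return np.stack(tensors)


def lasso_reference(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    n_penalties: int = 25,
) -> dict[str, float]:
    """L1-logistic coefficients on the standardized scale, penalty by 5-fold CV.

    The penalty grid spans C in [1e-3, 1e3]; the CV criterion is mean
    held-out deviance (log loss). Zero coefficients mark excluded features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]
    Z = StandardScaler().fit_transform(X)
    model = LogisticRegressionCV(
        l1_ratios=(1.0,),  # pure L1
        solver="liblinear",
        Cs=np.logspace(-3, 3, n_penalties),
        cv=5,
        scoring="neg_log_loss",
        random_state=seed,
        max_iter=1000,
        use_legacy_attributes=False,
    )
    model.fit(Z, y)
    return dict(zip(names, model.coef_.ravel().astype(float)))


def rank_concordance(
    rank_a: Sequence[str],
    rank_b: Sequence[str],
    k: int = 5,
    universe: Sequence[str] | None = None,
) -> ConcordanceResult:
    """Cohen's kappa on the binary indicator "feature in top-k" over the universe."""
    universe = list(universe) if universe is not None else sorted(set(rank_a) | set(rank_b))
    if k > len(universe):
        raise ValueError("k exceeds the size of the feature universe")
    top_a, top_b = set(rank_a[:k]), set(rank_b[:k])
    in_a = np.array([f in top_a for f in universe])
    in_b = np.array([f in top_b for f in universe])
    n = len(universe)
    po = float(np.mean(in_a == in_b))
    pa, pb = in_a.mean(), in_b.mean()
    pe = pa * pb + (1.0 - pa) * (1.0 - pb)
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return ConcordanceResult(float(kappa), sorted(top_a), sorted(top_b))


def comparison_table(
    shap_ranking: ImportanceRanking,
    intrinsic: dict[str, float],
    lasso: dict[str, float],
    k: int = 5,
) -> pd.DataFrame:
    """Side-by-side audit table: Shapley mean | intrinsic importance | LASSO beta."""
    top = set(shap_ranking.top(k))
    lasso_nonzero = {f for f, b in lasso.items() if b != 0.0}
    rows = []
    for f in shap_ranking.order:
        rows.append(
            {
                "feature": f,
                "shap_mean_abs": shap_ranking.importance[f],
                "intrinsic_importance": intrinsic.get(f, np.nan),
                "lasso_beta": lasso.get(f, np.nan),
                "consistent": bool(f in top and f in lasso_nonzero),
            }
        )
    return pd.DataFrame(rows)


def render_reports(
    attr: AttributionMatrix,
    predictions: np.ndarray,
    out_dir: str | Path,
    interactions: np.ndarray | None = None,
    patients: Sequence[int] = (),
) -> list[Path]:
    """Write summary, importance, waterfall, force, decision-path and
    interaction figures to ``out_dir``; returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    names = attr.feature_names
    ranking = global_importance(attr)
    order = [names.index(f) for f in ranking.order]

    # beeswarm-style summary
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(names) + 2))
    rng = np.random.default_rng(0)
    for row, j in enumerate(order):
        y = row + rng.uniform(-0.25, 0.25, size=attr.values.shape[0])
        ax.scatter(attr.values[:, j], y, s=6, alpha=0.5)
    ax.set_yticks(range(len(order)), [names[j] for j in order])
    ax.invert_yaxis()
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("attribution (margin units)")
    fig.tight_layout()
    path = out / "summary.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # global importance bars
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(names) + 2))
    ax.barh(ranking.order[::-1], [ranking.importance[f] for f in ranking.order[::-1]])
    ax.set_xlabel("mean |attribution|")
    fig.tight_layout()
    path = out / "importance.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    for idx in patients:
        contrib = attr.values[idx]
        srt = np.argsort(-np.abs(contrib))
        # waterfall
        fig, ax = plt.subplots(figsize=(6, 0.4 * len(names) + 2))
        running = attr.base_value
        for row, j in enumerate(srt):
            ax.barh(row, contrib[j], left=running,
                    color="firebrick" if contrib[j] > 0 else "steelblue")
            running += contrib[j]
        ax.set_yticks(range(len(srt)), [names[j] for j in srt])
        ax.invert_yaxis()
        ax.axvline(attr.base_value, color="k", lw=0.5, ls="--")
        ax.set_xlabel(f"margin (base {attr.base_value:.3f} -> {running:.3f})")
        fig.tight_layout()
        path = out / f"waterfall_patient{idx}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
        # force plot (stacked horizontal pushes)
        fig, ax = plt.subplots(figsize=(8, 1.8))
        left = attr.base_value
        for j in srt:
            ax.barh(0, contrib[j], left=left,
                    color="firebrick" if contrib[j] > 0 else "steelblue", height=0.4)
            left += contrib[j]
        ax.axvline(left, color="k", lw=1.0)
        ax.set_yticks([])
        ax.set_xlabel("margin")
        fig.tight_layout()
        path = out / f"force_patient{idx}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    # decision paths: cumulative attribution from base to prediction
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(names) + 2))
    idxs = list(patients) if patients else list(range(min(10, attr.values.shape[0])))
    for idx in idxs:
        cum = attr.base_value + np.cumsum(attr.values[idx][order])
        ax.plot(np.concatenate([[attr.base_value], cum]), range(len(order) + 1))
    ax.set_yticks(range(len(order) + 1), ["base"] + [names[j] for j in order])
    ax.invert_yaxis()
    ax.set_xlabel("cumulative margin")
    fig.tight_layout()
    path = out / "decision_paths.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    if interactions is not None:
        mean_abs = np.mean(np.abs(interactions), axis=0)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mean_abs, cmap="viridis")
        ax.set_xticks(range(len(names)), names, rotation=90)
        ax.set_yticks(range(len(names)), names)
        fig.colorbar(im, ax=ax, label="mean |interaction|")
        fig.tight_layout()
        path = out / "interactions.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
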