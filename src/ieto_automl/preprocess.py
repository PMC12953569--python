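"""Standardized preprocessing: split, outlier rectification, one-hot, imputation.

The pipeline mirrors standard tabular clinical-ML practice: an 8:2
train/test split, Tukey-fence winsorization of continuous variables with
fences learned on training data only, one-hot encoding with the category
vocabulary learned on training data, and MissForest-style iterative
random-forest multiple imputation pooled over several seeded completions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ieto_automl import schema

__all__ = [
    "SplitResult",
    "PreprocessModel",
    "split",
    "rectify_outliers",
    "one_hot",
    "rf_impute",
]


@dataclass
class SplitResult:
    train: pd.DataFrame
    test: pd.DataFrame
    seed: int


def split(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
) -> SplitResult:
    """Random (optionally outcome-stratified) split with |train| = floor(f*n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[int] = []
        for _, grp in table.groupby(schema.OUTCOME):
            idx = grp.index.to_numpy()
            take = int(round(train_fraction * idx.size))
            train_idx.extend(rng.permutation(idx)[:take])
        # adjust to the exact floor(f*n) size deterministically
        train_idx = list(rng.permutation(np.array(train_idx)))
        rest = [i for i in table.index if i not in set(train_idx)]
        while len(train_idx) > n_train:
            rest.append(train_idx.pop())
        while len(train_idx) < n_train and rest:
            train_idx.append(rest.pop())
        mask = table.index.isin(train_idx)
    else:
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_train]] = True
    return SplitResult(
        train=table.loc[mask].reset_index(drop=True),
        test=table.loc[~mask].reset_index(drop=True),
        seed=seed,
    )


def _tukey_fences(col: pd.Series) -> tuple[float, float]:
    q1, q3 = np.quantile(col.dropna().to_numpy(dtype=float), [0.25, 0.75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def rectify_outliers(
    train: pd.DataFrame,
    apply_to: pd.DataFrame | None = None,
    continuous: tuple[str, ...] = schema.CONTINUOUS_VARIABLES,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Winsorize continuous variables to Tukey fences learned on ``train``.

    Returns the rectified copy of ``apply_to`` (default: the training table
    itself) and a per-variable count of clipped cells. Categorical columns
    are untouched; a constant variable collapses its fences onto the
    constant and nothing is clipped.
    """
    target = (apply_to if apply_to is not None else train).copy()
    report: dict[str, int] = {}
    for col in continuous:
        if col not in train.columns or col not in target.columns:
            continue
        lo, hi = _tukey_fences(train[col])
        vals = target[col].to_numpy(dtype=float)
        clipped = np.clip(vals, lo, hi)
        report[col] = int(np.nansum(clipped != vals))
        target[col] = clipped
    return target, report


def one_hot(
    train: pd.DataFrame,
    apply_to: pd.DataFrame | None = None,
    categorical: tuple[str, ...] = schema.BINARY_VARIABLES,
) -> tuple[pd.DataFrame, list[str]]:
    """One-hot encode with the category vocabulary learned on ``train``.

    Two-level variables become a single 0/1 column (indicator of the larger
    level); variables with more levels expand to one indicator per seen
    category. Unseen categories at apply time yield an all-zero block and a
    warning.
    """
    target = (apply_to if apply_to is not None else train).copy()
    out = {}
    names: list[str] = []
    for col in target.columns:
        if col not in categorical:
            out[col] = target[col].to_numpy()
            names.append(col)
            continue
        vocab = sorted(train[col].dropna().unique().tolist())
        seen = set(vocab)
        unseen = set(target[col].dropna().unique()) - seen
        if unseen:
            warnings.warn(
                f"{col}: unseen categories {sorted(unseen)} encoded as all-zero",
                stacklevel=2,
            )
        if len(vocab) <= 2:
            positive = vocab[-1] if vocab else 1
            out[col] = (target[col] == positive).astype(float).to_numpy()
            names.append(col)
        else:
            for cat in vocab:
                name = f"{col}={cat}"
                out[name] = (target[col] == cat).astype(float).to_numpy()
                names.append(name)
    frame = pd.DataFrame(out, columns=names)
    return frame, names


def _fit_forest(kind: str, seed: int) -> RandomForestRegressor | RandomForestClassifier:
    # leaf-size floor keeps imputations from chasing noise in mostly
    # uninformative predictor sets
    common = dict(n_estimators=50, min_samples_leaf=5, n_jobs=1, random_state=seed)
    if kind == "continuous":
        return RandomForestRegressor(**common)
    return RandomForestClassifier(**common)


def _single_imputation(table: pd.DataFrame, kinds: dict[str, str], seed: int,
                       max_iter: int = 10) -> pd.DataFrame:
    work = table.copy()
    miss = {c: work[c].isna().to_numpy() for c in work.columns if work[c].isna().any()}
    # initialize: median for continuous, mode for categorical
    for col, mask in miss.items():
        if kinds[col] == "continuous":
            work.loc[mask, col] = work[col].median()
        else:
            work.loc[mask, col] = work[col].mode().iloc[0]
    order = sorted(miss, key=lambda c: miss[c].sum())
    others = {c: [o for o in work.columns if o != c] for c in order}
    prev_change = np.inf
    snapshot = work.copy()
    for _ in range(max_iter):
        for col in order:
            mask = miss[col]
            X_obs = work.loc[~mask, others[col]].to_numpy(dtype=float)
            y_obs = work.loc[~mask, col].to_numpy()
            X_mis = work.loc[mask, others[col]].to_numpy(dtype=float)
            forest = _fit_forest(kinds[col], seed)
            forest.fit(X_obs, y_obs)
            work.loc[mask, col] = forest.predict(X_mis)
        # stop when the change criterion stops decreasing
        change = 0.0
        for col in order:
            mask = miss[col]
            new = work.loc[mask, col].to_numpy(dtype=float)
            old = snapshot.loc[mask, col].to_numpy(dtype=float)
            if kinds[col] == "continuous":
                denom = max(np.sum(new**2), 1e-12)
                change += float(np.sum((new - old) ** 2) / denom)
            else:
                change += float(np.mean(new != old))
        if change >= prev_change:
            work = snapshot  # keep the better previous state
            break
        prev_change = change
        snapshot = work.copy()
    return work


def rf_impute(
    table: pd.DataFrame,
    seed: int = 0,
    m: int = 5,
    kinds: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """MissForest-style multiple imputation pooled to one completed table.

    ``m`` seeded iterative completions are pooled per cell — mean for
    continuous variables, mode for categorical ones. Observed cells are
    returned untouched; variables missing entirely, or more than half
    missing, raise.
    """
    kinds = kinds or {
        c: schema.VARIABLE_KINDS.get(c, "binary") for c in table.columns
    }
    frac = table.isna().mean()
    fully = [c for c in table.columns if len(table) and table[c].isna().all()]
    if fully:
        raise ValueError(f"variables with all values missing: {fully}")
    too_much = frac[frac > 0.5].index.tolist()
    if too_much:
        raise ValueError(f"variables exceed 50% missingness: {too_much}")
    diagnostics = {"missing_fraction": frac.to_dict(), "m": m}
    if not table.isna().any().any():
        return table.copy(), diagnostics
    completions = [
        _single_imputation(table, kinds, seed=seed + k) for k in range(m)
    ]
    pooled = table.copy()
    for col in table.columns:
        mask = table[col].isna()
        if not mask.any():
            continue
        stack = np.vstack([c.loc[mask, col].to_numpy(dtype=float) for c in completions])
        if kinds[col] == "continuous":
            pooled.loc[mask, col] = stack.mean(axis=0)
        else:
            # columnwise mode
            vals = []
            for j in range(stack.shape[1]):
                u, counts = np.unique(stack[:, j], return_counts=True)
                vals.append(u[np.argmax(counts)])
            pooled.loc[mask, col] = vals
    assert not pooled.isna().any().any()
    return pooled, diagnostics


@dataclass
class PreprocessModel:
    """Fitted preprocessing state: fences and one-hot vocabulary from training data.

    ``fit`` learns fences/vocabulary on a (completed) training table;
    ``transform`` applies them to any table with the same schema and returns
    the numeric design matrix together with its feature names.
    """

    continuous: tuple[str, ...] = schema.CONTINUOUS_VARIABLES
    categorical: tuple[str, ...] = schema.BINARY_VARIABLES
    fences: dict = field(default_factory=dict)
    train_reference: pd.DataFrame | None = None
    feature_names: list[str] = field(default_factory=list)

    def fit(self, train: pd.DataFrame) -> "PreprocessModel":
        features = train[[c for c in train.columns if c != schema.OUTCOME]]
        self.fences = {
            c: _tukey_fences(features[c]) for c in self.continuous if c in features
        }
        self.train_reference = features.copy()
        transformed, names = self._apply(features)
        self.feature_names = names
        return self

    def _apply(self, features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        work = features.copy()
        for col, (lo, hi) in self.fences.items():
            if col in work:
                work[col] = np.clip(work[col].to_numpy(dtype=float), lo, hi)
        return one_hot(self.train_reference, work, categorical=self.categorical)

    def transform(self, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        if self.train_reference is None:
            raise RuntimeError("PreprocessModel must be fitted first")
        features = table[[c for c in table.columns if c != schema.OUTCOME]]
        frame, names = self._apply(features)
        return frame.to_numpy(dtype=float), names
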