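"""Classification metrics, ROC/PR areas and decision-curve analysis.

Point metrics follow the usual confusion-matrix definitions (PRE, SEN, SPE,
ACC, F1 as the harmonic mean of PRE and SEN); ROC-AUC is the Mann-Whitney
probability of correct pair ordering with ties credited one half; PR-AUC is
average precision over the sorted-score sweep. Decision-curve analysis
reports net benefit NB(t) = TP/n - FP/n * t/(1-t) against treat-all and
treat-none references.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve, precision_recall_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "DCACurve",
    "point_metrics",
    "roc_auc",
    "pr_auc",
    "decision_curve",
    "report_from_scores",
    "cross_validated_report",
    "f1_from_pre_sen",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
    ) -> "ConfusionCounts":
        pred = np.asarray(scores) >= threshold
        labels = np.asarray(labels).astype(bool)
        return cls(
            tp=int(np.sum(pred & labels)),
            fp=int(np.sum(pred & ~labels)),
            tn=int(np.sum(~pred & ~labels)),
            fn=int(np.sum(~pred & labels)),
        )


@dataclass
class MetricsReport:
    PRE: float | None = None
    SEN: float | None = None
    SPE: float | None = None
    ACC: float | None = None
    F1: float | None = None
    ROC_AUC: float | None = None
    PR_AUC: float | None = None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class DCACurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray


def f1_from_pre_sen(pre: float, sen: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if pre + sen == 0:
        return 0.0
    return 2.0 * pre * sen / (pre + sen)


def point_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Confusion-matrix point metrics; zero denominators are flagged, not NaN."""
    report = MetricsReport()

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            report.undefined.append(name)
            return None
        return num / den

    report.PRE = ratio(counts.tp, counts.tp + counts.fp, "PRE")
    report.SEN = ratio(counts.tp, counts.tp + counts.fn, "SEN")
    report.SPE = ratio(counts.tn, counts.tn + counts.fp, "SPE")
    report.ACC = ratio(counts.tp + counts.tn, counts.n, "ACC")
    if report.PRE is not None and report.SEN is not None:
        report.F1 = f1_from_pre_sen(report.PRE, report.SEN)
    else:
        report.undefined.append("F1")
    return report


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC area = P(score_pos > score_neg) + 0.5 P(tie) (Mann-Whitney)."""
    labels = _check_binary(np.asarray(labels))
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision over the sorted-score precision/recall staircase."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0:
        raise ValueError("at least one positive label required")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def decision_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] | None = None,
) -> DCACurve:
    """Net-benefit curve with treat-all / treat-none references.

    Classification at score >= t. Thresholds default to the 0.01..0.99 grid
    in steps of 0.01; t = 1 is excluded (the t/(1-t) weight diverges).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0.0) or np.any(thresholds >= 1.0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = labels.size
    prevalence = labels.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        nb_model[i] = tp / n - fp / n * odds[i]
    nb_all = prevalence - (1.0 - prevalence) * odds
    nb_none = np.zeros_like(thresholds)
    return DCACurve(thresholds, nb_model, nb_all, nb_none)


def report_from_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> MetricsReport:
    """Full metric bundle from predicted probabilities and true labels."""
    counts = ConfusionCounts.from_predictions(np.asarray(scores), np.asarray(labels), threshold)
    report = point_metrics(counts)
    report.ROC_AUC = roc_auc(scores, labels)
    report.PR_AUC = pr_auc(scores, labels)
    return report


def cross_validated_report(
    model_builder: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """Stratified k-fold evaluation: every metric averaged over held-out folds.

    Note the fold-averaged F1 need not exactly equal the harmonic mean of the
    fold-averaged PRE and SEN (Jensen gap of the harmonic mean).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for tr, va in skf.split(X, y):
        model = model_builder()
        model.fit(X[tr], y[tr])
        scores = model.predict_proba(X[va])[:, 1]
        per_fold.append(report_from_scores(scores, y[va], threshold))
    report = MetricsReport()
    for name in ("PRE", "SEN", "SPE", "ACC", "F1", "ROC_AUC", "PR_AUC"):
        vals = [getattr(r, name) for r in per_fold]
        if any(v is None for v in vals):
            report.undefined.append(name)
        else:
            setattr(report, name, float(np.mean(vals)))
    return report


def export_curves(scores, labels, out_dir, prefix: str = "model", plots: bool = False) -> None:
    """Write ROC/PR/DCA curve CSVs (and optionally PNG figures)."""
    from pathlib import Path
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve(labels, scores)
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(out / f"{prefix}_roc.csv", index=False)
    prec, rec, _ = precision_recall_curve(labels, scores)
    pd.DataFrame({"recall": rec, "precision": prec}).to_csv(out / f"{prefix}_pr.csv", index=False)
    dca = decision_curve(scores, labels)
    pd.DataFrame(
        {
            "threshold": dca.thresholds,
            "nb_model": dca.nb_model,
            "nb_all": dca.nb_all,
            "nb_none": dca.nb_none,
        }
    ).to_csv(out / f"{prefix}_dca.csv", index=False)
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(15, 4))
        axes[0].plot(fpr, tpr)
        axes[0].plot([0, 1], [0, 1], "k--")
        axes[0].set(xlabel="1 - specificity", ylabel="sensitivity", title="ROC")
        axes[1].plot(rec, prec)
        axes[1].set(xlabel="recall", ylabel="precision", title="PR")
        axes[2].plot(dca.thresholds, dca.nb_model, label="model")
        axes[2].plot(dca.thresholds, dca.nb_all, "r--", label="treat all")
        axes[2].plot(dca.thresholds, dca.nb_none, "k--", label="treat none")
        axes[2].set(xlabel="threshold", ylabel="net benefit", title="DCA")
        axes[2].legend()
        axes[2].set_ylim(-0.1, max(0.5, dca.nb_model.max() + 0.05))
        fig.tight_layout()
        fig.savefig(out / f"{prefix}_curves.png", dpi=120)
        plt.close(fig)
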