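"""Baseline cohort comparisons: pooled two-sample t-tests and Pearson chi-square.

Continuous variables are compared with the pooled-variance (Student)
two-sample t-test and categorical variables with the Pearson chi-square test
without continuity correction — the conventions that reproduce published
baseline-characteristics tables from their printed summaries. Entry points
accept either raw cohort tables or printed summaries (mean/SD/n, 2x2
counts) directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ieto_automl import schema

__all__ = [
    "SummaryStat",
    "CountTable2x2",
    "TestResult",
    "pooled_t",
    "chi2_2x2",
    "baseline_table",
    "summarize_variable",
]


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not np.isfinite(self.sd) or self.sd < 0:
            raise ValueError("sd must be finite and >= 0")

    @classmethod
    def from_sample(cls, values: np.ndarray) -> "SummaryStat":
        values = np.asarray(values, dtype=float)
        return cls(float(values.mean()), float(values.std(ddof=1)), int(values.size))


@dataclass(frozen=True)
class CountTable2x2:
    a: int  # group 1, level 1
    b: int  # group 1, level 2
    c: int  # group 2, level 1
    d: int  # group 2, level 2

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    kind: str  # "t" | "chi2"


def pooled_t(g1: SummaryStat, g2: SummaryStat) -> TestResult:
    """Student's pooled-variance two-sample t-test from group summaries."""
    n1, n2 = g1.n, g2.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    if sp2 == 0:
        if diff == 0:
            return TestResult(0.0, df, 1.0, "t")
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p), "t")


def chi2_2x2(table: CountTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    if min(table.margins) == 0:
        raise ValueError("all margins must be positive")
    observed = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    rows = observed.sum(axis=1, keepdims=True)
    cols = observed.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.n
    stat = float(np.sum((observed - expected) ** 2 / expected))
    p = float(sps.chi2.sf(stat, 1))
    return TestResult(stat, 1, p, "chi2")


def summarize_variable(values: pd.Series, kind: str) -> str:
    values = values.dropna()
    if kind == "continuous":
        return f"{values.mean():.2f} ± {values.std(ddof=1):.2f}"
    n = len(values)
    yes = int((values == 1).sum())
    return f"{yes} ({100.0 * yes / n:.2f}%)" if n else "0"


def baseline_table(
    train: pd.DataFrame,
    test: pd.DataFrame,
    variables: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per variable: group summaries, test statistic, p-value.

    ``variables`` maps variable name to kind ("continuous" or "binary");
    defaults to the cohort schema.
    """
    variables = variables or {
        v: schema.VARIABLE_KINDS[v] for v in schema.FEATURE_COLUMNS
    }
    missing = [v for v in variables if v not in train.columns or v not in test.columns]
    if missing:
        raise ValueError(f"variables absent from a table: {missing}")
    rows = []
    for name, kind in variables.items():
        if kind == "continuous":
            res = pooled_t(
                SummaryStat.from_sample(train[name].dropna()),
                SummaryStat.from_sample(test[name].dropna()),
            )
        else:
            tr, te = train[name].dropna(), test[name].dropna()
            res = chi2_2x2(
                CountTable2x2(
                    int((tr == 1).sum()), int((tr != 1).sum()),
                    int((te == 1).sum()), int((te != 1).sum()),
                )
            )
        rows.append(
            {
                "variable": name,
                "train": summarize_variable(train[name], kind),
                "test": summarize_variable(test[name], kind),
                "statistic": res.statistic,
                "kind": res.kind,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
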