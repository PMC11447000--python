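"""Cohort-level statistics: Grubbs outlier screening and two-group t-tests.

Metrics are compared between genotypes (WT vs HET) with a two-tailed pooled
Student's t-test; single extreme values are screened with the two-sided
Grubbs test, removing at most one observation per invocation (iterative
screening is opt-in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "CohortTable",
    "TestResult",
    "grubbs_critical",
    "grubbs_test",
    "grubbs_screen",
    "two_group_t",
]


@dataclass
class CohortTable:
    """Tidy per-subject metric table.

    Columns: ``subject_id``, ``genotype`` ("WT" or "HET"), ``metric``,
    ``value`` — one value per subject x metric.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "genotype", "metric", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(["subject_id", "metric"])
        if dup.any():
            raise ValueError("one value per subject x metric required")

    def values(self, metric: str, genotype: str) -> np.ndarray:
        sel = (self.data["metric"] == metric) & (self.data["genotype"] == genotype)
        return self.data.loc[sel, "value"].to_numpy(dtype=float)


@dataclass
class TestResult:
    """Two-group test outcome with audit inputs."""

    statistic: float
    degrees_of_freedom: float
    p_value: float
    group_means: dict[str, float]
    group_sd: dict[str, float]
    n_per_group: dict[str, int]
    metric: str = ""


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t-distribution.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2}.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = sp_stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values: np.ndarray, alpha: float = 0.05) -> int | None:
    """Index of the single most extreme outlier, or None.

    G = max|x_i - mean| / sd (sample sd, ddof=1) against the two-sided
    critical value. At most one point is flagged; ties on deviation break to
    the lower index.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Grubbs test needs n >= 3, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))  # argmax takes the first maximum: lower index
    g = dev[idx] / sd
    return idx if g > grubbs_critical(x.size, alpha) else None


def grubbs_screen(
    values: np.ndarray, alpha: float = 0.05, iterative: bool = False
) -> list[int]:
    """Indices (into the original vector) flagged by Grubbs screening.

    By default a single invocation; with ``iterative=True`` the test is
    repeated on the remaining points until none is flagged or fewer than 3
    remain.
    """
    x = np.asarray(values, dtype=float)
    remaining = list(range(x.size))
    flagged: list[int] = []
    while len(remaining) >= 3:
        idx = grubbs_test(x[remaining], alpha)
        if idx is None:
            break
        flagged.append(remaining.pop(idx))
        if not iterative:
            break
    return flagged


def two_group_t(
    table: CohortTable,
    metric: str,
    groups: tuple[str, str] = ("WT", "HET"),
    welch: bool = False,
) -> TestResult:
    """Two-tailed Student's t-test between genotypes for one metric.

    Pooled-variance by default (df = n1 + n2 - 2); Welch's correction by
    flag. Identical degenerate groups (zero variance, equal means) return
    statistic 0 and p-value 1.
    """
    a = table.values(metric, groups[0])
    b = table.values(metric, groups[1])
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"both groups need n >= 2 for {metric!r}; got {a.size} and {b.size}"
        )
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        stat, p, df = 0.0, 1.0, float(a.size + b.size - 2)
    else:
        res = sp_stats.ttest_ind(a, b, equal_var=not welch)
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return TestResult(
        statistic=stat,
        degrees_of_freedom=df,
        p_value=p,
        group_means={groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        group_sd={groups[0]: float(a.std(ddof=1)), groups[1]: float(b.std(ddof=1))},
        n_per_group={groups[0]: int(a.size), groups[1]: int(b.size)},
        metric=metric,
    )
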