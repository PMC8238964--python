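"""Cohort statistics: group summaries, two-sample tests, regression.

Mirrors the study's statistical layer: per-group mean +- sample SD,
two-sample Welch t-tests (a pooled-variance option is exposed), and
ordinary least squares with R^2 reported as the squared Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """Mean +- sample SD of one metric within one group."""

    group: str
    metric: str
    mean: float
    sd: float
    n: int
    degenerate: bool = False  # single-member group: sd reported as 0


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def summarize(
    groups: Mapping[str, Sequence[float]], metric: str = ""
) -> list[GroupSummary]:
    """Arithmetic mean and sample SD (n-1 denominator) per group.

    A single-member group has no sample SD; it is reported as 0 with the
    ``degenerate`` flag set rather than failing the whole cohort run.
    """
    out = []
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=np.float64)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        degenerate = arr.size == 1
        sd = 0.0 if degenerate else float(np.std(arr, ddof=1))
        out.append(
            GroupSummary(
                group=name,
                metric=metric,
                mean=float(arr.mean()),
                sd=sd,
                n=int(arr.size),
                degenerate=degenerate,
            )
        )
    return out


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch (unequal variance) by default.

    Zero variance in both groups is degenerate for the t statistic: equal
    means report (0, 1) by convention, unequal means report (+-inf, 0).
    """
    a = np.asarray(list(values_a), dtype=np.float64)
    b = np.asarray(list(values_b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def regress(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x.

    R^2 is the squared Pearson correlation; the p-value is the two-sided
    t-test on the slope. Constant x leaves the slope unidentified and is
    an error.
    """
    xa = np.asarray(list(x), dtype=np.float64)
    ya = np.asarray(list(y), dtype=np.float64)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(xa) == 0:
        raise ValueError("x is constant; slope is unidentified")
    res = sps.linregress(xa, ya)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=int(xa.size),
    )
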