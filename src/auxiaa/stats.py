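"""Summary statistics used by the family survey.

Pearson correlation (copy number vs predicted loci), two-sample
Student's t-test (segmental vs tandem ω), paired t-test, and grouped
Ka/Ks means by lineage and duplication mode.  Plain wrappers around
scipy.stats with the degenerate cases pinned down: zero variance is an
error for the correlation, a zero pooled variance with separated means
is reported as the p → 0 limit, and undefined ω values (Ks = 0) are
excluded from group means with an explicit count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .codon import KaKsResult

__all__ = [
    "StatResult",
    "pearson_r",
    "students_t_test",
    "paired_t_test",
    "group_kaks_means",
]


@dataclass(frozen=True)
class StatResult:
    name: str
    estimate: float
    p_value: float | None
    n: int
    degrees_of_freedom: float | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Sample Pearson correlation with a two-sided p-value.

    The p-value comes from the t transform with n - 2 degrees of
    freedom.  Zero variance in either variable is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return StatResult("pearson_r", float(r), float(p), n, n - 2)


def students_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> StatResult:
    """Classic equal-variance two-sample t-test, two-sided.

    Fully separated samples with zero within-group variance have no
    finite t; they are reported as the limit p = 0 with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = a.size + b.size - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return StatResult("students_t", 0.0, 1.0, a.size + b.size, df)
        warnings.warn(
            "zero pooled variance with separated means: reporting p -> 0 limit",
            stacklevel=2,
        )
        t = float("inf") if a.mean() > b.mean() else float("-inf")
        return StatResult("students_t", t, 0.0, a.size + b.size, df)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return StatResult("students_t", float(t), float(p), a.size + b.size, df)


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> StatResult:
    """Welch's unequal-variance alternative, behind its own name."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return StatResult(
        "welch_t", float(res.statistic), float(res.pvalue), a.size + b.size, float(res.df)
    )


def paired_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> StatResult:
    """Paired t-test on element-wise differences, two-sided."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    df = a.size - 1
    if np.var(diff, ddof=1) == 0:
        if diff[0] == 0:
            return StatResult("paired_t", 0.0, 1.0, a.size, df)
        warnings.warn(
            "constant nonzero difference: reporting p -> 0 limit", stacklevel=2
        )
        t = float("inf") if diff[0] > 0 else float("-inf")
        return StatResult("paired_t", t, 0.0, a.size, df)
    t, p = sps.ttest_rel(a, b)
    return StatResult("paired_t", float(t), float(p), a.size, df)


def group_kaks_means(
    results: Iterable[KaKsResult],
    lineage_of: Mapping[str, str],
    duplication_of: Mapping[str, str],
) -> pd.DataFrame:
    """Mean ω per (lineage, duplication type) cell, to 4 decimals.

    Results with undefined ω (Ks = 0 or saturated rates) are excluded
    from both numerator and denominator; the exclusion count is carried
    per cell.  Empty cells are simply absent from the table.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    excluded: dict[tuple[str, str], int] = {}
    for res in results:
        if res.pair not in lineage_of:
            raise KeyError(f"pair {res.pair!r} has no lineage label")
        if res.pair not in duplication_of:
            raise KeyError(f"pair {res.pair!r} has no duplication label")
        key = (lineage_of[res.pair], duplication_of[res.pair])
        if res.omega is None:
            excluded[key] = excluded.get(key, 0) + 1
            continue
        cells.setdefault(key, []).append(res.omega)
    rows = []
    for (lineage, dup), omegas in sorted(cells.items()):
        rows.append(
            {
                "lineage": lineage,
                "duplication_type": dup,
                "mean_omega": round(float(np.mean(omegas)), 4),
                "n": len(omegas),
                "n_excluded": excluded.get((lineage, dup), 0),
            }
        )
    # cells with only excluded entries still appear, flagged without a mean
    for key, n_exc in sorted(excluded.items()):
        if key not in cells:
            rows.append(
                {
                    "lineage": key[0],
                    "duplication_type": key[1],
                    "mean_omega": None,
                    "n": 0,
                    "n_excluded": n_exc,
                }
            )
    return pd.DataFrame(rows)
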