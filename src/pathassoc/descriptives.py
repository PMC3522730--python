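"""Cohort description and case/control heterogeneity tests.

Quantitative variables are compared with a pooled-variance (Student) two-
sample t-test; categorical variables with a Pearson chi-square, applying
the Yates continuity correction by default on 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import SampleTable

__all__ = ["ttest_student", "chisq_2x2", "cohort_summary", "CohortSummary"]


def ttest_student(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    df = n1 + n2 - 2.  Zero variance in both groups with equal means gives
    (0, 1) rather than a division error.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if sp2 == 0.0:
        if mean1 == mean2:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def chisq_2x2(table, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square (1 df) on a 2x2 table; Yates correction default."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


@dataclass
class CohortSummary:
    table: pd.DataFrame           # variable, category, statistics, p
    n_cases: int
    n_controls: int


def cohort_summary(samples: SampleTable,
                   quantitative=("age",),
                   categorical=("ethnicity",),
                   yates: bool = True) -> CohortSummary:
    """Group-wise summaries with heterogeneity p-values.

    Quantitative variables: mean (SD) per group, Student t-test.
    Categorical variables: n (%) per group, chi-square (Yates on 2x2).
    Percentages are rounded to one decimal.
    """
    df = samples.table
    if len(df) == 0:
        raise ValueError("empty cohort")
    cases = df[df["status"] == 1]
    controls = df[df["status"] == 0]
    rows = []
    for var in quantitative:
        x1, x2 = cases[var].dropna(), controls[var].dropna()
        if len(x1) < 2 or len(x2) < 2:
            raise ValueError(f"SD undefined for {var!r}: fewer than 2 observations")
        t, p = ttest_student(x1.mean(), x1.std(ddof=1), len(x1),
                             x2.mean(), x2.std(ddof=1), len(x2))
        rows.append({"variable": var, "category": "mean (SD)",
                     "cases": f"{x1.mean():.2f} ({x1.std(ddof=1):.2f})",
                     "controls": f"{x2.mean():.2f} ({x2.std(ddof=1):.2f})",
                     "combined": f"{df[var].mean():.2f} ({df[var].std(ddof=1):.2f})",
                     "p_heterogeneity": p})
    for var in categorical:
        levels = sorted(df[var].dropna().unique())
        counts = np.array([[int((cases[var] == lv).sum()) for lv in levels],
                           [int((controls[var] == lv).sum()) for lv in levels]])
        if len(levels) == 2:
            _, p = chisq_2x2(counts, yates=yates)
        else:
            _, p, _, _ = stats.chi2_contingency(counts)
        for i, lv in enumerate(levels):
            c1, c2 = counts[0, i], counts[1, i]
            tot = int((df[var] == lv).sum())
            rows.append({
                "variable": var, "category": str(lv),
                "cases": f"{c1} ({100.0 * c1 / counts[0].sum():.1f})",
                "controls": f"{c2} ({100.0 * c2 / counts[1].sum():.1f})",
                "combined": f"{tot} ({100.0 * tot / counts.sum():.1f})",
                "p_heterogeneity": p if i == 0 else None})
    return CohortSummary(pd.DataFrame(rows), len(cases), len(controls))
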