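"""Cohort description tables: counts and rounded percentages per category.

Reproduces the classic "patients' characteristics" table: for each
categorical variable (tumour size, grade, nodal status, chemotherapy, ...)
and each cohort column, the count and its percentage of the column total,
rounded half-away-from-zero to the nearest integer.  Thin wrappers around
Fisher's exact, chi-squared and Mann-Whitney tests are provided for
between-column comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "round_percent",
    "summarize",
    "fisher_exact",
    "chi_square",
    "mann_whitney",
]


def round_percent(count: int, total: int) -> int:
    """Integer percentage, half rounded away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    return int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))


@dataclass
class CohortTable:
    """Counts and integer percentages per category level per cohort column."""

    table: pd.DataFrame          # MultiIndex (variable, level) x columns, "n (p%)"
    counts: pd.DataFrame
    percents: pd.DataFrame
    column_n: pd.Series

    def to_markdown(self) -> str:
        return self.table.to_markdown()


def summarize(
    annotation: pd.DataFrame,
    variables=None,
    column: str | None = None,
) -> CohortTable:
    """Build a cohort-characteristics table from a per-sample annotation.

    ``column`` names the annotation field splitting samples into cohort
    columns (e.g. subtype); None summarises everything in one column.
    ``variables`` defaults to all remaining categorical fields.
    """
    if annotation.empty:
        raise ValueError("empty cohort")
    if column is not None:
        col_labels = annotation[column].astype(str)
    else:
        col_labels = pd.Series("All", index=annotation.index)
    col_levels = list(pd.unique(col_labels))
    if variables is None:
        variables = [
            c
            for c in annotation.columns
            if c != column
            and (annotation[c].dtype == object or annotation[c].nunique() <= 10)
        ]

    rows, counts, percents = [], [], []
    for var in variables:
        for level in pd.unique(annotation[var].dropna()):
            idx = (var, str(level))
            cnt, pct = {}, {}
            for cl in col_levels:
                mask = col_labels == cl
                n_col = int(mask.sum())
                n = int(((annotation[var] == level) & mask).sum())
                cnt[cl] = n
                pct[cl] = round_percent(n, n_col)
            rows.append(idx)
            counts.append(cnt)
            percents.append(pct)

    index = pd.MultiIndex.from_tuples(rows, names=["variable", "level"])
    counts = pd.DataFrame(counts, index=index)
    percents = pd.DataFrame(percents, index=index)
    display = counts.astype(str) + " (" + percents.astype(str) + "%)"
    column_n = col_labels.value_counts().reindex(col_levels)
    return CohortTable(table=display, counts=counts, percents=percents, column_n=column_n)


# Between-column comparison pass-throughs


def fisher_exact(table_2x2) -> tuple[float, float]:
    res = stats.fisher_exact(np.asarray(table_2x2))
    return float(res[0]), float(res[1])


def chi_square(table) -> tuple[float, float]:
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table))
    return float(chi2), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
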