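"""Descriptive layer: screening-status cross-tabs, chi-squared tests,
median (IQR), and the two-sample rank-sum test.

Each table uses its own pairwise complete cases, so denominators may differ
across characteristics (variables collected only in a survey subsample yield
smaller tables).  Percentages are always row-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_spec import PathDiagram

__all__ = [
    "ContingencyTable",
    "crosstab",
    "chi_squared_test",
    "ranksum_test",
    "median_iqr",
    "table_one",
]


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # non-negative integers, rows x cols

    @property
    def row_percent(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / totals

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


def _categorical_series(records: pd.DataFrame, diagram: PathDiagram, name: str) -> pd.Series:
    var = diagram.variable(name)
    if not var.is_categorical:
        raise TypeError(f"{name} is continuous; crosstab needs categorical variables")
    s = records[name].astype("object").where(lambda x: ~x.isna(), None)
    s = s.map(lambda v: None if v is None or str(v).strip() in ("", "NA") else str(v).strip())
    return s


def crosstab(
    records: pd.DataFrame, diagram: PathDiagram, rowvar: str, colvar: str
) -> ContingencyTable:
    """Counts of rowvar x colvar over the pair's complete cases, with label
    order taken from the variable declarations."""
    rows = _categorical_series(records, diagram, rowvar)
    cols = _categorical_series(records, diagram, colvar)
    keep = rows.notna() & cols.notna()
    rows, cols = rows[keep], cols[keep]
    row_labels = list(diagram.variable(rowvar).levels)
    col_labels = list(diagram.variable(colvar).levels)
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    tab = pd.crosstab(rows, cols)
    for i, rl in enumerate(row_labels):
        for j, cl in enumerate(col_labels):
            if rl in tab.index and cl in tab.columns:
                counts[i, j] = tab.loc[rl, cl]
    return ContingencyTable(row_labels, col_labels, counts)


def chi_squared_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction).

    Zero marginal rows/columns make expected counts zero and the statistic
    undefined; such tables are rejected rather than silently collapsed.
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: a row or column marginal is zero")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def ranksum_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum: mid-ranks for ties, tie-corrected
    normal approximation without continuity correction, two-sided p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    # recover the signed z from U (mannwhitneyu reports U of the first sample)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (u.statistic - mu) / np.sqrt(var)
    return float(z), float(u.pvalue)


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) using linear-interpolation ("type 7") quantiles."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def table_one(
    records: pd.DataFrame,
    diagram: PathDiagram,
    by: Optional[str] = None,
) -> pd.DataFrame:
    """Characteristics cross-tabulated against the outcome (or ``by``):
    counts (row %) with chi-squared p for categorical variables, median (IQR)
    with rank-sum p for continuous ones."""
    by = by or diagram.outcome
    by_var = diagram.variable(by)
    rows: list[dict] = []
    for var in diagram.variables:
        if var.name == by:
            continue
        if var.is_categorical:
            tab = crosstab(records, diagram, var.name, by)
            nonzero = tab.counts.sum(axis=1) > 0
            try:
                _, _, p = chi_squared_test(
                    ContingencyTable(
                        [l for l, k in zip(tab.row_labels, nonzero) if k],
                        tab.col_labels,
                        tab.counts[nonzero],
                    )
                )
            except ValueError:
                p = np.nan
            pct = tab.row_percent
            for i, lvl in enumerate(tab.row_labels):
                row = {"characteristic": f"{var.name}—{lvl}", "p": p if i == 0 else np.nan}
                for j, cl in enumerate(tab.col_labels):
                    row[cl] = f"{tab.counts[i, j]} ({pct[i, j]:.2f})"
                rows.append(row)
        else:
            groups = _categorical_series(records, diagram, by)
            vals = pd.to_numeric(records[var.name], errors="coerce")
            keep = groups.notna() & vals.notna()
            samples = {
                lvl: vals[keep & (groups == lvl)].to_numpy() for lvl in by_var.levels
            }
            if all(s.size for s in samples.values()) and len(samples) == 2:
                _, p = ranksum_test(*samples.values())
            else:
                p = np.nan
            row = {"characteristic": f"{var.name}—median(IQR)", "p": p}
            for lvl, s in samples.items():
                if s.size:
                    med, q1, q3 = median_iqr(s)
                    row[lvl] = f"{med:g} ({q1:g},{q3:g})"
                else:
                    row[lvl] = ""
            rows.append(row)
    return pd.DataFrame(rows)
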