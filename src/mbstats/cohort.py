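"""Clinicopathologic table statistics.

Conventions here are the ones that make two-group patient-characteristic
tables exactly reproducible from their printed counts: Pearson chi-square
without Yates continuity correction for nominal variables, and the
Cochran-Armitage trend test with integer scores and the binomial variance
WITHOUT the finite-population N/(N-1) factor for ordinal variables.
Wilcoxon rank-sum handles continuous variables, exact for small untied
samples and normal-approximated with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import TestResult, ValidationError

__all__ = [
    "ContingencyTable",
    "wilcoxon_rank_sum",
    "chi_square_test",
    "cochran_armitage_trend",
    "cohort_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Categories x groups count table; rows ordered if the variable is ordinal."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape inconsistent with labels")
        if c.shape[0] < 2 or c.shape[1] < 2:
            raise ValidationError("contingency table must be at least 2x2")
        if (c < 0).any():
            raise ValidationError("counts must be non-negative")
        if c.sum() == 0:
            raise ValidationError("empty contingency table")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @classmethod
    def from_lists(cls, rows, cols, counts) -> "ContingencyTable":
        return cls(tuple(rows), tuple(cols), np.asarray(counts))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most 20 and there
    are no ties; otherwise the normal approximation with tie correction
    (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = combined.size <= 20 and not has_ties
    res = stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="wilcoxon_exact" if exact else "wilcoxon_normal",
    )


def chi_square_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    c = table.counts
    if (c.sum(axis=1) == 0).any() or (c.sum(axis=0) == 0).any():
        raise ValidationError("zero marginal row or column")
    chi2, p, _dof, _exp = stats.chi2_contingency(c, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p), method="pearson_chi2")


def cochran_armitage_trend(table: ContingencyTable, scores=None) -> TestResult:
    """Cochran-Armitage test for trend across ordered categories, two groups.

    With row totals n_i, first-group counts r_i, scores s_i (default 1..r),
    R = sum r_i and N = sum n_i:

        T = sum s_i (r_i - n_i R / N)
        Var(T) = (R/N)(1 - R/N) [sum n_i s_i^2 - (sum n_i s_i)^2 / N]

    Z = T / sqrt(Var) is referred to the standard normal, two-sided.  No
    finite-population correction factor is applied to the variance.
    """
    c = table.counts
    if c.shape[1] != 2:
        raise ValidationError("trend test requires exactly 2 groups (columns)")
    if c.shape[0] < 2:
        raise ValidationError("trend test requires >=2 ordered categories")
    n_i = c.sum(axis=1).astype(float)
    r_i = c[:, 0].astype(float)
    n_total = n_i.sum()
    r_total = r_i.sum()
    s = np.arange(1, c.shape[0] + 1, dtype=float) if scores is None else np.asarray(scores, float)
    if s.shape != (c.shape[0],):
        raise ValidationError("scores length must equal number of rows")
    t = np.sum(s * (r_i - n_i * r_total / n_total))
    pbar = r_total / n_total
    var = pbar * (1 - pbar) * (np.sum(n_i * s**2) - np.sum(n_i * s) ** 2 / n_total)
    if var <= 0:
        return TestResult(statistic=0.0, p_value=1.0, method="cochran_armitage")
    z = t / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return TestResult(statistic=float(z), p_value=p, method="cochran_armitage")


def cohort_report(metadata: pd.DataFrame, manifest, group_col: str) -> pd.DataFrame:
    """Two-group characteristics table from per-subject metadata.

    ``manifest`` is a list of ``(variable, kind)`` pairs with kind one of
    ``continuous``, ``nominal``, ``ordinal``; ordinal variables must be
    pandas Categoricals with ordered categories (or sortable values).
    Missing values are dropped per variable.  Returns one row per variable
    with the test used and its p-value.
    """
    groups = pd.unique(metadata[group_col].dropna())
    if len(groups) != 2:
        raise ValidationError(f"{group_col!r} must have exactly 2 levels")
    rows = []
    for var, kind in manifest:
        sub = metadata[[var, group_col]].dropna()
        g1 = sub.loc[sub[group_col] == groups[0], var]
        g2 = sub.loc[sub[group_col] == groups[1], var]
        if kind == "continuous":
            res = wilcoxon_rank_sum(g1.astype(float), g2.astype(float))
        elif kind in ("nominal", "ordinal"):
            cats = (
                list(sub[var].cat.categories)
                if isinstance(sub[var].dtype, pd.CategoricalDtype)
                else sorted(sub[var].unique())
            )
            counts = np.array(
                [[(g1 == c).sum(), (g2 == c).sum()] for c in cats], dtype=int
            )
            keep = counts.sum(axis=1) > 0
            ct = ContingencyTable(
                tuple(str(c) for c, k in zip(cats, keep) if k),
                (str(groups[0]), str(groups[1])),
                counts[keep],
            )
            res = chi_square_test(ct) if kind == "nominal" else cochran_armitage_trend(ct)
        else:
            raise ValidationError(f"unknown variable kind {kind!r} for {var!r}")
        rows.append(
            {
                "variable": var,
                "kind": kind,
                "test": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)
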