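"""Taxon aggregation, filtering, and permutation F-tests for abundance shifts.

The differential-abundance test fits, per feature, an ordinary linear model
of the square-root-transformed proportion on covariates plus group, takes
the partial F statistic for the group term, and assesses significance with
Freedman-Lane residual permutation under the covariates-only model.  The
square root damps outliers while keeping zeros at zero; permutation avoids
normality assumptions that proportion data violate.  The same machinery
applies unchanged to functional (pathway) count tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import OtuTable, TAXONOMIC_RANKS, ValidationError, to_proportions

__all__ = [
    "FilterRule",
    "aggregate_taxa",
    "filter_features",
    "permutation_f_test",
    "functional_da",
]


@dataclass(frozen=True)
class FilterRule:
    """Prevalence/abundance filter for low-information taxa.

    A feature is retained only when its prevalence (fraction of samples with
    a nonzero count) is at least ``min_prevalence`` AND its maximum relative
    abundance across samples is at least ``min_max_proportion``.
    """

    min_prevalence: float = 0.10
    min_max_proportion: float = 0.002

    def __post_init__(self):
        for v in (self.min_prevalence, self.min_max_proportion):
            if not 0.0 <= v <= 1.0:
                raise ValidationError("filter thresholds must lie in [0, 1]")


def aggregate_taxa(table: OtuTable, taxonomy: pd.DataFrame, rank: str) -> OtuTable:
    """Sum OTU counts to a taxonomic rank.

    Unclassified lineages are pooled per parent label (an OTU whose genus is
    unknown but whose family is F contributes to ``F;unclassified`` rather
    than to a global unclassified bin), so depth is conserved exactly.
    """
    if rank not in TAXONOMIC_RANKS:
        raise ValidationError(f"rank must be one of {TAXONOMIC_RANKS}")
    missing = sorted(set(table.feature_ids) - set(taxonomy.index))
    if missing:
        raise ValidationError(f"OTUs missing from taxonomy: {missing}")
    ranks_upto = TAXONOMIC_RANKS[: TAXONOMIC_RANKS.index(rank) + 1]
    labels = []
    for otu in table.feature_ids:
        lineage = [str(taxonomy.loc[otu, r]) for r in ranks_upto]
        # collapse trailing unclassified ranks onto the deepest named parent
        while len(lineage) > 1 and lineage[-1] == "unclassified":
            lineage.pop()
        if lineage[-1] == "unclassified":
            labels.append("unclassified")
        elif len(lineage) < len(ranks_upto):
            labels.append(";".join(lineage) + ";unclassified")
        else:
            labels.append(lineage[-1])
    df = table.to_dataframe()
    df.columns = labels
    agg = df.T.groupby(level=0, sort=False).sum().T
    return OtuTable(agg.to_numpy(), table.sample_ids, list(agg.columns))


def filter_features(
    table: OtuTable, rule: FilterRule = FilterRule()
) -> tuple[OtuTable, pd.DataFrame]:
    """Apply a prevalence/maximum-abundance filter.

    Returns the retained table and a report of removed features with the
    statistic that failed.
    """
    props = to_proportions(table)
    prevalence = (table.counts > 0).mean(axis=0)
    max_prop = props.max(axis=0)
    keep = (prevalence >= rule.min_prevalence) & (max_prop >= rule.min_max_proportion)
    removed = pd.DataFrame(
        {
            "feature": [f for f, k in zip(table.feature_ids, keep) if not k],
            "prevalence": prevalence[~keep],
            "max_proportion": max_prop[~keep],
        }
    )
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    if not kept_ids:
        raise ValidationError("filter removed every feature")
    return table.select_features(kept_ids), removed


def _group_dummies(group) -> np.ndarray:
    g = pd.Series(list(group))
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValidationError("group must have at least 2 levels")
    return pd.get_dummies(g, drop_first=True).to_numpy(dtype=float)


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permutation_f_test(
    table: OtuTable,
    group,
    covariates=None,
    n_perm: int = 1000,
    seed: int | None = None,
    transform: str = "sqrt",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-feature permutation F-test of group on transformed proportions.

    For each feature the outcome is the square root of its relative
    abundance; a linear model with covariates plus group is compared to the
    covariates-only null via the partial F statistic.  The null distribution
    comes from ``n_perm`` Freedman-Lane permutations: null-model residuals
    are permuted (the same permutations for every feature), refitted, and
    the permuted F computed.  Ties count as exceedances, so
    ``p >= 1/(n_perm+1)``.

    Returns a DataFrame with one row per feature: F, p (unadjusted -- no
    multiple-testing correction by default), per-group mean proportions, and
    a nominal ``significant`` flag at p < 0.05.  Set ``bh_correction=True``
    for an additional Benjamini-Hochberg column.
    """
    props = to_proportions(table)
    y = np.sqrt(props) if transform == "sqrt" else props
    n, p = y.shape
    g = _group_dummies(group)
    if len(g) != n:
        raise ValidationError("group length does not match table")
    x0 = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        x0 = np.column_stack([x0, cov])
    x1 = np.column_stack([x0, g])
    rank0 = np.linalg.matrix_rank(x0)
    rank1 = np.linalg.matrix_rank(x1)
    if rank1 <= rank0:
        raise ValidationError("group is confounded with the covariates")
    df1 = rank1 - rank0
    df2 = n - rank1
    if df2 <= 0:
        raise ValidationError("model saturates the data (no residual df)")

    h0, h1 = _hat(x0), _hat(x1)
    m0 = np.eye(n) - h0
    m1 = np.eye(n) - h1

    def f_stat(ymat: np.ndarray) -> np.ndarray:
        rss0 = np.sum((m0 @ ymat) ** 2, axis=0)
        rss1 = np.sum((m1 @ ymat) ** 2, axis=0)
        diff = np.clip(rss0 - rss1, 0.0, None)
        scale = np.sum(ymat**2, axis=0) + 1e-300  # outcome magnitude per feature
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (diff / df1) / (rss1 / df2)
        # degenerate outcomes: no residual variation under the null model
        # means F carries no evidence (0); a perfect full-model fit of a
        # varying outcome is unbounded evidence (inf)
        f = np.where(rss0 / scale < 1e-12, 0.0,
                     np.where(rss1 / scale < 1e-12, np.inf, f))
        return f

    f_obs = f_stat(y)
    fitted0 = h0 @ y
    resid0 = m0 @ y
    rng = np.random.default_rng(seed)
    exceed = np.zeros(p)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted0 + resid0[perm]
        exceed += f_stat(y_star) >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    glabels = pd.Series(list(group))
    out = pd.DataFrame({"feature": table.feature_ids, "F": f_obs, "p": pvals})
    for level in pd.unique(glabels):
        out[f"mean_proportion_{level}"] = props[(glabels == level).to_numpy()].mean(axis=0)
    out["significant"] = out["p"] < 0.05
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def functional_da(
    pathway_table: OtuTable,
    group,
    covariates=None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Differential abundance of functional categories (pathway counts).

    Pathway counts are normalized to relative abundances and tested with the
    same square-root permutation F-test as taxa; identical contract to
    :func:`permutation_f_test`.
    """
    return permutation_f_test(
        pathway_table, group, covariates=covariates, n_perm=n_perm, seed=seed
    )
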