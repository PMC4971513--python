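"""Alpha diversity, rarefaction curves, UniFrac distances, PCoA, clustering.

UniFrac is computed from a branch x sample incidence decomposition of the
rooted phylogeny: every branch contributes its length weighted by the
presence (unweighted) or the descendant-proportion difference (weighted) of
the two communities.  Both variants are evaluated for all sample pairs with
vectorized branch sums, which keeps full-cohort distance matrices cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix, TreeNode

from .core import OtuTable, ValidationError, rarefy, to_proportions

__all__ = [
    "observed_otus",
    "shannon",
    "alpha_diversity",
    "rarefaction_curve",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pcoa",
    "OrdinationResult",
    "presence_absence_clustering",
]


def observed_otus(counts) -> int:
    """Number of features with a positive count (species richness)."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    return int((counts > 0).sum())


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i over positive proportions.

    Natural logarithm; richness-and-evenness measure.  All-zero input is an
    error (no community to describe).
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("Shannon index undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


_ALPHA_METRICS = {"observed_otus": observed_otus, "shannon": shannon}


def alpha_diversity(table: OtuTable, metric: str = "observed_otus") -> pd.Series:
    """Per-sample alpha diversity as a Series indexed by sample ID."""
    try:
        fn = _ALPHA_METRICS[metric]
    except KeyError:
        raise ValidationError(f"unknown alpha metric {metric!r}") from None
    return pd.Series(
        [fn(row) for row in table.counts], index=table.sample_ids, name=metric
    )


def rarefaction_curve(
    table: OtuTable,
    depths,
    n_reps: int = 10,
    seed: int | None = None,
    metric: str = "observed_otus",
) -> pd.DataFrame:
    """Mean alpha diversity per sample at each rarefaction depth.

    For each depth the table is independently rarefied ``n_reps`` times and
    the metric averaged.  Samples below a depth get NaN there.  Returns a
    DataFrame (samples x depths).
    """
    depths = list(depths)
    if depths != sorted(depths):
        raise ValidationError("depths must be sorted ascending")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(np.nan, index=table.sample_ids, columns=depths)
    for depth in depths:
        if not (table.depths >= depth).any():
            continue
        acc = None
        for _ in range(n_reps):
            sub, _dropped = rarefy(table, depth, rng=rng)
            vals = alpha_diversity(sub, metric)
            acc = vals if acc is None else acc.add(vals)
        out[depth] = acc / n_reps
    return out


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def _branch_decomposition(tree: TreeNode, feature_ids) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a rooted tree into branches over a fixed leaf ordering.

    Returns ``(lengths, membership)`` where ``lengths`` has one entry per
    non-root branch and ``membership[b, j]`` is 1 when leaf ``j`` descends
    from branch ``b``.  Raises if any feature is not a leaf of the tree.
    """
    leaf_pos = {f: j for j, f in enumerate(feature_ids)}
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(feature_ids) - tips)
    if missing:
        raise ValidationError(f"features absent from tree: {missing}")
    lengths, rows = [], []
    memo: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            vec = np.zeros(len(feature_ids), dtype=np.float64)
            if node.name in leaf_pos:
                vec[leaf_pos[node.name]] = 1.0
        else:
            vec = np.sum([memo.pop(id(c)) for c in node.children], axis=0)
        memo[id(node)] = vec
        lengths.append(node.length or 0.0)
        rows.append(vec)
    return np.asarray(lengths), np.vstack(rows)


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: fraction of branch length unique to one community.

    For samples i, j the distance is the total length of branches leading to
    leaves present in exactly one of the two communities, divided by the
    length of branches leading to leaves present in either.  Presence of a
    branch means any descendant leaf has count > 0.  Values lie in [0, 1];
    identical presence profiles give 0.
    """
    lengths, membership = _branch_decomposition(tree, table.feature_ids)
    present = (membership @ (table.counts.T > 0)) > 0  # branches x samples
    wl = lengths[:, None] * present
    # shared[i,j] = sum of lengths of branches present in both
    shared = wl.T.astype(float) @ present.astype(float)
    total = wl.sum(axis=0)
    union = total[:, None] + total[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (union - shared) / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(_symmetrize(d), ids=table.sample_ids)


def weighted_unifrac(
    table: OtuTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac on per-sample relative abundances.

    With ``normalized=True`` (default) the raw abundance-weighted branch
    difference ``sum_b l_b |p_ib - p_jb|`` is divided by
    ``sum_b l_b (p_ib + p_jb)``, bounding the distance to [0, 1]; fully
    disjoint communities reach exactly 1.
    """
    lengths, membership = _branch_decomposition(tree, table.feature_ids)
    props = to_proportions(table)
    branch_p = membership @ props.T  # branches x samples
    wp = lengths[:, None] * branch_p
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(wp[:, i, None] - wp[:, i + 1 :]).sum(axis=0)
        if normalized:
            denom = (wp[:, i, None] + wp[:, i + 1 :]).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                diff = np.where(denom > 0, diff / denom, 0.0)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return DistanceMatrix(_symmetrize(d), ids=table.sample_ids)


def _symmetrize(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


# ---------------------------------------------------------------------------
# Principal coordinates analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates`` is samples x k (axes ordered by decreasing eigenvalue),
    ``eigenvalues`` holds the full spectrum, and ``proportion_explained``
    divides each retained positive eigenvalue by the sum of positive ones.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Eigendecomposes the Gower-centered matrix ``-1/2 J D^2 J``; coordinates
    are eigenvectors scaled by the square root of their (positive)
    eigenvalues.  Negative eigenvalues -- which arise for non-Euclidean
    dissimilarities such as UniFrac -- are excluded from both the coordinates
    and the percent-explained denominator (no Cailliez/Lingoes correction).
    Each axis is oriented so that its largest-magnitude coordinate is
    positive, making the output independent of the eigensolver's sign choice.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if k > n - 1:
        raise ValidationError(f"k={k} exceeds n-1={n - 1}")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12 if evals.max() > 0 else evals > 0
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    for a in range(k_eff):
        col = coords[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    pos_sum = evals[pos].sum() if n_pos else 1.0
    explained = np.array([evals[a] / pos_sum for a in range(k_eff)])
    coord_df = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{a + 1}" for a in range(k_eff)]
    )
    return OrdinationResult(coord_df, evals, explained)


def presence_absence_clustering(table: OtuTable) -> np.ndarray:
    """Complete-linkage hierarchical clustering of 0/1 OTU profiles.

    Samples are reduced to presence/absence vectors, pairwise Euclidean
    distances taken, and merged by complete linkage.  Returns a SciPy linkage
    matrix (usable with ``scipy.cluster.hierarchy.dendrogram``).
    """
    if table.n_samples < 2:
        raise ValidationError("clustering needs at least 2 samples")
    profiles = (table.counts > 0).astype(float)
    return linkage(profiles, method="complete", metric="euclidean")
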