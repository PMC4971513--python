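"""Synthetic microbiome data with the structure the analysis pipeline assumes.

The generator emulates a surgical tissue-microbiome study design: tens of
subjects each contributing up to four sample types (breast tissue, skin
tissue, skin swab, buccal swab), split over two sequencing batches, with a
binary disease state (benign vs malignant) driving composition differences
concentrated in rare lineages.

Counts follow a Dirichlet-multinomial: per sample the composition is drawn
from Dirichlet(theta * pi) where log pi stacks a log-normal baseline,
sample-type and batch offsets, a subject-level random effect (shared across a
subject's samples, inducing within-subject correlation), and a disease-state
log fold-change on a designated set of differential features; reads are then
multinomial at a log-normally distributed depth.  Taxonomy is assigned by
cutting the simulated phylogeny into clades at five ranks, so rank
aggregation respects the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import OtuTable, TAXONOMIC_RANKS, ValidationError

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_counts",
    "simulate_gene_content",
    "simulate_functional_table",
]

_PHYLA = (
    "Bacteroidetes",
    "Firmicutes",
    "Proteobacteria",
    "Actinobacteria",
    "Fusobacteria",
    "Verrucomicrobia",
)
# Log-scale boosts making the first four phyla dominate, as in human tissue
# 16S surveys where Bacteroidetes/Firmicutes/Proteobacteria/Actinobacteria
# carry most of the abundance.
_PHYLUM_LOG_BOOST = (2.0, 2.0, 1.5, 1.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the Dirichlet-multinomial community generator.

    Defaults mirror the scale of an aseptic breast-surgery cohort: 33
    subjects, four sample types each, ~1,460 OTUs dominated by a handful of
    phyla, per-sample depths log-normal around a median of ~127,000 reads
    (range clipped to 28,549-335,363), and two sequencing batches.

    Attributes
    ----------
    n_otus, n_subjects, sample_types
        Community and design size.
    malignant_fraction
        Fraction of subjects labeled malignant; the rest are benign.
    n_differential, group_log_fold_change
        Number of disease-affected features and the natural-log fold-change
        applied to their baseline abundance in malignant subjects.  Affected
        features are drawn from the rarest quintile of the baseline by
        default (``differential_from_rarest=True``), matching the
        observation that disease signal sits in rare lineages.
    theta
        Dirichlet-multinomial concentration (precision); smaller values give
        more overdispersed compositions.  The default 200 places most of the
        between-sample overdispersion in the explicit log-normal noise
        (``composition_sd``) rather than the multinomial compounding.
    batch_effect_sd
        SD of the per-OTU log offset distinguishing batch B from batch A.
    sample_type_effect_sd
        SD of per-OTU log offsets separating sample types (0 for the first
        type, independent draws for the others).
    rho
        Within-subject correlation of the log-abundance noise: the noise SD
        ``composition_sd`` is split into a subject-level component (variance
        ``rho * composition_sd**2``) shared by all of a subject's samples and
        an independent per-sample remainder.
    baseline_log_mean, baseline_log_sd
        Log-normal baseline abundance parameters (rank-abundance shape).
    depth_log_median, depth_log_sd, depth_min, depth_max
        Log-normal read-depth distribution with clipping.
    """

    n_otus: int = 1460
    n_subjects: int = 33
    sample_types: tuple[str, ...] = (
        "breast_tissue",
        "skin_tissue",
        "skin_swab",
        "buccal_swab",
    )
    malignant_fraction: float = 0.5
    n_differential: int = 50
    group_log_fold_change: float = np.log(4.0)
    differential_features: tuple[str, ...] | None = None
    differential_from_rarest: bool = True
    theta: float = 200.0
    batch_effect_sd: float = 0.3
    sample_type_effect_sd: float = 1.0
    rho: float = 0.5
    composition_sd: float = 0.7
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 2.0
    depth_log_median: float = 126_764.0
    depth_log_sd: float = 0.5
    depth_min: int = 28_549
    depth_max: int = 335_363
    seed: int = 0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValidationError("theta must be > 0")
        if not 0 <= self.rho < 1:
            raise ValidationError("rho must be in [0, 1)")
        if self.n_otus < 2:
            raise ValidationError("need at least 2 OTUs")
        if not self.sample_types:
            raise ValidationError("at least one sample type required")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def simulate_tree(n_otus: int, seed: int | None = None) -> TreeNode:
    """Simulate a rooted binary pure-birth phylogeny over ``n_otus`` leaves.

    Starting from a cherry, a uniformly chosen leaf is repeatedly split until
    the target leaf count is reached; branch lengths are independent
    Exponential(1) draws.  Leaves are labeled ``OTU_1`` ... ``OTU_n`` in
    left-to-right order.  Deterministic for a given seed.
    """
    if n_otus < 2:
        raise ValidationError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    # children[i] = (left, right) node indices, or None for a leaf
    children = {0: None, 1: None}
    root_children = (0, 1)
    leaves = [0, 1]
    next_id = 2
    while len(leaves) < n_otus:
        pos = rng.integers(len(leaves))
        node = leaves[pos]
        left, right = next_id, next_id + 1
        next_id += 2
        children[node] = (left, right)
        children[left] = None
        children[right] = None
        leaves[pos] = left
        leaves.append(right)

    lengths = rng.exponential(1.0, size=next_id)

    label_counter = [0]

    def build(idx: int) -> TreeNode:
        if children[idx] is None:
            label_counter[0] += 1
            return TreeNode(name=f"OTU_{label_counter[0]}", length=float(lengths[idx]))
        kids = [build(c) for c in children[idx]]
        return TreeNode(length=float(lengths[idx]), children=kids)

    root = TreeNode(length=0.0, children=[build(c) for c in root_children])
    return root


def _clade_partition(tree: TreeNode, k: int) -> list[list[str]]:
    """Partition leaves into ``k`` disjoint clades by splitting largest first."""
    clades = [tree]
    while len(clades) < k:
        clades.sort(key=lambda n: -n.count(tips=True))
        biggest = clades.pop(0)
        if biggest.is_tip():
            clades.append(biggest)
            break
        clades.extend(biggest.children)
    return [[t.name for t in c.tips()] if not c.is_tip() else [c.name] for c in clades]


def _assign_taxonomy(tree: TreeNode, rng: np.random.Generator) -> pd.DataFrame:
    """Build a 5-rank taxonomy by nested clade cuts of the tree."""
    n = tree.count(tips=True)
    targets = {
        "phylum": min(len(_PHYLA), max(2, n // 250)) if n >= 12 else 2,
        "class": max(3, n // 120),
        "order": max(4, n // 60),
        "family": max(5, n // 30),
        "genus": max(6, n // 15),
    }
    # enforce monotone refinement of group counts across ranks
    prev = 2
    for rank in TAXONOMIC_RANKS:
        targets[rank] = min(n, max(prev, targets[rank]))
        prev = targets[rank]

    leaf_order = [t.name for t in tree.tips()]
    tax = pd.DataFrame(index=leaf_order, columns=list(TAXONOMIC_RANKS), dtype=object)
    phylum_clades = _clade_partition(tree, targets["phylum"])
    # Largest clades get the dominant phylum names.
    order = np.argsort([-len(c) for c in phylum_clades])
    for rank_idx, (rank, n_groups) in enumerate(targets.items()):
        clades = _clade_partition(tree, n_groups)
        if rank == "phylum":
            names = {}
            for name_idx, clade_idx in enumerate(order):
                label = _PHYLA[name_idx % len(_PHYLA)]
                if name_idx >= len(_PHYLA):
                    label = f"{label}_{name_idx}"
                names[clade_idx] = label
            for clade_idx, clade in enumerate(clades):
                tax.loc[clade, "phylum"] = names[clade_idx]
        else:
            for gi, clade in enumerate(clades):
                # label nests under the parent rank of the clade's first leaf
                parent = tax.loc[clade[0], TAXONOMIC_RANKS[rank_idx - 1]]
                tax.loc[clade, rank] = f"{parent}_{rank[0]}{gi + 1}"
    return tax


def simulate_counts(
    config: SimulationConfig, tree: TreeNode
) -> tuple[OtuTable, pd.DataFrame, pd.DataFrame]:
    """Simulate an OTU table, sample metadata, and taxonomy.

    Returns
    -------
    (table, metadata, taxonomy)
        ``metadata`` has columns sample_id, subject_id, sample_type,
        disease_state, batch, depth; ``taxonomy`` is indexed by OTU ID with
        one column per rank.
    """
    leaf_names = [t.name for t in tree.tips()]
    if len(leaf_names) != config.n_otus:
        raise ValidationError(
            f"tree has {len(leaf_names)} leaves but config.n_otus={config.n_otus}"
        )
    rng = np.random.default_rng(config.seed)
    p = config.n_otus

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=p)
    taxonomy = _assign_taxonomy(tree, rng)
    boost = dict(zip(_PHYLA, _PHYLUM_LOG_BOOST))
    baseline = baseline + np.array(
        [boost.get(str(ph).split("_")[0], 0.0) for ph in taxonomy["phylum"]]
    )

    if config.differential_features is not None:
        unknown = sorted(set(config.differential_features) - set(leaf_names))
        if unknown:
            raise ValidationError(f"differential features not in tree: {unknown}")
        diff_idx = np.array([leaf_names.index(f) for f in config.differential_features])
    else:
        k = min(config.n_differential, p)
        if config.differential_from_rarest:
            quintile = np.argsort(baseline)[: max(k, p // 5)]
            diff_idx = rng.choice(quintile, size=k, replace=False)
        else:
            diff_idx = rng.choice(p, size=k, replace=False)
    group_effect = np.zeros(p)
    group_effect[diff_idx] = config.group_log_fold_change

    type_effects = {config.sample_types[0]: np.zeros(p)}
    for st in config.sample_types[1:]:
        type_effects[st] = rng.normal(0.0, config.sample_type_effect_sd, size=p)
    batch_effect = rng.normal(0.0, config.batch_effect_sd, size=p)

    n_mal = int(round(config.malignant_fraction * config.n_subjects))
    disease = np.array(["malignant"] * n_mal + ["benign"] * (config.n_subjects - n_mal))
    rng.shuffle(disease)
    # batches randomized with equal representation of each disease state
    batch = np.empty(config.n_subjects, dtype=object)
    for state in ("malignant", "benign"):
        idx = np.flatnonzero(disease == state)
        half = len(idx) // 2 + (len(idx) % 2) * rng.integers(2)
        chosen = rng.choice(idx, size=int(half), replace=False)
        batch[idx] = "B"
        batch[chosen] = "A"

    sd_subject = config.composition_sd * np.sqrt(config.rho)
    sd_sample = config.composition_sd * np.sqrt(1.0 - config.rho)

    rows, meta_rows = [], []
    for si in range(config.n_subjects):
        subject_noise = rng.normal(0.0, sd_subject, size=p)
        for st in config.sample_types:
            log_pi = baseline + type_effects[st] + subject_noise
            log_pi = log_pi + rng.normal(0.0, sd_sample, size=p)
            if disease[si] == "malignant":
                log_pi = log_pi + group_effect
            if batch[si] == "B":
                log_pi = log_pi + batch_effect
            pi = np.exp(log_pi - log_pi.max())
            pi /= pi.sum()
            depth = int(
                np.clip(
                    rng.lognormal(np.log(config.depth_log_median), config.depth_log_sd),
                    config.depth_min,
                    config.depth_max,
                )
            )
            composition = rng.dirichlet(config.theta * pi)
            rows.append(rng.multinomial(depth, composition))
            meta_rows.append(
                {
                    "sample_id": f"S{si + 1}_{st}",
                    "subject_id": f"subj{si + 1}",
                    "sample_type": st,
                    "disease_state": disease[si],
                    "batch": batch[si],
                    "depth": depth,
                }
            )

    counts = np.vstack(rows)
    metadata = pd.DataFrame(meta_rows)
    table = OtuTable(counts, metadata["sample_id"].tolist(), leaf_names)
    return table, metadata, taxonomy


def simulate_gene_content(
    n_features: int, n_pathways: int, seed: int | None = None, density: float = 0.3
) -> np.ndarray:
    """Random sparse non-negative gene-content matrix (features x pathways).

    Emulates per-OTU functional copy numbers: each OTU carries a Poisson
    number of gene copies for a random subset of pathways.
    """
    rng = np.random.default_rng(seed)
    content = rng.poisson(2.0, size=(n_features, n_pathways)).astype(float)
    content *= rng.random((n_features, n_pathways)) < density
    return content


def simulate_functional_table(
    table: OtuTable, gene_content: np.ndarray, pathway_ids=None
) -> OtuTable:
    """Project OTU counts through a gene-content matrix to pathway counts.

    ``gene_content`` is features x pathways, non-negative; pathway counts are
    the rounded matrix product ``counts @ gene_content``.  Deterministic.
    """
    gene_content = np.asarray(gene_content, dtype=float)
    if gene_content.ndim != 2 or gene_content.shape[0] != table.n_features:
        raise ValidationError(
            f"gene content shape {gene_content.shape} does not match "
            f"{table.n_features} features"
        )
    if (gene_content < 0).any():
        raise ValidationError("gene content must be non-negative")
    pathway_counts = np.round(table.counts @ gene_content).astype(np.int64)
    if pathway_ids is None:
        pathway_ids = [f"pathway_{j + 1}" for j in range(gene_content.shape[1])]
    return OtuTable(pathway_counts, table.sample_ids, pathway_ids)
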