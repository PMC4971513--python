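"""Core data structures and I/O for microbiome count analysis.

The central object is :class:`OtuTable`, a samples x features matrix of
non-negative integer read counts with ordered, unique sample and feature
identifiers.  Features may be OTUs, taxa aggregated to a rank, or functional
categories (e.g. KEGG pathways) -- every downstream stage consumes the same
container.  Phylogenies are handled as :class:`skbio.TreeNode` objects,
taxonomies as pandas DataFrames indexed by OTU with one column per rank.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OtuTable",
    "TestResult",
    "TAXONOMIC_RANKS",
    "METADATA_COLUMNS",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "write_tree",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "validate_metadata",
    "rarefy",
    "to_proportions",
]

#: Ranks used for taxonomic aggregation, coarsest first.
TAXONOMIC_RANKS = ("phylum", "class", "order", "family", "genus")

#: Columns every per-sample metadata table must provide.
METADATA_COLUMNS = ("sample_id", "subject_id", "sample_type", "disease_state", "batch")

#: Greengenes-style rank prefixes accepted in lineage strings.
_RANK_PREFIXES = {"p": "phylum", "c": "class", "o": "order", "f": "family", "g": "genus"}


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class TestResult:
    """Uniform return contract for every hypothesis test in the package.

    ``n_permutations`` is 0 for asymptotic tests; for permutation tests the
    attained p-value can never fall below ``1 / (n_permutations + 1)``.
    """

    statistic: float
    p_value: float
    n_permutations: int = 0
    method: str = ""
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


class OtuTable:
    """Samples x features count matrix with aligned identifier lists.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per sample.
    sample_ids, feature_ids
        Unique, ordered identifiers matching the matrix shape.
    """

    def __init__(self, counts, sample_ids, feature_ids):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if np.issubdtype(counts.dtype, np.floating):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        counts = counts.astype(np.int64, copy=False)
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        sample_ids = [str(s) for s in sample_ids]
        feature_ids = [str(f) for f in feature_ids]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample IDs")
        if len(set(feature_ids)) != len(feature_ids):
            raise ValidationError("duplicate feature IDs")
        if counts.shape != (len(sample_ids), len(feature_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(sample_ids)} samples x {len(feature_ids)} features"
            )
        self.counts = counts
        self.sample_ids = sample_ids
        self.feature_ids = feature_ids

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def proportions(self) -> np.ndarray:
        """Row-normalized relative abundances; see :func:`to_proportions`."""
        return to_proportions(self)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(self.counts[idx], list(sample_ids), self.feature_ids)

    def select_features(self, feature_ids) -> "OtuTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return OtuTable(self.counts[:, idx], self.sample_ids, list(feature_ids))

    def __repr__(self):
        return f"OtuTable({self.n_samples} samples x {self.n_features} features)"

    def __eq__(self, other):
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, samples_as_rows: bool | None = None) -> OtuTable:
    """Read a tab-delimited count matrix.

    The file's first column holds row IDs and the first row holds column IDs.
    By convention files are features x samples; pass ``samples_as_rows=True``
    if rows are samples.  With ``None`` the orientation is taken from the
    convention (features as rows) -- auto-detection is not attempted because
    ID sets rarely disambiguate.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty or unparseable table file: {path}") from exc
    if df.empty and df.shape[1] == 0:
        raise ValidationError(f"empty table file: {path}")
    for col in df.columns:
        bad = df[col].apply(lambda v: not float(v).is_integer() or float(v) < 0)
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValidationError(
                f"non-integer or negative count at row {row!r}, column {col!r}"
            )
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError("duplicate IDs in table file")
    if not samples_as_rows:
        df = df.T
    return OtuTable.from_dataframe(df)


def write_otu_table(table: OtuTable, path, samples_as_rows: bool = False) -> None:
    df = table.to_dataframe()
    if not samples_as_rows:
        df = df.T
    df.to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; midpoint-root unrooted input.

    A tree is treated as unrooted when its root has more than two children
    (the usual serialization of unrooted trees).  Branch lengths must be
    non-negative; a missing root branch length is taken as zero.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise ValidationError(f"unparseable Newick file {path}: {exc}") from exc
    return _prepare_tree(tree)


def _prepare_tree(tree: TreeNode) -> TreeNode:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValidationError(f"negative branch length on node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate leaf labels in tree")
    if len(tree.children) > 2:
        tree = tree.root_at_midpoint()
    return tree


def parse_tree(newick: str) -> TreeNode:
    """Parse a Newick string (same contract as :func:`read_tree`)."""
    try:
        tree = TreeNode.read(_io.StringIO(newick), format="newick")
    except Exception as exc:
        raise ValidationError(f"unparseable Newick string: {exc}") from exc
    return _prepare_tree(tree)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a two-column (OTU, lineage) tab-delimited taxonomy file.

    Lineages are semicolon-delimited, coarsest rank first; Greengenes-style
    prefixes (``p__Firmicutes``) are stripped.  Missing ranks become the
    explicit placeholder ``unclassified``.
    """
    raw = pd.read_csv(path, sep="\t", header=None, names=["otu", "lineage"], dtype=str)
    if raw["otu"].duplicated().any():
        dupes = raw["otu"][raw["otu"].duplicated()].tolist()
        raise ValidationError(f"duplicate OTU IDs in taxonomy: {dupes}")
    rows = {}
    for otu, lineage in zip(raw["otu"], raw["lineage"]):
        fields = [f.strip() for f in str(lineage).split(";")]
        entry = {r: "unclassified" for r in TAXONOMIC_RANKS}
        for pos, f in enumerate(fields):
            if "__" in f:
                prefix, _, name = f.partition("__")
                rank = _RANK_PREFIXES.get(prefix.strip())
                if rank is None:
                    continue
            else:
                if pos >= len(TAXONOMIC_RANKS):
                    continue
                rank, name = TAXONOMIC_RANKS[pos], f
            entry[rank] = name if name else "unclassified"
        rows[otu] = entry
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(TAXONOMIC_RANKS))


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for otu, row in taxonomy.iterrows():
            lineage = ";".join(
                f"{rank[0]}__{row[rank]}" if row[rank] != "unclassified" else f"{rank[0]}__"
                for rank in TAXONOMIC_RANKS
            )
            fh.write(f"{otu}\t{lineage}\n")


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype=str)
    validate_metadata(md)
    if "depth" in md.columns:
        md["depth"] = md["depth"].astype(int)
    return md


def validate_metadata(md: pd.DataFrame, sample_ids=None) -> None:
    """Check required columns and, optionally, coverage of a sample list."""
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    if md["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    if sample_ids is not None:
        absent = sorted(set(sample_ids) - set(md["sample_id"]))
        if absent:
            raise ValidationError(f"samples without metadata rows: {absent}")


def write_metadata(md: pd.DataFrame, path) -> None:
    md.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Rarefaction and proportions
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int = 20_000, seed: int | None = None,
           rng: np.random.Generator | None = None) -> tuple[OtuTable, list[str]]:
    """Subsample each sample's reads to a common depth, without replacement.

    Each retained sample's counts become a multivariate-hypergeometric draw of
    exactly ``depth`` reads from its observed reads, so rarefied counts never
    exceed the originals and row sums equal ``depth``.  Samples whose total is
    below ``depth`` cannot be subsampled and are dropped.

    Returns
    -------
    (rarefied_table, dropped_sample_ids)

    Raises
    ------
    ValidationError
        If ``depth < 1`` or no sample reaches the requested depth.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    totals = table.depths
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise ValidationError(f"no samples retained at rarefaction depth {depth}")
    out = np.empty((int(keep.sum()), table.n_features), dtype=np.int64)
    row = 0
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            out[row] = table.counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(table.counts[i], depth)
        row += 1
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return OtuTable(out, kept_ids, table.feature_ids), dropped


def to_proportions(table: OtuTable) -> np.ndarray:
    """Row-normalize counts to relative abundances (rows sum to 1)."""
    totals = table.depths
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValidationError(f"zero-depth samples cannot be normalized: {bad}")
    return table.counts / totals[:, None]
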