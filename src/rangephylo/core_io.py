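"""Trees, tables and their cross-validation.

The pipeline consumes three inputs: a rooted, branch-length-bearing
phylogeny covering the regional species pool (Newick), a plot-by-species
abundance matrix (delimited text, plots as rows), and a per-plot
environment table (elevation in metres, latitude/longitude in decimal
degrees).  This module reads and validates them, reconciles their name
spaces, and derives the patristic (tip-to-tip path length) distance
matrix on which every phylogenetic metric downstream is based.

Trees are :class:`dendropy.Tree` objects throughout; multifurcations are
accepted as-is because patristic distances are well defined on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "PatristicMatrix",
    "normalize_name",
    "read_phylogeny",
    "validate_phylogeny",
    "ultrametricity_gap",
    "patristic_distances",
    "read_community",
    "write_community",
    "read_environment",
    "write_environment",
    "harmonize",
]


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


class ValidationError(ValueError):
    """Parsed input violates a structural invariant."""


def normalize_name(name: str) -> str:
    """Canonical species/plot identifier: trimmed, spaces -> underscores.

    Matching between tree tips, community columns and environment rows is
    exact-string after this normalisation; no fuzzy taxonomy matching.
    """
    return str(name).strip().replace(" ", "_")


# ---------------------------------------------------------------------------
# Phylogeny


def validate_phylogeny(tree: dendropy.Tree) -> dendropy.Tree:
    """Check tree invariants in place and return the tree.

    Requires >=2 uniquely-labelled tips and non-negative branch lengths.
    Missing branch lengths are set to 0.0 (zero-length branches are legal);
    negative lengths are rejected.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValidationError(f"tree has {len(leaves)} tips; need at least 2")
    labels = []
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValidationError("tree contains an unlabelled tip")
        labels.append(normalize_name(leaf.taxon.label))
        leaf.taxon.label = labels[-1]
    dupes = {lb for lb in labels if labels.count(lb) > 1}
    if dupes:
        raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
        elif edge.length < 0:
            raise ValidationError(
                f"negative branch length {edge.length} above "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'}"
            )
    return tree


def read_phylogeny(path) -> dendropy.Tree:
    """Read a rooted Newick tree and validate it."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon" in str(exc):
            raise ValidationError(f"duplicate tip labels in {path}: {exc}") from exc
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    tree.is_rooted = True
    return validate_phylogeny(tree)


def tree_from_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string (convenience wrapper used heavily in tests)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        if "Duplicate taxon" in str(exc):
            raise ValidationError(f"duplicate tip labels: {exc}") from exc
        raise FormatError(f"cannot parse Newick string: {exc}") from exc
    tree.is_rooted = True
    return validate_phylogeny(tree)


def ultrametricity_gap(tree: dendropy.Tree) -> float:
    """Max minus min root-to-tip depth.

    Reported as a diagnostic only: a dated (chronogram) tree should have a
    gap near zero, but none of the metrics here require ultrametricity.
    """
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return float(max(depths) - min(depths))


@dataclass
class PatristicMatrix:
    """Square matrix of tip-to-tip path-length sums on a tree."""

    labels: list[str]
    values: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        self._index = {lb: i for i, lb in enumerate(self.labels)}

    def indices(self, species) -> np.ndarray:
        return np.array([self._index[normalize_name(s)] for s in species], dtype=int)

    def submatrix(self, species) -> np.ndarray:
        idx = self.indices(species)
        return self.values[np.ix_(idx, idx)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels) -> "PatristicMatrix":
        idx = self.indices(labels)
        return PatristicMatrix(list(labels), self.values[np.ix_(idx, idx)])


def patristic_distances(tree: dendropy.Tree) -> PatristicMatrix:
    """Pairwise patristic distances between all tips.

    Computed by accumulating each tip's depth below every ancestor, so a
    pair's distance is depth(i) + depth(j) below their MRCA; O(n^2) time.
    """
    leaves = tree.leaf_nodes()
    labels = [leaf.taxon.label for leaf in leaves]
    n = len(leaves)
    pos = {id(leaf): i for i, leaf in enumerate(leaves)}
    # depth of every tip below each internal node, built postorder
    below: dict[int, dict[int, float]] = {}
    d = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = {pos[id(node)]: 0.0}
            continue
        groups = []
        for child in node.child_nodes():
            sub = below.pop(id(child))
            bl = child.edge.length or 0.0
            groups.append({tip: dep + bl for tip, dep in sub.items()})
        merged: dict[int, float] = {}
        for gi, g in enumerate(groups):
            for h in groups[gi + 1 :]:
                for ti, di in g.items():
                    for tj, dj in h.items():
                        d[ti, tj] = d[tj, ti] = di + dj
            merged.update(g)
        below[id(node)] = merged
    return PatristicMatrix(labels, d)


# ---------------------------------------------------------------------------
# Tabular inputs


def read_community(path, sep: str = "\t") -> pd.DataFrame:
    """Plot-by-species abundance matrix; plots as rows, header = species."""
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot read community table {path}: {exc}") from exc
    return validate_community(df)


def validate_community(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.index = [normalize_name(p) for p in df.index]
    df.columns = [normalize_name(s) for s in df.columns]
    if df.index.has_duplicates:
        raise ValidationError("duplicate plot ids in community matrix")
    if df.columns.has_duplicates:
        raise ValidationError("duplicate species ids in community matrix")
    values = df.to_numpy()
    if not np.isfinite(values).all():
        raise ValidationError("community matrix contains non-finite entries")
    if (values < 0).any():
        raise ValidationError("community matrix contains negative abundances")
    if not np.allclose(values, np.round(values)):
        raise ValidationError("community abundances must be integer counts")
    return df.astype(int)


def write_community(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="plot_id")


def read_environment(path, sep: str = "\t") -> pd.DataFrame:
    """Per-plot environment table: elevation (m), latitude/longitude (deg)."""
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot read environment table {path}: {exc}") from exc
    return validate_environment(df)


def validate_environment(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.index = [normalize_name(p) for p in df.index]
    if df.index.has_duplicates:
        raise ValidationError("duplicate plot ids in environment table")
    missing = {"elevation", "latitude"} - set(df.columns)
    if missing:
        raise ValidationError(f"environment table lacks columns: {sorted(missing)}")
    if not np.isfinite(df["elevation"].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite elevations")
    lat = df["latitude"].to_numpy(dtype=float)
    if not np.isfinite(lat).all() or (np.abs(lat) > 90).any():
        raise ValidationError("latitudes must be finite and within [-90, 90]")
    return df


def write_environment(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="plot_id")


# ---------------------------------------------------------------------------
# Harmonisation


def harmonize(
    tree: dendropy.Tree, comm: pd.DataFrame, env: pd.DataFrame
) -> tuple[dendropy.Tree, pd.DataFrame, pd.DataFrame]:
    """Reconcile tree tips, community columns and environment rows.

    The tree is pruned to species present in the community matrix, the
    matrix restricted to tree tips, and plots restricted to those present
    in both the matrix and the environment table.  Dropped names are
    logged.  Idempotent; raises ``ValidationError`` if either intersection
    is empty.
    """
    tree = validate_phylogeny(tree.clone(depth=1))
    comm = validate_community(comm)
    env = validate_environment(env)

    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    shared_sp = [s for s in comm.columns if s in tip_labels]
    if not shared_sp:
        raise ValidationError("no species shared between tree and community matrix")
    dropped_tips = sorted(tip_labels - set(shared_sp))
    dropped_cols = [s for s in comm.columns if s not in tip_labels]
    if dropped_tips:
        logger.info("harmonize: pruning %d tree tips absent from the community: %s",
                    len(dropped_tips), dropped_tips)
        tree = tree.extract_tree_with_taxa_labels(shared_sp)
        tree.is_rooted = True
        tree = validate_phylogeny(tree)
    if dropped_cols:
        logger.info("harmonize: dropping %d species absent from the tree: %s",
                    len(dropped_cols), dropped_cols)

    shared_plots = [p for p in comm.index if p in set(env.index)]
    if not shared_plots:
        raise ValidationError("no plots shared between community matrix and environment")
    dropped_plots = sorted((set(comm.index) | set(env.index)) - set(shared_plots))
    if dropped_plots:
        logger.info("harmonize: dropping %d plots not present in both tables: %s",
                    len(dropped_plots), dropped_plots)

    comm = comm.loc[shared_plots, shared_sp]
    env = env.loc[shared_plots]
    empty = comm.index[(comm.sum(axis=1) == 0)]
    if len(empty):
        logger.warning("harmonize: %d plots have zero total abundance: %s",
                       len(empty), list(empty))
    return tree, comm, env
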