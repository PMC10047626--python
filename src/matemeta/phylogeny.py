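"""Tree calibration and the Brownian-motion correlation matrix.

Supertrees assembled from topology-only sources carry no meaningful branch
lengths, so every input tree is calibrated with Grafen's method: each
internal node is placed at height (number of descendant tips - 1) ** rho,
heights are normalized so the root sits at 1 and tips at 0, and edge lengths
are the parent-child height differences.  The result is ultrametric with
root-to-tip depth 1.

Under Brownian motion on such a tree, the expected correlation between trait
values of two species equals the depth (from the root) of their most recent
common ancestor; the resulting matrix enters the meta-analytic model as the
correlation structure of the phylogenetic random effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCorrelation",
    "TreeError",
    "normalize_label",
    "read_newick",
    "tree_from_string",
    "grafen_calibrate",
    "brownian_correlation",
    "prune",
]

ULTRAMETRIC_TOL = 1e-9


class TreeError(ValueError):
    """Malformed or unusable tree input."""


def normalize_label(label: str) -> str:
    """Canonical species key: strip, spaces to underscores, case-folded."""
    return label.strip().replace(" ", "_").casefold()


@dataclass
class PhyloTree:
    """A rooted tree with (possibly calibrated) branch lengths.

    Wraps a :class:`dendropy.Tree`; tip labels are exposed verbatim while
    matching is done on normalized labels.
    """

    tree: dendropy.Tree
    calibrated: bool = False

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        norm = [normalize_label(x) for x in labels]
        if len(set(norm)) != len(norm):
            dupes = sorted({x for x in norm if norm.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if not self.tree.is_rooted:
            raise TreeError("tree is unrooted; root it before calibration")

    @property
    def tip_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def normalized_tip_labels(self) -> dict[str, str]:
        """Map normalized label -> original tip label."""
        return {normalize_label(x): x for x in self.tip_labels}

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path lengths keyed by tip label."""
        out: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            parent_depth = 0.0 if node.parent_node is None else node.parent_node._depth
            node._depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                out[node.taxon.label] = node._depth
        return out

    def is_ultrametric(self, depth: float = 1.0, tol: float = ULTRAMETRIC_TOL) -> bool:
        d = np.array(list(self.depths().values()))
        return bool(np.max(np.abs(d - depth)) < tol)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


@dataclass
class PhyloCorrelation:
    """Brownian correlation matrix over an ordered set of species labels."""

    labels: list[str]
    matrix: np.ndarray
    label_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.min(np.linalg.eigvalsh(m)) < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.label_index = {normalize_label(x): i for i, x in enumerate(self.labels)}

    def submatrix(self, labels: list[str]) -> np.ndarray:
        idx = [self.label_index[normalize_label(x)] for x in labels]
        return self.matrix[np.ix_(idx, idx)]


def read_newick(path) -> PhyloTree:
    """Load a rooted Newick tree; polytomies are permitted and preserved."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick file {path}: {exc}") from exc
    return PhyloTree(tree)


def tree_from_string(newick: str) -> PhyloTree:
    """Parse a Newick string (convenience twin of :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"could not parse Newick string: {exc}") from exc
    return PhyloTree(tree)


def grafen_calibrate(ptree: PhyloTree, rho: float = 1.0) -> PhyloTree:
    """Assign Grafen node heights and return an ultrametric depth-1 tree.

    Internal nodes get height (descendant tips - 1) ** rho, normalized by the
    root height; tips sit at height 0.  Edge length = parent height - child
    height, which is nonnegative because tip counts are monotone up the tree.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    tree = ptree.tree.clone(depth=1)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._ntips = 1
        else:
            node._ntips = sum(ch._ntips for ch in node.child_nodes())
    root = tree.seed_node
    root_height = float(root._ntips - 1) ** rho
    if root_height <= 0:
        raise TreeError("root must subtend at least 2 tips")
    for node in tree.preorder_node_iter():
        n = node._ntips
        node._height = 0.0 if n == 1 else float(n - 1) ** rho / root_height
        if node.parent_node is not None:
            node.edge.length = node.parent_node._height - node._height
        else:
            node.edge.length = None
    return PhyloTree(tree, calibrated=True)


def brownian_correlation(ptree: PhyloTree) -> PhyloCorrelation:
    """Correlation matrix implied by Brownian evolution on a depth-1 tree.

    Entry (i, j) is the root-to-MRCA depth of tips i and j; the diagonal is
    1.  Requires an ultrametric tree of depth 1 (the correlation reading of
    shared path length is invalid otherwise).
    """
    if not ptree.is_ultrametric(1.0):
        raise TreeError(
            "tree is not ultrametric with depth 1; calibrate it first "
            "(grafen_calibrate)"
        )
    labels = ptree.tip_labels
    index = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    mat = np.zeros((n, n))

    tree = ptree.tree
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._depth
        node._depth = parent_depth + (node.edge.length or 0.0)
    # Tips whose MRCA is a given node lie in different child subtrees of it.
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipidx = [index[node.taxon.label]]
            continue
        blocks = [ch._tipidx for ch in node.child_nodes()]
        for i, bi in enumerate(blocks):
            for bj in blocks[i + 1:]:
                mat[np.ix_(bi, bj)] = node._depth
                mat[np.ix_(bj, bi)] = node._depth
        node._tipidx = [t for b in blocks for t in b]
    np.fill_diagonal(mat, 1.0)
    return PhyloCorrelation(labels, mat)


def prune(ptree: PhyloTree, keep, recalibrate: bool = True,
          rho: float = 1.0) -> PhyloTree:
    """Induced subtree on ``keep``; recalibrated by default.

    With ``recalibrate=False`` the calibrated branch lengths are inherited
    (path lengths between retained tips are preserved, so a depth-1 input
    stays depth-1).
    """
    want = {normalize_label(x) for x in keep}
    have = ptree.normalized_tip_labels
    missing = sorted(want - set(have))
    if missing:
        raise TreeError(f"species not in tree: {missing}")
    if len(want) < 2:
        raise TreeError("need at least 2 species to prune to")
    sub = ptree.tree.extract_tree_with_taxa_labels(
        labels=[have[w] for w in sorted(want)],
        suppress_unifurcations=True,
    )
    sub.is_rooted = True
    out = PhyloTree(sub, calibrated=ptree.calibrated)
    if recalibrate:
        out = grafen_calibrate(out, rho=rho)
    return out
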