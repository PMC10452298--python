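"""Phylogenetic trees and the shared-branch-length covariance matrix.

A rooted tree with branch lengths induces, under a Brownian-motion model of
trait evolution, a species-by-species covariance matrix ``C`` whose entry
``c_ij`` is the total branch length shared by the root-to-tip paths of tips
*i* and *j* (the depth of their most recent common ancestor) and whose
diagonal ``c_ii`` is the root-to-tip path length of tip *i*.  This matrix is
the dependence structure that the phylogenetic regression models embed in
their estimating equations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "NewickParseError",
    "PhyloTree",
    "PhyloCovariance",
    "parse_newick",
    "tree_to_covariance",
    "scale_tree",
    "generate_tree",
]


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed into a valid tree."""


class PhyloTree:
    """A rooted phylogenetic tree with branch lengths on every edge.

    Thin wrapper over :class:`dendropy.Tree` that enforces the invariants the
    regression machinery relies on: unique tip labels, non-negative branch
    lengths present on every non-root edge.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) < 1:
            raise NewickParseError("tree has no tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate tip labels: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                raise NewickParseError(
                    f"missing branch length on edge above {_node_name(node)}"
                )
            if node.edge.length < 0:
                raise NewickParseError(
                    f"negative branch length ({node.edge.length}) above "
                    f"{_node_name(node)}"
                )

    # -- basic queries -----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in the order they appear in the newick string."""
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip (the root edge, if any, is ignored)."""
        depths: dict[str, float] = {}
        node_depth = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            node_depth[node] = node_depth[node.parent_node] + node.edge.length
            if node.is_leaf():
                depths[node.taxon.label] = node_depth[node]
        return depths

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        d = self.tip_depths()
        return max(d.values()) if d else 0.0

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(np.all(np.abs(d - d[0]) <= rel_tol * max(d.max(), 1.0)))

    # -- output ------------------------------------------------------------

    def write_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhyloTree with {self.n_tips} tips, height {self.height:g}>"


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return repr(node.taxon.label)
    return "an internal node"


@dataclass
class PhyloCovariance:
    """The n-by-n matrix of shared branch lengths, with its tip ordering.

    ``matrix[i, j]`` is the depth of the most recent common ancestor of tips
    ``labels[i]`` and ``labels[j]``; the diagonal holds root-to-tip depths.
    """

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"covariance shape {self.matrix.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def is_psd(self, tol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh(self.matrix)
        return bool(w.min() >= -tol * max(1.0, abs(w.max())))

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        """Return a copy with rows/columns permuted into the given label order."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"labels not in covariance: {missing}")
        idx = [pos[l] for l in labels]
        return PhyloCovariance(list(labels), self.matrix[np.ix_(idx, idx)])

    def correlation(self) -> np.ndarray:
        """Standardize to unit diagonal (used for the Gaussian copula).

        Tips with zero depth have no Brownian variance; their latent
        correlation with everything is taken as 0.
        """
        d = np.sqrt(np.diag(self.matrix))
        with np.errstate(divide="ignore", invalid="ignore"):
            R = self.matrix / np.outer(d, d)
        R[~np.isfinite(R)] = 0.0
        np.fill_diagonal(R, 1.0)
        return R

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


# ---------------------------------------------------------------------------
# operations


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string (branch lengths required on every edge).

    Internal node labels are tolerated and ignored; trailing whitespace is
    tolerated.  Malformed input raises :class:`NewickParseError` naming the
    position dendropy reports.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"newick parse error: {exc}") from exc
    return PhyloTree(tree)


def tree_to_covariance(tree: PhyloTree) -> PhyloCovariance:
    """Compute C: shared root-to-MRCA branch length for every tip pair.

    Each non-root edge contributes its length to ``c_ij`` for every pair of
    tips (including i = j) in the clade below it, so the diagonal accumulates
    tip depths and off-diagonals accumulate MRCA depths.
    """
    dtree = tree._tree
    leaves = list(dtree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    # postorder pass collecting the tip set under each node
    below: dict[int, np.ndarray] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            tips = np.array([index[id(node)]])
        else:
            tips = np.concatenate([below.pop(id(ch)) for ch in node.child_nodes()])
        below[id(node)] = tips
        if node is not dtree.seed_node:
            C[np.ix_(tips, tips)] += node.edge.length
    return PhyloCovariance(labels, C)


def scale_tree(tree: PhyloTree, target_height: float) -> PhyloTree:
    """Uniformly rescale branch lengths so the deepest tip sits at *target_height*."""
    if target_height <= 0:
        raise ValueError("target_height must be positive")
    h = tree.height
    if h <= 0:
        raise ValueError("cannot scale a zero-height tree")
    factor = target_height / h
    out = tree.copy()
    for node in out._tree.preorder_node_iter():
        if node is not out._tree.seed_node and node.edge.length is not None:
            node.edge.length *= factor
    return out


# -- tree generators --------------------------------------------------------

TREE_KINDS = ("coalescent", "balanced", "left", "star")


def generate_tree(kind: str, n: int, seed: int | None = None) -> PhyloTree:
    """Generate an ultrametric tree of unit height.

    Parameters
    ----------
    kind:
        ``"coalescent"`` — Kingman-style exchangeable pairwise coalescence
        with exponential waiting times, rescaled to unit height (seeded);
        ``"balanced"`` — equal-depth nested splits (n must be a power of 2);
        ``"left"`` — pectinate (caterpillar) topology with split depths
        equally spaced; ``"star"`` — all tips attached to the root.
    n:
        number of tips (>= 2).
    seed:
        RNG seed; only the coalescent kind draws random numbers.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    if kind == "star":
        newick = "(" + ",".join(f"t{i}:1" for i in range(1, n + 1)) + ");"
        return parse_newick(newick)
    if kind == "balanced":
        if n & (n - 1):
            raise ValueError("balanced tree requires n to be a power of 2")
        levels = int(np.log2(n))
        step = 1.0 / levels

        def build(lo: int, hi: int) -> str:
            if hi - lo == 1:
                return f"t{lo + 1}:{step:.17g}"
            mid = (lo + hi) // 2
            return f"({build(lo, mid)},{build(mid, hi)}):{step:.17g}"

        mid = n // 2
        newick = f"({build(0, mid)},{build(mid, n)});"
        return parse_newick(newick)
    if kind == "left":
        # split depths 0, 1/(n-1), ..., (n-2)/(n-1); all tips at depth 1
        gap = 1.0 / (n - 1)
        sub = f"t{n}:{gap:.17g},t{n - 1}:{gap:.17g}"
        for k in range(n - 2, 0, -1):
            depth = (k - 1) * gap
            tip_len = 1.0 - depth
            sub = f"({sub}):{gap:.17g},t{k}:{tip_len:.17g}"
        return parse_newick(f"({sub});")
    if kind == "coalescent":
        return _kingman_tree(n, seed)
    raise ValueError(f"unknown tree kind {kind!r}; expected one of {TREE_KINDS}")


def _kingman_tree(n: int, seed: int | None) -> PhyloTree:
    rng = np.random.default_rng(seed)
    # node ages measured from the present (tips at age 0)
    nodes = [f"t{i + 1}:" for i in range(n)]  # newick fragments missing lengths
    ages = [0.0] * n
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(j)
        bj = ages.pop(j)
        a = nodes.pop(i)
        bi = ages.pop(i)
        frag = f"({a}{t - bi:.17g},{b}{t - bj:.17g}):"
        nodes.append(frag)
        ages.append(t)
    newick = nodes[0][:-1] + ";"
    tree = parse_newick(newick)
    return scale_tree(tree, 1.0)
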