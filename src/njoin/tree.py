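"""Unrooted trees with branch lengths: Newick I/O, patristic matrices, RF.

Trees are thin wrappers around :class:`dendropy.Tree`, treated as unrooted
throughout: neighbor joining produces unrooted trees, and Robinson–Foulds
comparison between rooted and unrooted trees is ill-defined.  Rooted Newick
input is unrooted on parse by suppressing the degree-2 root.
"""

from __future__ import annotations

from typing import Iterable

import dendropy
import numpy as np

from .errors import NewickParseError, ValidationError
from .matrix import DistanceMatrix

__all__ = ["Tree", "parse_newick", "write_newick", "patristic_matrix", "rf_distance"]


class Tree:
    """An unrooted, edge-weighted tree with uniquely labeled leaves."""

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = False
        seed = dtree.seed_node
        if seed is not None and len(seed.child_nodes()) == 2 and len(dtree.leaf_nodes()) > 2:
            dtree.collapse_basal_bifurcation()
        self._dt = dtree
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate leaf labels in tree")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string; missing branch lengths default to 0."""
        text = text.strip()
        if not text:
            raise NewickParseError("empty Newick string")
        if not text.endswith(";"):
            raise NewickParseError(
                f"Newick string must end with ';' (position {len(text)})"
            )
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
                rooting="force-unrooted",
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise NewickParseError(f"malformed Newick: {exc}") from None
        for edge in dt.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
        return cls(dt)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        """Newick string with ';' terminator and full-precision lengths."""
        s = self._dt.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
            unquoted_underscores=True,
        )
        return s.strip()

    def __str__(self) -> str:
        return self.to_newick()

    # -- structure ---------------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._dt.leaf_node_iter() if lf.taxon]

    @property
    def n_leaves(self) -> int:
        return len(self._dt.leaf_nodes())

    def n_edges(self) -> int:
        return sum(1 for e in self._dt.preorder_edge_iter() if e.head_node is not self._dt.seed_node)

    def is_binary(self) -> bool:
        """True when every internal vertex has degree 3 (unrooted sense)."""
        for nd in self._dt.preorder_node_iter():
            deg = len(nd.child_nodes()) + (0 if nd is self._dt.seed_node else 1)
            if not nd.is_leaf() and deg != 3:
                return False
        return True

    # -- derived quantities ------------------------------------------------

    def patristic_matrix(self, clamp_negative: bool = False) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (labels in tree taxon order).

        Negative branch lengths are rejected unless ``clamp_negative`` maps
        them to 0 first.  For a tree realizing a metric exactly, the result
        satisfies the four-point condition up to accumulation error.
        """
        dt = self._dt
        neg = [e for e in dt.preorder_edge_iter() if e.length is not None and e.length < 0]
        if neg and not clamp_negative:
            raise ValidationError("tree has negative branch lengths (pass clamp_negative=True)")
        if neg:
            dt = self._dt.clone(depth=1)
            for e in dt.preorder_edge_iter():
                if e.length is not None and e.length < 0:
                    e.length = 0.0
        pdm = dt.phylogenetic_distance_matrix()
        taxa = [lf.taxon for lf in dt.leaf_node_iter()]
        labels = [t.label for t in taxa]
        n = len(taxa)
        sq = np.zeros((n, n))
        for i in range(n):
            for k in range(i):
                sq[i, k] = sq[k, i] = pdm.patristic_distance(taxa[i], taxa[k])
        return DistanceMatrix.from_square(labels, sq)

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial bipartitions, each keyed by the leaf set on the side not
        containing the lexicographically smallest label."""
        labels = set(self.leaf_labels())
        anchor = min(labels)
        out: set[frozenset] = set()
        for nd in self._dt.preorder_node_iter():
            if nd is self._dt.seed_node or nd.is_leaf():
                continue
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            side = frozenset(labels - below) if anchor in below else below
            if 2 <= len(side) <= len(labels) - 2:
                out.add(side)
        return out

    def edge_length_map(self) -> dict[frozenset, float]:
        """Map every edge (pendant and internal) to its length, keyed by the
        anchor-free side of its bipartition.  Suitable for comparing branch
        lengths of two same-topology trees."""
        labels = set(self.leaf_labels())
        anchor = min(labels)
        out: dict[frozenset, float] = {}
        for nd in self._dt.preorder_node_iter():
            if nd is self._dt.seed_node:
                continue
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            side = frozenset(labels - below) if anchor in below else below
            if 1 <= len(side) <= len(labels) - 1:
                out[side] = out.get(side, 0.0) + (nd.edge.length or 0.0)
        return out

    def rf_distance(self, other: "Tree") -> tuple[int, float]:
        """Robinson–Foulds distance: (symmetric-difference count, normalized).

        The normalization denominator is the total number of nontrivial
        bipartitions in both trees (``2(n-3)`` for two binary trees), giving a
        value in [0, 1].  Both trees must share the same leaf label set.
        """
        la, lb = set(self.leaf_labels()), set(other.leaf_labels())
        if la != lb:
            raise ValidationError("rf_distance requires identical leaf label sets")
        ba, bb = self.bipartitions(), other.bipartitions()
        rf = len(ba ^ bb)
        denom = len(ba) + len(bb)
        return rf, (rf / denom if denom else 0.0)

    def copy(self) -> "Tree":
        return Tree(self._dt.clone(depth=1))


# -- module-level functional surface ---------------------------------------


def parse_newick(text: str) -> Tree:
    return Tree.from_newick(text)


def write_newick(t: Tree) -> str:
    return t.to_newick()


def patristic_matrix(t: Tree, clamp_negative: bool = False) -> DistanceMatrix:
    return t.patristic_matrix(clamp_negative=clamp_negative)


def rf_distance(a: Tree, b: Tree) -> tuple[int, float]:
    return a.rf_distance(b)


def build_tree(
    labels: list[str],
    joins: Iterable,
    center: list[tuple[int, float]] | None,
    pair: tuple[int, int, float] | None = None,
) -> Tree:
    """Assemble an unrooted tree from neighbor-joining output.

    ``joins`` is a sequence of JoinEvents whose handles index ``labels`` for
    leaves (0..n-1) and earlier events for internal nodes.  ``center`` lists
    the (handle, length) spokes of the terminal vertex for n >= 3; ``pair``
    is the 2-leaf degenerate case ``(h1, h2, distance)``.
    """
    tns = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    for h, label in enumerate(labels):
        nd = dendropy.Node()
        nd.taxon = tns.new_taxon(label=label)
        nodes[h] = nd
    for ev in joins:
        z = dendropy.Node()
        for h, bl in ((ev.x, ev.bx), (ev.y, ev.by)):
            child = nodes[h]
            z.add_child(child)
            child.edge.length = float(bl)
        nodes[ev.z] = z
    if pair is not None:
        h1, h2, d = pair
        seed = dendropy.Node()
        for h, bl in ((h1, d / 2.0), (h2, d / 2.0)):
            child = nodes[h]
            seed.add_child(child)
            child.edge.length = float(bl)
    elif center is not None:
        seed = dendropy.Node()
        for h, bl in center:
            child = nodes[h]
            seed.add_child(child)
            child.edge.length = float(bl)
    else:  # single leaf
        seed = nodes[0]
    dt = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    dt.is_rooted = False
    return Tree(dt)
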