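"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import njoin


def branch_length_gap(a: njoin.Tree, b: njoin.Tree) -> float:
    """Max absolute difference between matching edges of two trees, keyed by
    bipartition; +inf when the topologies differ."""
    ma, mb = a.edge_length_map(), b.edge_length_map()
    if set(ma) != set(mb):
        return float("inf")
    return max(abs(ma[k] - mb[k]) for k in ma) if ma else 0.0


def assert_same_tree(a: njoin.Tree, b: njoin.Tree, tol: float = 1e-9) -> None:
    rf, _ = a.rf_distance(b)
    assert rf == 0, f"topologies differ (RF={rf})"
    gap = branch_length_gap(a, b)
    assert gap <= tol, f"branch lengths differ by {gap}"


@pytest.fixture
def worked_tree() -> njoin.Tree:
    """The five-edge reference tree A-u:1, B-u:2, u-v:2, C-v:3, D-v:4."""
    return njoin.parse_newick("((A:1,B:2):2,C:3,D:4);")


@pytest.fixture
def worked_matrix(worked_tree) -> njoin.DistanceMatrix:
    """Additive matrix of the reference tree, labels A..D."""
    return worked_tree.patristic_matrix()


@pytest.fixture
def abc_matrix() -> njoin.DistanceMatrix:
    """3-taxon matrix D(B,A)=2, D(C,A)=3, D(C,B)=4."""
    return njoin.DistanceMatrix(["A", "B", "C"], [[], [2.0], [3.0, 4.0]])


def random_matrix(rng: np.random.Generator, n: int) -> njoin.DistanceMatrix:
    """Arbitrary (not necessarily metric) non-negative symmetric matrix."""
    sq = rng.uniform(0.1, 5.0, size=(n, n))
    sq = (sq + sq.T) / 2
    np.fill_diagonal(sq, 0.0)
    return njoin.DistanceMatrix.from_square([f"t{i}" for i in range(n)], sq)
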