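"""Seeded generators of trees and distance matrices for testing and audits.

Every generator is a pure function of its parameters and seed (NumPy PCG64
via ``default_rng``), so suites replay identically across machines.  The
fixtures emulate the regimes relevant to NJ search behavior:

- additive matrices (patristic distances of random binary trees) — the case
  where both exact and heuristic variants must reproduce canonical NJ;
- Euclidean / cosine point-cloud matrices — metric inputs for the
  lower-bound diagnostics;
- clustered Gaussian-mixture matrices — hierarchically structured data where
  the dynamic search rescans few rows per iteration;
- the equal-distance star matrix — the adversarial case where nearly every
  row must be rescanned every iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .matrix import DistanceMatrix
from .tree import Tree, build_tree
from .core import JoinEvent

__all__ = [
    "random_binary_tree",
    "additive_matrix",
    "metric_matrix",
    "perturb",
    "clustered_matrix",
    "star_matrix",
]


def _labels(n: int) -> list[str]:
    return [f"t{i + 1}" for i in range(n)]


def random_binary_tree(
    n: int, seed: int, length_range: tuple[float, float] = (0.1, 2.0)
) -> Tree:
    """Random binary unrooted tree over leaves ``t1..tn``.

    Topology is grown by repeatedly attaching the next leaf to a uniformly
    chosen existing edge; branch lengths are then drawn i.i.d. uniform from
    ``length_range``.  Deterministic for a fixed seed.
    """
    lo, hi = length_range
    if n < 2:
        raise ValidationError("random_binary_tree requires n >= 2")
    if not (0 < lo <= hi):
        raise ValidationError("length_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    if n == 2:
        d = float(rng.uniform(lo, hi))
        return build_tree(_labels(2), [], None, pair=(0, 1, d))
    # Leaves are handles 0..n-1; internal vertices get handles n, n+1, ...
    edges: list[list[int]] = [[0, 1]]
    nxt = n
    for leaf in range(2, n):
        eidx = int(rng.integers(len(edges)))
        u, v = edges[eidx]
        w = nxt
        nxt += 1
        edges[eidx] = [u, w]
        edges.append([w, v])
        edges.append([w, leaf])
    lengths = rng.uniform(lo, hi, size=len(edges))

    # Orient the tree from an internal vertex and express it as join events
    # so build_tree can assemble it: every internal vertex except the chosen
    # center has exactly two children once rooted at the center.
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), L in zip(edges, lengths):
        adj.setdefault(u, []).append((v, float(L)))
        adj.setdefault(v, []).append((u, float(L)))
    center = n  # first internal vertex (exists for n >= 3)
    joins: list[JoinEvent] = []
    order: dict[int, int] = {h: h for h in range(n)}  # handle remap for build_tree

    def collect(v: int, parent: int) -> int:
        kids = [(c, L) for c, L in adj[v] if c != parent]
        if not kids:
            return order[v]
        (a, la), (b, lb) = kids
        ha, hb = collect(a, v), collect(b, v)
        h = len(order)
        order[v] = h
        joins.append(JoinEvent(ha, hb, h, la, lb))
        return h

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 100))
    try:
        spokes = [(collect(c, center), L) for c, L in adj[center]]
    finally:
        sys.setrecursionlimit(old)
    return build_tree(_labels(n), joins, spokes)


def additive_matrix(
    n: int, seed: int, length_range: tuple[float, float] = (0.1, 2.0)
) -> DistanceMatrix:
    """Strictly additive matrix: patristic distances of a random binary tree.
    Satisfies the four-point condition by construction."""
    return random_binary_tree(n, seed, length_range).patristic_matrix()


def metric_matrix(
    n: int, seed: int, dim: int = 8, metric: str = "euclidean"
) -> DistanceMatrix:
    """Distances between ``n`` i.i.d. standard-normal points in ``dim``
    dimensions; ``euclidean`` (exactly metric) or ``cosine`` (1 - cos)."""
    if n < 2 or dim < 1:
        raise ValidationError("metric_matrix requires n >= 2 and dim >= 1")
    if metric not in ("euclidean", "cosine"):
        raise ValidationError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, dim))
    sq = squareform(pdist(pts, metric=metric))
    return DistanceMatrix.from_square(_labels(n), np.maximum(sq, 0.0))


def perturb(m: DistanceMatrix, noise: float, seed: int) -> DistanceMatrix:
    """Multiply every cell by an independent uniform draw from
    ``[1 - noise, 1 + noise]``; preserves non-negativity for noise < 1."""
    if not 0 <= noise < 1:
        raise ValidationError("noise must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = [
        r.astype(np.float64) * rng.uniform(1 - noise, 1 + noise, size=r.size)
        for r in m.rows
    ]
    return DistanceMatrix(m.labels, rows)


def clustered_matrix(
    n: int, k_clusters: int, seed: int, dim: int = 8, separation: float = 10.0
) -> DistanceMatrix:
    """Euclidean distances of a well-separated Gaussian mixture.

    ``k_clusters`` unit-variance clusters whose centers are standard-normal
    draws scaled by ``separation`` (default 10 sigma, so within-cluster
    distances sit far below between-cluster ones).  Points are assigned to
    clusters round-robin.
    """
    if not 1 <= k_clusters <= n:
        raise ValidationError("need n >= k_clusters >= 1")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k_clusters, dim)) * separation
    assign = np.arange(n) % k_clusters
    pts = centers[assign] + rng.standard_normal((n, dim))
    sq = squareform(pdist(pts, metric="euclidean"))
    return DistanceMatrix.from_square(_labels(n), sq)


def star_matrix(n: int, distance: float = 1.0) -> DistanceMatrix:
    """Adversarial fixture: all off-diagonal distances equal (the patristic
    matrix of a star tree with uniform branch lengths).  Every join criterion
    ties at every iteration, so the dynamic search degenerates to rescanning
    nearly every row."""
    if n < 2:
        raise ValidationError("star_matrix requires n >= 2")
    rows = [np.full(i, float(distance)) for i in range(n)]
    return DistanceMatrix(_labels(n), rows)
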