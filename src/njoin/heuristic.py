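"""Heuristic neighbor joining: quadratic-time approximate NJ.

HNJ initializes the same per-row cache of minimal join criteria as the
dynamic algorithm, but never performs the per-iteration row sweep.  Each
iteration joins the minimum of the cached vector directly; after the matrix
is contracted, every row's cache becomes the smaller of two candidate terms,

    Q_i = min( (n-2) D(i, j) - S_i - S_j ,   (n-2) D(i, z) - S_i - S_z )

where ``j`` is the row's remembered partner and ``z`` the newly formed node.
Both terms are evaluated with the current ``n`` and ``S``, so the cache always
holds the true criterion of one concrete live pair per row — just not
necessarily the row's optimum.  That is the approximation: a join can expose
a better partner elsewhere in a row, which HNJ will not notice.  On strictly
additive matrices such an alternative never appears, so HNJ returns the exact
NJ tree there; on noisy matrices the output remains a valid binary unrooted
tree whose distance from the exact tree grows with the departure from
additivity.

When a row's remembered partner was itself consumed by a join (and the new
node's term does not apply), that single row is rescanned — bounded by one
scan per row per iteration, preserving the O(n^2) total in practice.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .matrix import DistanceMatrix
from .core import NJState, RunReport, do_join, finish
from .dynamic import QCache, init_cache, _scan_row
from .tree import Tree

__all__ = ["hnj_update", "hnj"]


def hnj_update(cache: QCache, state: NJState, z: int) -> None:
    """Refresh the cache after a join produced slot ``z``.

    The new node's row is scanned in full.  Every other active row compares
    its remembered-partner term, re-evaluated with the current ``n`` and
    ``S`` (a stale scalar would embed outdated row sums), against the
    new-node term where ``z`` precedes the row in storage order; rows whose
    remembered partner was retired are rescanned once instead.
    """
    q, j = _scan_row(state, z)
    cache.Q[z], cache.J[z] = q, j
    cache.Jh[z] = state.handles[j] if j >= 0 else -1
    cache.scans_total += 1
    cache.Q[~state.active] = np.inf
    n = state.n_active
    act = state.active_slots()
    for i in act[1:]:
        i = int(i)
        if i == z:
            continue
        if cache.partner_is_stale(state, i):
            qi, ji = _scan_row(state, i)  # single-row rescan; includes z if z < i
            cache.Q[i], cache.J[i] = qi, ji
            cache.Jh[i] = state.handles[ji] if ji >= 0 else -1
            cache.rescans += 1
            cache.scans_total += 1
            continue
        ji = int(cache.J[i])
        qi = (n - 2) * float(state.R[i, ji]) - state.S[i] - state.S[ji]
        cache.Q[i], cache.J[i] = qi, ji
        if z < i:
            qz = (n - 2) * float(state.R[i, z]) - state.S[i] - state.S[z]
            if qz < qi:
                cache.Q[i], cache.J[i] = qz, z
                cache.Jh[i] = state.handles[z]


def _argmin_cached(cache: QCache, state: NJState) -> tuple[int, int]:
    """Minimum of the cached Q vector; ties to the smallest row slot (each
    row's cached partner already took the smallest column at scan time)."""
    act = state.active_slots()
    best, q_best = -1, np.inf
    for i in act[1:]:
        i = int(i)
        if cache.Q[i] < q_best:
            q_best, best = cache.Q[i], i
    return best, int(cache.J[best])


def hnj(
    m: DistanceMatrix,
    clamp_negative: bool = False,
    with_report: bool = False,
) -> Tree | tuple[Tree, RunReport]:
    """Heuristic neighbor joining in O(n^2) total time.

    Exact on strictly additive matrices; approximate otherwise, always
    returning a valid binary unrooted tree over the input taxa.  The run
    report's ``rescans`` counts rows rescanned due to retired partners.
    """
    if m.n < 2:
        raise ValidationError("neighbor joining requires at least 2 taxa")
    state = NJState(m, clamp_negative=clamp_negative)
    report = RunReport(method="hnj", n=m.n)
    cache = init_cache(state)
    while state.n_active > 3:
        i, k = _argmin_cached(cache, state)
        z = do_join(state, i, k)
        hnj_update(cache, state, z)
        report.iterations += 1
    tree = finish(state)
    report.rescans = cache.rescans
    report.scans_total = cache.scans_total
    return (tree, report) if with_report else tree
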