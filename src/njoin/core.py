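"""Shared neighbor-joining machinery and the canonical O(n^3) algorithm.

Neighbor joining repeatedly joins the pair of nodes minimizing the criterion

    Q(i, j) = (n - 2) * D(i, j) - S(i) - S(j),      S(i) = sum_k D(i, k)

where ``n`` is the number of nodes still live, then contracts the matrix by

    D(i, z) = (D(x, i) + D(i, y) - D(x, y)) / 2

for the node ``z`` replacing the joined pair ``(x, y)``.  The canonical
implementation here rescans every pair each iteration; it is the exactness
oracle for the dynamic and heuristic variants, which share all of this
module's state handling, branch-length estimation, and termination logic.

Storage layout: rows of the (conceptually lower-triangular) matrix occupy
fixed slots.  A join retires both slots and re-uses the lower one for the new
node; no rows are moved.  Stable slot order gives all three algorithms one
well-defined tie-break rule — smallest row slot, then smallest column slot —
and keeps per-row cached minima valid as lower bounds for the dynamic search.

``S`` and ``Q`` are always computed in double precision, whatever the storage
precision of the distances; in the uint8/uint16 modes newly formed distances
are snapped back onto the quantization grid, saturating at the top level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .matrix import QUANT_LEVELS, DistanceMatrix
from .tree import Tree, build_tree

__all__ = [
    "NJState",
    "JoinEvent",
    "RunReport",
    "row_sums",
    "q_value",
    "branch_lengths",
    "update_after_join",
    "canonical_nj",
]


@dataclass
class JoinEvent:
    """One agglomeration: nodes ``x`` and ``y`` joined into ``z`` with branch
    lengths ``bx`` (x–z) and ``by`` (y–z), in the units of the input matrix."""

    x: int
    y: int
    z: int
    bx: float
    by: float


@dataclass
class RunReport:
    """Run statistics emitted by the NJ variants.

    ``rescans`` counts full row scans performed after initialization (the
    dynamic algorithm's per-iteration row examinations, ``d``, summed over
    iterations; for the heuristic variant, rescans forced by stale partners).
    ``scans_total`` additionally includes the initialization scans and the
    new-node row scans.  ``violations`` lists any observed breaches of the
    cached-minimum lower-bound property as ``(iteration, row, slack)``.
    """

    method: str
    n: int
    iterations: int = 0
    rescans: int = 0
    scans_total: int = 0
    violations: list = field(default_factory=list)
    sweep_mismatches: int = 0

    @property
    def mean_rescans_per_iteration(self) -> float:
        return self.rescans / self.iterations if self.iterations else 0.0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "iterations": self.iterations,
            "rescans": self.rescans,
            "scans_total": self.scans_total,
            "mean_rescans_per_iteration": self.mean_rescans_per_iteration,
            "violations": len(self.violations),
            "sweep_mismatches": self.sweep_mismatches,
        }


class NJState:
    """Live clustering state shared by all NJ variants.

    Holds the dense symmetric working matrix (true distances), the active-slot
    mask, per-row sums ``S`` in double precision, node handles per slot, and
    the accumulated join events.  Leaf handles are ``0..n-1`` in label order;
    each join allocates the next handle.
    """

    def __init__(self, m: DistanceMatrix, clamp_negative: bool = False):
        if m.n < 1:
            raise ValidationError("empty distance matrix")
        self.labels = list(m.labels)
        n = m.n
        dtype = np.float32 if m.precision == "float" else np.float64
        self.R = m.to_square().astype(dtype)
        if m.precision in QUANT_LEVELS:
            self.grid: tuple[float, int] | None = (m.scale, QUANT_LEVELS[m.precision])
        else:
            self.grid = None
        self.active = np.ones(n, dtype=bool)
        self.n_active = n
        self.S = self.R.sum(axis=1, dtype=np.float64)
        self.handles = np.arange(n, dtype=np.int64)
        self.next_handle = n
        self.joins: list[JoinEvent] = []
        self.clamp_negative = clamp_negative

    def active_slots(self) -> np.ndarray:
        return np.flatnonzero(self.active)

    def distance(self, i: int, k: int) -> float:
        return float(self.R[i, k])

    def fresh_row_sums(self) -> np.ndarray:
        """Recompute S from scratch over active slots (bookkeeping audit)."""
        act = self.active_slots()
        S = np.full(len(self.active), np.nan)
        S[act] = self.R[np.ix_(act, act)].sum(axis=1, dtype=np.float64)
        return S


def row_sums(m: DistanceMatrix) -> np.ndarray:
    """Per-taxon distance sums ``S_i = sum_{k != i} D(i, k)`` in float64."""
    return m.to_square().sum(axis=1, dtype=np.float64)


def q_value(state: NJState, i: int, k: int) -> float:
    """Join criterion ``(n - 2) D(i,k) - S_i - S_k`` for two active slots."""
    n = state.n_active
    return (n - 2) * float(state.R[i, k]) - state.S[i] - state.S[k]


def branch_lengths(state: NJState, x: int, y: int) -> tuple[float, float]:
    """Branch lengths from ``x`` and ``y`` to their new parent.

    Standard Studier–Keppler estimates:
    ``bx = D(x,y)/2 + (S_x - S_y) / (2 (n - 2))`` and ``by = D(x,y) - bx``.
    Negative values are returned as computed unless the state was built with
    ``clamp_negative``, in which case each is clamped to 0 independently.
    """
    n = state.n_active
    if n < 3:
        raise ValidationError("branch_lengths requires at least 3 active nodes")
    d = float(state.R[x, y])
    bx = d / 2.0 + (state.S[x] - state.S[y]) / (2.0 * (n - 2))
    by = d - bx
    if state.clamp_negative:
        bx, by = max(bx, 0.0), max(by, 0.0)
    return bx, by


def update_after_join(state: NJState, x: int, y: int) -> int:
    """Contract the matrix after joining slots ``x`` and ``y``.

    The new node re-uses the lower slot; the higher slot is retired.  For every
    other active ``i``: ``D(i, z) = (D(x,i) + D(i,y) - D(x,y)) / 2`` (snapped
    to the quantization grid, saturating, when the input was integer-mode) and
    ``S_i <- S_i - D(x,i) - D(i,y) + D(i,z)``; ``S_z`` is the sum of the new
    row.  Returns the slot of the new node (its handle is allocated here).
    """
    if x == y or not (state.active[x] and state.active[y]):
        raise ValidationError("update_after_join requires two distinct active slots")
    zslot, dead = (x, y) if x < y else (y, x)
    act = state.active_slots()
    others = act[(act != x) & (act != y)]
    dxy = float(state.R[x, y])
    dx = state.R[others, x].astype(np.float64)
    dy = state.R[others, y].astype(np.float64)
    dz = (dx + dy - dxy) / 2.0
    if state.grid is not None:
        scale, levels = state.grid
        cells = np.clip(np.floor(dz / scale + 0.5), 0, levels)
        dz = cells * scale
    state.S[others] += dz - dx - dy
    state.active[dead] = False
    state.R[dead, :] = 0.0
    state.R[:, dead] = 0.0
    state.R[others, zslot] = dz
    state.R[zslot, others] = dz
    state.R[zslot, zslot] = 0.0
    state.S[zslot] = dz.sum(dtype=np.float64)
    state.handles[zslot] = state.next_handle
    state.next_handle += 1
    state.n_active -= 1
    return zslot


def do_join(state: NJState, i: int, k: int) -> int:
    """Join the pair at slots ``(i, k)``: record the event, contract the
    matrix, return the new node's slot.  ``x`` is the smaller slot."""
    x, y = (i, k) if i < k else (k, i)
    bx, by = branch_lengths(state, x, y)
    hx, hy = int(state.handles[x]), int(state.handles[y])
    z = update_after_join(state, x, y)
    state.joins.append(JoinEvent(hx, hy, int(state.handles[z]), bx, by))
    return z


def finish(state: NJState) -> Tree:
    """Resolve the terminal configuration (<= 3 live nodes) into a Tree.

    With three nodes the three spoke lengths solve the pairwise-distance
    equations exactly; with two, the single distance is split evenly.
    """
    act = state.active_slots()
    hs = [int(state.handles[s]) for s in act]
    if len(act) == 1:
        return build_tree(state.labels, state.joins, None)
    if len(act) == 2:
        d = float(state.R[act[0], act[1]])
        return build_tree(state.labels, state.joins, None, pair=(hs[0], hs[1], d))
    a, b, c = act
    dab, dac, dbc = (float(state.R[a, b]), float(state.R[a, c]), float(state.R[b, c]))
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    if state.clamp_negative:
        la, lb, lc = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    center = list(zip(hs, (la, lb, lc)))
    return build_tree(state.labels, state.joins, center)


def argmin_pair(state: NJState) -> tuple[int, int]:
    """Exact global argmin of the join criterion over all active pairs.

    Ties break to the smallest row slot, then the smallest column slot, in
    storage order — the rule shared by every variant in this package.
    """
    act = state.active_slots()
    sub = state.R[np.ix_(act, act)].astype(np.float64)
    S = state.S[act]
    q = (state.n_active - 2) * sub - S[:, None] - S[None, :]
    iu = np.triu_indices(len(act), k=0)
    q[iu] = np.inf  # keep the strict lower triangle: row > column
    flat = int(np.argmin(q))  # row-major: first hit = smallest row, then column
    r, c = divmod(flat, len(act))
    return int(act[r]), int(act[c])


def canonical_nj(
    m: DistanceMatrix,
    clamp_negative: bool = False,
    with_report: bool = False,
) -> Tree | tuple[Tree, RunReport]:
    """Canonical Saitou–Nei neighbor joining with a full pair scan per
    iteration — the exactness oracle for the faster variants.

    Joins the global criterion argmin until three nodes remain, then resolves
    the terminal vertex exactly.  Requires ``n >= 2``.
    """
    if m.n < 2:
        raise ValidationError("neighbor joining requires at least 2 taxa")
    state = NJState(m, clamp_negative=clamp_negative)
    report = RunReport(method="nj", n=m.n)
    while state.n_active > 3:
        i, k = argmin_pair(state)
        do_join(state, i, k)
        report.iterations += 1
        report.rescans += state.n_active  # full scan touched every live row
        report.scans_total += state.n_active
    tree = finish(state)
    return (tree, report) if with_report else tree
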