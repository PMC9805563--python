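"""Dynamic NJ: cache initialization, running-minimum sweep, repair, exactness."""

import copy

import numpy as np
import pytest

import njoin
from njoin.core import NJState, do_join
from njoin.dynamic import (
    QCache,
    _scan_row,
    brute_global_min,
    init_cache,
    lower_bound_slacks,
    repair_cache,
    sweep_min,
)
from njoin import synthetic

from conftest import assert_same_tree


def reference_sweep(cache: QCache, state: NJState):
    """Test-local simulation of the running-minimum recursion: descending row
    order, strict rescan test against M, M-initialization from the previous
    join's new-node row.  Returns (pair, rescanned row list)."""
    act = [int(i) for i in state.active_slots()]
    Q = cache.Q.copy()
    J = cache.J.copy()
    fresh = set()
    M = np.inf
    z = cache.last_z
    if z is not None and state.active[z] and np.isfinite(Q[z]):
        M = float(Q[z])
        fresh.add(z)
    rescanned = []
    for i in reversed(act[1:]):
        if i == z:
            continue
        if Q[i] < M:
            q, j = _scan_row(state, i)
            Q[i], J[i] = q, j
            fresh.add(i)
            rescanned.append(i)
            M = min(M, q)
    best = min(i for i in fresh if Q[i] == M)
    return (best, int(J[best])), rescanned


class TestInitCache:
    def test_three_taxa_ties_take_smallest_column(self, abc_matrix):
        state = NJState(abc_matrix)
        cache = init_cache(state)
        assert cache.Q[1] == cache.Q[2] == pytest.approx(-9.0)
        # row C ties between A and B at -9; smallest-index rule picks A
        assert cache.J[1] == 0 and cache.J[2] == 0
        assert cache.scans_total == 2

    def test_constant_matrix_first_column(self):
        n, c = 6, 1.0
        state = NJState(synthetic.star_matrix(n, distance=c))
        cache = init_cache(state)
        assert np.allclose(cache.Q[1:], -n * c)
        assert all(cache.J[1:] == 0)

    def test_two_taxa_degenerate(self):
        state = NJState(njoin.DistanceMatrix(["A", "B"], [[], [5.0]]))
        cache = init_cache(state)
        assert cache.Q[1] == pytest.approx(0 * 5.0 - 5.0 - 5.0)


class TestSweepMin:
    def test_first_sweep_rescans_descending_records(self):
        """On a fresh cache (all rows exact, no previous join) the sweep
        rescans exactly the rows whose cached Q is a strict running minimum
        from the top, and returns the global argmin pair."""
        m = synthetic.metric_matrix(12, seed=3)
        state = NJState(m)
        cache = init_cache(state)
        Q0 = cache.Q.copy()
        before = cache.rescans
        i, j = sweep_min(cache, state)
        # expected rescans: strict descending records of the cached vector
        M, expected = np.inf, 0
        for r in range(11, 0, -1):
            if Q0[r] < M:
                expected += 1
                M = Q0[r]
        assert cache.rescans - before == expected
        # exactness of the located pair
        assert cache.Q[i] == pytest.approx(brute_global_min(state))
        qd = njoin.q_value(state, i, j)
        assert qd == pytest.approx(cache.Q[i])

    def test_matches_reference_simulation_across_run(self):
        """Every sweep in a full run agrees with a test-local reimplementation
        of the recursion on pair choice and rescanned rows."""
        m = synthetic.metric_matrix(24, seed=11)
        state = NJState(m)
        cache = init_cache(state)
        while state.n_active > 3:
            ref_pair, ref_rows = reference_sweep(copy.deepcopy(cache), state)
            before = cache.rescans
            pair = sweep_min(cache, state)
            assert pair == ref_pair
            assert cache.rescans - before == len(ref_rows)
            z = do_join(state, *pair)
            repair_cache(cache, state, z)

    def test_single_pair_returned_directly(self):
        state = NJState(njoin.DistanceMatrix(["A", "B"], [[], [5.0]]))
        cache = init_cache(state)
        assert sweep_min(cache, state) == (1, 0)

    def test_selected_row_is_always_fresh(self):
        m = synthetic.metric_matrix(16, seed=5)
        state = NJState(m)
        cache = init_cache(state)
        while state.n_active > 3:
            i, _ = sweep_min(cache, state)
            assert cache.fresh[i]
            z = do_join(state, i, int(cache.J[i]))
            repair_cache(cache, state, z)


class TestRepairCache:
    def _run_to(self, m, iters):
        state = NJState(m)
        cache = init_cache(state)
        for _ in range(iters):
            pair = sweep_min(cache, state)
            z = do_join(state, *pair)
            repair_cache(cache, state, z)
        return state, cache

    def test_new_node_term_folds_in(self):
        m = synthetic.metric_matrix(10, seed=2)
        state, cache = self._run_to(m, 1)
        z = cache.last_z
        n = state.n_active
        for i in state.active_slots():
            i = int(i)
            if i <= z:
                continue
            term = (n - 2) * state.R[i, z] - state.S[i] - state.S[z]
            assert cache.Q[i] <= term + 1e-12

    def test_lower_bound_holds_on_metric_input(self):
        """After every repair, brute-force row minima never undercut caches
        (the skip rule's soundness condition) on a metric matrix, n=30."""
        m = synthetic.metric_matrix(30, seed=9)
        state = NJState(m)
        cache = init_cache(state)
        while state.n_active > 3:
            assert lower_bound_slacks(cache, state) == []
            pair = sweep_min(cache, state)
            z = do_join(state, *pair)
            repair_cache(cache, state, z)

    def test_new_row_scanned_exactly(self):
        m = synthetic.metric_matrix(10, seed=4)
        state, cache = self._run_to(m, 2)
        z = cache.last_z
        q, j = _scan_row(state, z)
        assert cache.Q[z] == pytest.approx(q) and cache.J[z] == j


class TestDNJ:
    @pytest.mark.parametrize("n", [4, 5, 8, 16, 33, 64])
    def test_equals_canonical_on_additive(self, n):
        m = synthetic.additive_matrix(n, seed=n * 7 + 5)
        assert_same_tree(njoin.dnj(m), njoin.canonical_nj(m), tol=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 10, 21, 40])
    def test_equals_canonical_on_metric(self, n):
        m = synthetic.metric_matrix(n, seed=n * 3 + 2)
        assert_same_tree(njoin.dnj(m), njoin.canonical_nj(m), tol=1e-9)

    def test_two_taxa(self):
        out = njoin.dnj(njoin.DistanceMatrix(["A", "B"], [[], [6.0]]))
        assert out.to_newick().startswith("(A:3")

    def test_audits_clean_on_metric(self):
        m = synthetic.metric_matrix(25, seed=1)
        _, rep = njoin.dnj(m, with_report=True, audit_lower_bound=True, audit_sweep=True)
        assert rep.violations == [] and rep.sweep_mismatches == 0

    def test_report_counts(self):
        n = 20
        m = synthetic.metric_matrix(n, seed=6)
        _, rep = njoin.dnj(m, with_report=True)
        assert rep.n == n and rep.iterations == n - 3
        assert rep.rescans >= rep.iterations  # at least one refresh per sweep
        assert rep.scans_total >= rep.rescans

    def test_star_forces_near_full_rescans(self):
        """Equal-distance input drives the rescan count toward the active row
        count each iteration (the worst-case regime)."""
        n = 64
        _, rep = njoin.dnj(synthetic.star_matrix(n), with_report=True)
        mean_active = np.mean(np.arange(4, n + 1) - 1)
        assert rep.mean_rescans_per_iteration >= 0.8 * mean_active
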