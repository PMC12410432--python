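"""Two-point statistics, grouping, ordering and map distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radymap.linkage import (MapConfig, build_linkage_map, corrected_r,
                             group_markers, haldane, haldane_inverse,
                             join_singles, locate_y_region, order_group,
                             positions_from_order, twopoint,
                             twopoint_matrices)


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

class TestHaldane:
    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.0, 0.49))
    def test_round_trip(self, r):
        assert haldane_inverse(haldane(r)) == pytest.approx(r, abs=1e-12)

    def test_known_distance(self):
        assert haldane(0.1) == pytest.approx(-50 * np.log(0.8), abs=1e-12)
        assert float(haldane(0.0)) == 0.0


# ---------------------------------------------------------------------------
# two-point LOD
# ---------------------------------------------------------------------------

def grid_lod_oracle(R, n):
    """Max over the rational grid k/(2n) of the binomial log10 likelihood
    ratio against r = 0.5 (independent of the closed-form route)."""
    grid = np.arange(0, n + 1) / (2.0 * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(R > 0, R * np.log10(grid), 0.0) + np.where(
            n - R > 0, (n - R) * np.log10(1 - grid), 0.0
        )
    ll0 = R * np.log10(0.5) + (n - R) * np.log10(0.5)
    return float(np.nanmax(ll) - ll0)


def make_pair_calls(R, n, rng=None):
    a = np.zeros(n, dtype=np.int8)
    b = np.zeros(n, dtype=np.int8)
    b[:R] = 1
    return a, b


class TestTwoPoint:
    def test_perfect_linkage_closed_form(self):
        a, b = make_pair_calls(0, 10)
        res = twopoint(a, b)
        assert res.r_hat == 0.0
        assert res.lod == pytest.approx(10 * np.log10(2), abs=1e-12)

    def test_independence_gives_zero_lod(self):
        a, b = make_pair_calls(5, 10)
        res = twopoint(a, b)
        assert res.r_hat == 0.5
        assert res.lod == 0.0

    def test_known_value(self):
        a, b = make_pair_calls(2, 20)
        assert twopoint(a, b).lod == pytest.approx(3.197, abs=5e-4)

    @pytest.mark.parametrize("R,n", [(0, 7), (1, 20), (2, 20), (5, 37),
                                     (10, 100), (49, 100)])
    def test_matches_grid_likelihood_oracle(self, R, n):
        a, b = make_pair_calls(R, n)
        assert twopoint(a, b).lod == pytest.approx(grid_lod_oracle(R, n), abs=1e-9)

    def test_phase_maximisation(self):
        # 18/20 discordant is 2/20 recombinant under the opposite phase
        a = np.zeros(20, dtype=np.int8)
        b = np.ones(20, dtype=np.int8)
        b[:2] = 0
        res = twopoint(a, b)
        assert res.R == 2 and res.r_hat == pytest.approx(0.1)

    def test_missing_excluded(self):
        a = np.array([0, 0, 1, -1, 1], dtype=np.int8)
        b = np.array([0, 0, 1, 1, -1], dtype=np.int8)
        assert twopoint(a, b).n_informative == 3

    def test_no_informative_offspring_errors(self):
        with pytest.raises(ValueError):
            twopoint([-1, -1], [0, 1])

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(1, 60))
    def test_lod_decreases_with_recombinants(self, n):
        lods = []
        for R in range(n // 2 + 1):
            a, b = make_pair_calls(R, n)
            lods.append(twopoint(a, b).lod)
        assert all(x >= y - 1e-12 for x, y in zip(lods, lods[1:]))
        assert lods[-1] == pytest.approx(0.0, abs=1e-9) or n % 2 == 1

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(-1, 2, size=(8, 50)).astype(np.int8)
        R, N, r_hat, lod = twopoint_matrices(calls)
        for i in range(8):
            for j in range(i + 1, 8):
                res = twopoint(calls[i], calls[j])
                assert R[i, j] == res.R
                assert N[i, j] == res.n_informative
                assert lod[i, j] == pytest.approx(res.lod, abs=1e-9)


class TestCorrectedR:
    def test_zero_error_reduces_to_raw_fraction(self):
        R = np.array([[0, 3], [3, 0]])
        N = np.array([[20, 20], [20, 20]])
        r0 = corrected_r(R, N, None)
        r1 = corrected_r(R, N, np.zeros(2))
        assert np.allclose(r0, r1)
        assert r1[0, 1] == pytest.approx(0.15)

    def test_zero_error_colocates_only_identical(self):
        R = np.array([[0, 1], [1, 0]])
        N = np.full((2, 2), 50)
        assert corrected_r(R, N, np.zeros(2))[0, 1] > 0
        R[0, 1] = R[1, 0] = 0
        assert corrected_r(R, N, np.zeros(2))[0, 1] == 0.0

    def test_error_floor_absorbs_expected_discordance(self):
        # discordance exactly at the error floor -> co-located
        eps = np.array([0.05, 0.05])
        c = 2 * 0.05 * 0.95
        N = np.full((2, 2), 200)
        R = np.full((2, 2), int(round(c * 200)))
        np.fill_diagonal(R, 0)
        assert corrected_r(R, N, eps)[0, 1] == 0.0

    def test_excess_discordance_maps_to_distance(self):
        eps = np.array([0.02, 0.02])
        N = np.full((2, 2), 1000)
        R = np.full((2, 2), 150)  # far above the ~3.9% error floor
        np.fill_diagonal(R, 0)
        r = corrected_r(R, N, eps)[0, 1]
        assert 0.1 < r < 0.15  # (0.15 - 0.0392) / (1 - 0.0784) ~ 0.120


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def bfs_components(adj):
    """Hand-rolled connected components (oracle)."""
    n = len(adj)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], []
        seen.add(s)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if adj[u][v] and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


class TestGrouping:
    def test_transitive_closure(self):
        lod = np.zeros((3, 3))
        lod[0, 1] = lod[1, 0] = 25
        lod[1, 2] = lod[2, 1] = 25
        groups, unplaced = group_markers(lod, 20)
        assert groups == [[0, 1, 2]] and unplaced == []

    def test_all_below_threshold_unplaced(self):
        lod = np.full((4, 4), 10.0)
        np.fill_diagonal(lod, 0)
        groups, unplaced = group_markers(lod, 20)
        assert groups == [] and unplaced == [0, 1, 2, 3]

    def test_asymmetric_matrix_rejected(self):
        lod = np.zeros((2, 2))
        lod[0, 1] = 30
        with pytest.raises(ValueError):
            group_markers(lod, 20)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_components(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        lod = rng.uniform(0, 40, (n, n))
        lod = (lod + lod.T) / 2
        np.fill_diagonal(lod, 0)
        groups, unplaced = group_markers(lod, 20)
        adj = (lod >= 20).tolist()
        for i in range(n):
            adj[i][i] = False
        oracle = bfs_components(adj)
        got = sorted(groups + [[u] for u in unplaced])
        assert got == sorted(oracle)


class TestJoinSingles:
    def _setup(self):
        lod = np.zeros((5, 5))
        for i, j, v in [(0, 1, 30), (2, 3, 30)]:
            lod[i, j] = lod[j, i] = v
        return lod

    def test_joins_at_threshold(self):
        lod = self._setup()
        lod[4, 2] = lod[2, 4] = 16.0
        groups, unplaced = group_markers(lod, 20)
        groups, unplaced = join_singles(groups, unplaced, lod, 15)
        assert [2, 3, 4] in groups and unplaced == []

    def test_below_threshold_stays_unplaced(self):
        lod = self._setup()
        lod[4, 2] = lod[2, 4] = 14.9
        groups, unplaced = group_markers(lod, 20)
        groups, unplaced = join_singles(groups, unplaced, lod, 15)
        assert unplaced == [4]

    def test_never_merges_groups(self):
        lod = self._setup()
        lod[4, 0] = lod[0, 4] = 18
        lod[4, 2] = lod[2, 4] = 19
        groups0, unplaced0 = group_markers(lod, 20)
        groups, unplaced = join_singles(groups0, unplaced0, lod, 15)
        assert len(groups) == len(groups0)
        assert sum(len(g) for g in groups) == sum(len(g) for g in groups0) + 1
        # tie-ish case resolved toward the best-LOD partner's group
        assert [2, 3, 4] in groups


# ---------------------------------------------------------------------------
# ordering & positions
# ---------------------------------------------------------------------------

def simulate_three_markers(d_cm=10.0, n=1000, seed=0):
    """Testcross calls for markers at 0, d, 2d cM (Haldane meiosis)."""
    rng = np.random.default_rng(seed)
    r = float(0.5 * -np.expm1(-2 * d_cm / 100))
    start = rng.integers(0, 2, n)
    s1 = start ^ (rng.random(n) < r)
    s2 = s1 ^ (rng.random(n) < r)
    return np.vstack([start, s1, s2]).astype(np.int8)


class TestOrdering:
    def test_single_marker_group(self):
        assert order_group([3], np.zeros((5, 5))) == [3]

    def test_three_marker_recovery(self):
        calls = simulate_three_markers()
        _, _, r_hat, _ = twopoint_matrices(calls)
        order = order_group([0, 1, 2], r_hat)
        assert order in ([0, 1, 2], [2, 1, 0])

    def test_known_gap_distance(self):
        r = np.array([[0, 0.1], [0.1, 0]])
        pos = positions_from_order([0, 1], r, MapConfig())
        assert pos[1] == pytest.approx(-50 * np.log(0.8), abs=1e-9)  # 11.157

    def test_unlinked_gap_capped(self):
        r = np.array([[0, 0.5], [0.5, 0]])
        with pytest.warns(UserWarning):
            pos = positions_from_order([0, 1], r, MapConfig(max_gap_cM=100))
        assert pos[1] == 100.0

    def test_positions_nondecreasing_and_total(self):
        rng = np.random.default_rng(5)
        r = rng.uniform(0.01, 0.3, (6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        order = order_group(list(range(6)), r)
        pos = positions_from_order(order, r, MapConfig())
        assert all(b >= a for a, b in zip(pos, pos[1:]))
        gaps = [b - a for a, b in zip(pos, pos[1:])]
        assert sum(gaps) == pytest.approx(pos[-1])

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(11)
        r = rng.uniform(0.01, 0.3, (5, 5))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        order = order_group(list(range(5)), r)
        fwd = positions_from_order(order, r, MapConfig())
        rev = positions_from_order(order[::-1], r, MapConfig())
        gaps_f = sorted(round(b - a, 9) for a, b in zip(fwd, fwd[1:]))
        gaps_r = sorted(round(b - a, 9) for a, b in zip(rev, rev[1:]))
        assert gaps_f == gaps_r


class TestLocateYRegion:
    def _map_from_rows(self, rows):
        import pandas as pd

        from radymap.linkage import LinkageMap

        return LinkageMap(pd.DataFrame(
            rows, columns=["group", "order_index", "marker", "cm", "y_flag"]
        ))

    def test_terminal_colocated_block(self):
        rows = [(1, 0, "a", 0.0, False), (1, 1, "b", 10.0, False),
                (1, 2, "y1", 20.0, True), (1, 3, "y2", 20.0, True)]
        rep = locate_y_region(self._map_from_rows(rows))
        assert len(rep) == 1
        row = rep.iloc[0]
        assert row.span_cm == 0.0 and row.touches_end and row.max_colocated == 2

    def test_split_groups_reported(self):
        rows = [(1, 0, "a", 0.0, True), (1, 1, "b", 5.0, False),
                (2, 0, "c", 0.0, True), (2, 1, "d", 3.0, False)]
        rep = locate_y_region(self._map_from_rows(rows))
        assert sorted(rep["group"]) == [1, 2]

    def test_no_y_markers_warns_empty(self):
        rows = [(1, 0, "a", 0.0, False)]
        with pytest.warns(UserWarning):
            rep = locate_y_region(self._map_from_rows(rows))
        assert len(rep) == 0
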