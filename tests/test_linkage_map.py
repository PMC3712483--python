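"""Two-point statistics, Kosambi transform, grouping, ordering and maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cepmap.linkage_map import (
    MarkerGenotypes,
    build_map,
    form_groups,
    kosambi_cm,
    kosambi_inverse,
    order_markers,
    pool_recombination,
    twopoint,
    _order_ll,
    _pairwise_tables,
)
from cepmap.synthetic_data import SimulationConfig, simulate_cross


def _geno(marker_id, calls):
    return MarkerGenotypes(marker_id, np.asarray(calls, dtype=np.int8))


def _vectors_with_recombinants(n, n_flips):
    a = np.zeros(n, dtype=np.int8)
    b = a.copy()
    b[:n_flips] = 1
    return _geno("a", a), _geno("b", b)


class TestTwoPoint:
    def test_one_recombinant_in_102(self):
        a, b = _vectors_with_recombinants(102, 1)
        tp = twopoint(a, b)
        assert tp.n_informative == 102 and tp.n_recombinant == 1
        assert tp.r_hat == pytest.approx(1 / 102)
        assert tp.lod == pytest.approx(28.26, abs=0.01)

    def test_identical_vectors_lod(self):
        a, b = _vectors_with_recombinants(100, 0)
        tp = twopoint(a, b)
        assert tp.r_hat == 0.0
        assert tp.lod == pytest.approx(100 * math.log10(2), abs=1e-9)

    def test_independent_markers_near_zero_lod(self, rng):
        a = _geno("a", rng.integers(0, 2, size=5000))
        b = _geno("b", rng.integers(0, 2, size=5000))
        tp = twopoint(a, b)
        assert tp.r_hat == pytest.approx(0.5, abs=0.03)
        assert tp.lod < 3.0

    def test_symmetric_and_phase_flip_invariant(self, rng):
        calls_a = rng.integers(0, 2, size=80)
        calls_b = rng.integers(0, 2, size=80)
        a, b = _geno("a", calls_a), _geno("b", calls_b)
        assert twopoint(a, b).lod == pytest.approx(twopoint(b, a).lod)
        flipped = _geno("a", 1 - calls_a)
        assert twopoint(flipped, b).lod == pytest.approx(twopoint(a, b).lod)
        assert twopoint(flipped, b).n_recombinant == 80 - twopoint(a, b).n_recombinant

    def test_missing_calls_pairwise_complete(self):
        a = _geno("a", [1, 0, -1, 1, 0])
        b = _geno("b", [1, 0, 1, -1, 0])
        tp = twopoint(a, b)
        assert tp.n_informative == 3

    def test_no_shared_offspring_raises(self):
        a = _geno("a", [1, -1])
        b = _geno("b", [-1, 0])
        with pytest.raises(ValueError, match="no shared informative"):
            twopoint(a, b)


class TestKosambi:
    @pytest.mark.parametrize(
        "r, cm, tol",
        [
            (1 / 102, 0.98, 0.005),
            (1 / 168, 0.6, 0.05),
            (0.0, 0.0, 1e-12),
            (0.25, 27.47, 0.01),
        ],
    )
    def test_known_distances(self, r, cm, tol):
        assert kosambi_cm(r) == pytest.approx(cm, abs=tol)

    def test_unlinked_fraction_rejected(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)

    @given(st.floats(min_value=0.0, max_value=0.499))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_and_lower_bound(self, r):
        d = kosambi_cm(r)
        assert abs(kosambi_inverse(d) - r) < 1e-10
        assert d >= 100 * r - 1e-12
        if r > 1e-4:  # the gap is O(r^3), below float resolution for tiny r
            assert d > 100 * r


class TestFormGroups:
    def _panel(self, seed, positions, phases, n=102, supergene=16.58):
        cfg = SimulationConfig(
            seed=seed,
            n_offspring=n,
            marker_positions_cm=positions,
            marker_phases=phases,
            supergene_position_cm=supergene,
        )
        truth = simulate_cross(cfg)
        return [
            MarkerGenotypes(name, truth.father_gametes[:, j])
            for j, name in enumerate(truth.marker_names)
        ]

    def test_linked_panel_forms_single_group(self):
        from cepmap.experiments import mapping_genotypes_from_truth

        positions = (0.0, 4.0, 8.0, 12.0, 15.6, 15.6, 15.6, 21.0, 25.5, 30.5, 35.8)
        phases = ("banding",) * 7 + ("colour",) * 4
        cfg = SimulationConfig(
            seed=11,
            n_offspring=102,
            marker_positions_cm=positions,
            marker_phases=phases,
            supergene_position_cm=16.58,
        )
        genotypes, _ = mapping_genotypes_from_truth(simulate_cross(cfg))
        groups = form_groups(genotypes, lod_threshold=3.0)
        assert len(groups) == 1
        assert len(groups[0].markers) == 13  # 11 markers + colour/banding loci

    def test_unlinked_markers_split_into_groups(self):
        genotypes = self._panel(
            5, (0.0, 2.0, 30.0), ("banding", "banding", "unlinked")
        )
        groups = form_groups(genotypes, lod_threshold=3.0)
        sizes = sorted(len(g.markers) for g in groups)
        assert sizes == [1, 3]

    def test_single_marker_is_own_group(self):
        g = _geno("solo", [1, 0, 1, 0])
        groups = form_groups([g])
        assert [grp.markers for grp in groups] == [["solo"]]


class TestOrderMarkers:
    def test_three_marker_oracle(self):
        # pairwise R/N: A-B 1/100, A-C 5/100, B-C 6/100 -> C-A-B up to reversal
        n = 100
        a = np.zeros(n, dtype=np.int8)
        b = a.copy()
        b[:1] = 1
        c = a.copy()
        c[1:6] = 1
        res = order_markers([_geno("A", a), _geno("B", b), _geno("C", c)])
        assert res.order in (["C", "A", "B"], ["B", "A", "C"])
        # independent oracle: best of the three distinct orders by likelihood
        genos = [_geno("A", a), _geno("B", b), _geno("C", c)]
        R, N = _pairwise_tables(genos)
        lls = {
            tuple(order): _order_ll(order, R, N)
            for order in ([0, 1, 2], [0, 2, 1], [1, 0, 2])
        }
        assert res.log10_likelihood == pytest.approx(max(lls.values()))

    def test_two_markers_trivial(self):
        a, b = _vectors_with_recombinants(50, 2)
        res = order_markers([a, b])
        assert res.order == ["a", "b"]

    def test_identical_markers_flagged_unresolved(self):
        a, b = _vectors_with_recombinants(30, 0)
        res = order_markers([a, b])
        assert res.unresolved

    def test_exhaustive_agrees_with_heuristic_small_panels(self):
        # force the heuristic path on <= 6 markers and compare to exhaustive
        import cepmap.linkage_map as lm

        positions = (0.0, 7.0, 14.0, 21.0, 28.0)
        phases = ("banding",) * 5
        for seed in range(12):
            cfg = SimulationConfig(
                seed=seed,
                n_offspring=102,
                marker_positions_cm=positions,
                marker_phases=phases,
                supergene_position_cm=35.0,
            )
            truth = simulate_cross(cfg)
            genotypes = [
                MarkerGenotypes(name, truth.father_gametes[:, j])
                for j, name in enumerate(truth.marker_names)
            ]
            exhaustive = order_markers(genotypes)
            old = lm.EXHAUSTIVE_LIMIT
            lm.EXHAUSTIVE_LIMIT = 0
            try:
                heuristic = order_markers(genotypes)
            finally:
                lm.EXHAUSTIVE_LIMIT = old
            assert heuristic.log10_likelihood == pytest.approx(
                exhaustive.log10_likelihood
            )

    def test_flips_report_contains_near_ties(self):
        a, b = _vectors_with_recombinants(30, 0)
        c = _geno("c", np.r_[np.ones(3, dtype=np.int8), np.zeros(27, dtype=np.int8)])
        res = order_markers([a, b, c])
        assert res.flips  # indistinguishable a/b swap is within any margin
        assert res.flips[0][1] == pytest.approx(0.0)


class TestBuildMap:
    def test_adjacent_interval_distances(self):
        n = 102
        a = np.zeros(n, dtype=np.int8)
        b = a.copy()
        b[0] = 1  # 1/102 from a
        genotypes = [_geno("m1", a), _geno("m2", a.copy()), _geno("m3", b)]
        gmap = build_map(genotypes)
        assert gmap.adjacent_cm[0] == pytest.approx(0.0)  # co-segregating pair
        assert gmap.adjacent_cm[1] == pytest.approx(0.98, abs=0.005)
        assert gmap.total_length_cm == pytest.approx(sum(gmap.adjacent_cm))

    def test_total_length_invariant_under_reversal(self, rng):
        cfg = SimulationConfig(
            seed=99,
            n_offspring=102,
            marker_positions_cm=(0.0, 5.0, 12.0, 20.0),
            marker_phases=("banding",) * 4,
            supergene_position_cm=25.0,
        )
        truth = simulate_cross(cfg)
        genotypes = [
            MarkerGenotypes(name, truth.father_gametes[:, j])
            for j, name in enumerate(truth.marker_names)
        ]
        forward = build_map(genotypes)
        backward = build_map(genotypes[::-1])
        assert forward.total_length_cm == pytest.approx(backward.total_length_cm)

    def test_simulated_total_length_within_three_se(self):
        # true length 35.8 cM over 12 intervals, 102 offspring per replicate
        positions = (0.0, 4.0, 8.0, 12.0, 15.6, 15.6, 15.6, 21.0, 25.5, 30.5, 35.8)
        phases = ("banding",) * 7 + ("colour",) * 4
        totals = []
        for seed in range(25):
            cfg = SimulationConfig(
                seed=seed,
                n_offspring=102,
                marker_positions_cm=positions,
                marker_phases=phases,
                supergene_position_cm=16.58,
            )
            truth = simulate_cross(cfg)
            order = np.argsort(truth.marker_positions_cm, kind="stable")
            genotypes = [
                MarkerGenotypes(truth.marker_names[j], truth.father_gametes[:, j])
                for j in order
            ]
            totals.append(build_map(genotypes).total_length_cm)
        se = np.std(totals, ddof=1) / math.sqrt(len(totals))
        assert abs(np.mean(totals) - 35.8) <= 3 * se


class TestPoolRecombination:
    def test_study_pooling(self):
        pooled = pool_recombination([(1, 102), (0, 66)])
        assert (pooled.n_recombinant, pooled.n_informative) == (1, 168)
        assert pooled.distance_cm == pytest.approx(0.6, abs=0.05)

    def test_zero_pooling(self):
        pooled = pool_recombination([(0, 10), (0, 10)])
        assert (pooled.n_recombinant, pooled.n_informative) == (0, 20)
        assert pooled.distance_cm == 0.0

    def test_equal_n_matches_weighted_average(self):
        pooled = pool_recombination([(2, 100), (4, 100)])
        assert pooled.r_hat == pytest.approx((2 / 100 + 4 / 100) / 2)
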