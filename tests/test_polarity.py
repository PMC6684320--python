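"""Polarity index, angle geometry, assignment, binning, rows, threshold."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccpol.polarity import (CellPolarityRecord, EdgeReference, angular_histogram,
                            assign_golgi, bin_pi_by_distance, classify_rows,
                            derive_threshold, polarity_angle, polarity_index,
                            rayleigh_test, segment_centroids)


class TestPolarityIndex:
    @pytest.mark.parametrize("angles, pi, mean", [
        ([0.0, 0.0, 0.0], 1.0, 0.0),                      # fully polarized
        ([0.0, 90.0, 180.0, 270.0], 0.0, None),           # 4-fold symmetry
        ([0.0, 90.0], np.sqrt(2) / 2, 45.0),              # direct formula
        ([30.0] * 7, 1.0, 30.0),
    ])
    def test_formula_examples(self, angles, pi, mean):
        res = polarity_index(angles)
        assert res.pi == pytest.approx(pi, abs=1e-12)
        if mean is not None:
            assert res.mean_angle == pytest.approx(mean, abs=1e-9)
        assert res.n == len(angles)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            polarity_index([])

    @given(st.lists(st.floats(-180, 180), min_size=2, max_size=30),
           st.floats(-720, 720))
    @settings(max_examples=50, deadline=None)
    def test_rotation_invariance(self, angles, shift):
        """PI is unchanged by rotating every angle; the mean angle shifts."""
        base = polarity_index(angles)
        rot = polarity_index([a + shift for a in angles])
        assert rot.pi == pytest.approx(base.pi, abs=1e-9)
        if base.pi > 1e-6:
            expected = (base.mean_angle + shift + 180) % 360 - 180
            diff = (rot.mean_angle - expected + 180) % 360 - 180
            assert abs(diff) < 1e-6

    @given(st.lists(st.floats(-180, 180), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_order_and_duplication_invariance(self, angles):
        base = polarity_index(angles)
        assert polarity_index(angles[::-1]).pi == pytest.approx(base.pi)
        assert polarity_index(angles * 2).pi == pytest.approx(base.pi, abs=1e-12)

    def test_uniform_limit_is_small(self, rng):
        angles = rng.uniform(-180.0, 180.0, 100_000)
        assert polarity_index(angles).pi < 0.01


class TestPolarityAngle:
    def test_cardinal_directions(self, straight_edge):
        # nucleus at (10, 0); Golgi toward / beside / away from the wound
        assert polarity_angle((10, 0), (5, 0), straight_edge) == pytest.approx(0.0)
        assert polarity_angle((10, 0), (10, 5), straight_edge) == pytest.approx(90.0)
        assert polarity_angle((10, 0), (15, 0), straight_edge) == pytest.approx(180.0)

    def test_zero_vector_flagged(self, straight_edge):
        with pytest.raises(ValueError):
            polarity_angle((10, 0), (10, 0), straight_edge)

    def test_distance_to_polyline(self):
        edge = EdgeReference(np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0]]))
        assert edge.distance((5.0, 3.0)) == pytest.approx(3.0)
        assert edge.distance((13.0, 14.0)) == pytest.approx(5.0)  # past the corner


class TestAssignGolgi:
    def test_beats_greedy_on_constructed_case(self):
        # greedy pairs (0,0)<->(1,0) first, forcing (2,0)<->(-3,0): total 6;
        # the optimum crosses: total 4
        pairs, un_n, un_g = assign_golgi([(0, 0), (2, 0)], [(1, 0), (-3, 0)],
                                         max_distance=np.inf)
        assert set(pairs) == {(0, 1), (1, 0)}
        assert un_n == [] and un_g == []

    def test_identity_for_identical_lists(self, rng):
        pts = rng.uniform(0, 100, (6, 2))
        pairs, _, _ = assign_golgi(pts, pts)
        assert pairs == [(i, i) for i in range(6)]

    def test_matches_exhaustive_optimum(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 6))
            nuc = rng.uniform(0, 100, (n, 2))
            gol = rng.uniform(0, 100, (m, 2))
            pairs, _, _ = assign_golgi(nuc, gol, max_distance=np.inf)
            total = sum(np.hypot(*(nuc[i] - gol[j])) for i, j in pairs)
            k = min(n, m)
            best = min(
                sum(np.hypot(*(nuc[i] - gol[j])) for i, j in zip(rows, perm))
                for rows in itertools.combinations(range(n), k)
                for perm in itertools.permutations(range(m), k))
            assert total == pytest.approx(best)

    def test_max_distance_dissolves_pairs(self):
        pairs, un_n, un_g = assign_golgi([(0, 0)], [(100, 0)], max_distance=30)
        assert pairs == [] and un_n == [0] and un_g == [0]


class TestBinning:
    def test_one_cell_per_bin(self, straight_edge):
        recs = [CellPolarityRecord(i, (d, 0), alpha=0.0, distance_to_edge=d)
                for i, d in enumerate([10.0, 60.0, 110.0])]
        prof = bin_pi_by_distance(recs, straight_edge)
        assert len(prof.results) == 3
        assert all(r.n == 1 and r.pi == pytest.approx(1.0) for r in prof.results)

    def test_boundary_cell_in_second_bin(self, straight_edge):
        recs = [CellPolarityRecord(0, (50.0, 0), alpha=0.0, distance_to_edge=50.0),
                CellPolarityRecord(1, (10.0, 0), alpha=0.0, distance_to_edge=10.0),
                CellPolarityRecord(2, (70.0, 0), alpha=0.0, distance_to_edge=70.0)]
        prof = bin_pi_by_distance(recs, straight_edge)
        assert prof.results[0].n == 1
        assert prof.results[1].n == 2   # the 50 um cell joins [50, 100)

    def test_empty_bin_flagged_none(self, straight_edge):
        recs = [CellPolarityRecord(0, (10.0, 0), alpha=0.0, distance_to_edge=10.0),
                CellPolarityRecord(1, (120.0, 0), alpha=0.0, distance_to_edge=120.0)]
        prof = bin_pi_by_distance(recs, straight_edge)
        assert prof.results[1] is None


class TestDeriveThreshold:
    def test_hand_computed_example(self):
        profs = [_profile_from_pis([0.5, 0.06, 0.14, 0.10])]  # first bin excluded
        assert derive_threshold(profs) == pytest.approx(0.14, abs=1e-12)

    def test_zero_spread(self):
        profs = [_profile_from_pis([0.9, 0.2, 0.2, 0.2])]
        assert derive_threshold(profs) == pytest.approx(0.2)

    @given(st.floats(-0.05, 0.05))
    @settings(max_examples=20, deadline=None)
    def test_translation_covariance(self, c):
        pis = [0.5, 0.06, 0.14, 0.10]
        base = derive_threshold([_profile_from_pis(pis)])
        shifted = derive_threshold([_profile_from_pis([p + c for p in pis])])
        assert shifted == pytest.approx(base + c, abs=1e-9)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            derive_threshold([_profile_from_pis([0.5, 0.1])])


class TestAngularHistogram:
    def test_single_bin_holds_all(self):
        counts, centers = angular_histogram([0.0] * 10, n_bins=24)
        assert counts.sum() == 10
        assert counts.max() == 10

    def test_uniform_multinomial(self, rng):
        counts, _ = angular_histogram(rng.uniform(-180, 180, 24_000), n_bins=24)
        assert counts.sum() == 24_000
        # each bin ~ Binomial(24000, 1/24): mean 1000, sd ~31
        assert np.all(np.abs(counts - 1000) < 5 * 31.3)

    def test_wraparound_adjacency(self):
        counts, centers = angular_histogram([-179.0, 179.0], n_bins=24)
        occupied = np.nonzero(counts)[0]
        assert list(occupied) == [0, 23]   # circularly adjacent bins


class TestRayleigh:
    def test_aligned_sample_highly_significant(self):
        z, p = rayleigh_test([10.0] * 100)
        assert p < 1e-6

    def test_pi_zero_gives_p_one(self):
        z, p = rayleigh_test([0.0, 90.0, 180.0, 270.0, 0.0, 90.0, 180.0, 270.0])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_implementation(self, rng):
        """Cross-check Z and p against pingouin's circular Rayleigh test."""
        pingouin = pytest.importorskip("pingouin")
        angles = rng.uniform(-180, 180, 200)
        z, p = rayleigh_test(angles)
        z_ref, p_ref = pingouin.circ_rayleigh(np.radians(angles))
        assert z == pytest.approx(z_ref, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 1.0, 2.0])


class TestSegmentCentroids:
    def test_square_centroid(self):
        img = np.zeros((20, 20))
        img[0:5, 0:5] = 10.0
        cents = segment_centroids(img, pixel_size_um=1.0, min_area=5)
        assert len(cents) == 1
        assert cents[0] == pytest.approx((2.0, 2.0))

    def test_min_area_filter_and_order(self):
        img = np.zeros((30, 30))
        img[2:8, 2:8] = 5.0       # 36 px
        img[20:22, 20:22] = 5.0   # 4 px, below min_area
        cents = segment_centroids(img, pixel_size_um=0.5, min_area=10,
                                  threshold_method="nonzero")
        assert len(cents) == 1
        assert cents[0] == pytest.approx((4.5 * 0.5, 4.5 * 0.5))

    def test_unknown_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            segment_centroids(np.ones((5, 5)), pixel_size_um=None)


class TestClassifyRows:
    def test_lattice_columns_get_rows(self, straight_edge):
        recs = [CellPolarityRecord((i, j), (x, float(y)))
                for i, x in enumerate([10.0, 30.0, 50.0])
                for j, y in enumerate(range(10, 110, 20))]
        classify_rows(recs, straight_edge)
        for rec in recs:
            assert rec.row_index == rec.cell_id[0] + 1

    def test_single_row_all_leaders(self, straight_edge):
        recs = [CellPolarityRecord(j, (10.0, float(y)))
                for j, y in enumerate(range(10, 110, 20))]
        assert classify_rows(recs, straight_edge) == [1] * 5

    def test_leader_set_matches_nearest_cell_oracle(self, rng):
        """Row 1 = cells owning some point of the edge (nearest-site oracle)."""
        pts = rng.uniform([5.0, 0.0], [200.0, 300.0], size=(60, 2))
        recs = [CellPolarityRecord(i, tuple(p)) for i, p in enumerate(pts)]
        edge = EdgeReference(np.array([[0.0, -50.0], [0.0, 350.0]]))
        rows = np.array(classify_rows(recs, edge))
        # oracle: sample the same edge finely; the nearest nucleus of each
        # edge point has a neighborhood region touching the edge
        edge_pts = np.column_stack([np.zeros(20000), np.linspace(-50, 350, 20000)])
        d = np.hypot(pts[:, 0][:, None] - edge_pts[:, 0][None, :],
                     pts[:, 1][:, None] - edge_pts[:, 1][None, :])
        oracle_leaders = set(np.unique(np.argmin(d, axis=0)))
        assert set(np.nonzero(rows == 1)[0]) == oracle_leaders


def _profile_from_pis(pis):
    """Profile with one cell-backed PI per 50 um bin (helper)."""
    from ccpol.polarity import PolarityIndexResult, PolarityProfile
    edges = np.arange(len(pis) + 1) * 50.0
    results = [PolarityIndexResult(pi=p, mean_angle=0.0, n=10) for p in pis]
    return PolarityProfile(bin_edges=edges, results=results)
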