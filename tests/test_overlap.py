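"""Overlap degree, map algebra, EMD and the per-cohort overlap report."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

import tmsmap as tm
from tmsmap.overlap import OdCategory, emd_point_masses


def _map(grid, resolution=1.0, origin=(0.0, 0.0), muscle=""):
    return tm.MotorMap(
        origin=origin, resolution=resolution, grid=np.asarray(grid, float),
        muscle=muscle,
    )


def _random_map(rng, shape=(8, 8), peak=300.0):
    return _map(rng.uniform(0.0, peak, size=shape))


def dense_lp_emd(pos_a, w_a, pos_b, w_b):
    """Independent dense transportation-LP formulation of the EMD."""
    n, m = len(w_a), len(w_b)
    cost = cdist(pos_a, pos_b)
    A = []
    b = []
    for i in range(n):  # row sums
        row = np.zeros((n, m))
        row[i, :] = 1.0
        A.append(row.ravel())
        b.append(w_a[i])
    for j in range(m - 1):  # column sums (last one redundant)
        col = np.zeros((n, m))
        col[:, j] = 1.0
        A.append(col.ravel())
        b.append(w_b[j])
    res = linprog(cost.ravel(), A_eq=np.array(A), b_eq=np.array(b), bounds=(0, None))
    assert res.success
    return float(res.fun)


class TestIntersectionMap:
    def test_self_intersection_idempotent(self):
        rng = np.random.default_rng(0)
        a = _random_map(rng)
        np.testing.assert_array_equal(tm.intersection_map(a, a).grid, a.grid)

    def test_disjoint_supports_zero_overlap_area(self):
        a = _map(np.pad(np.full((3, 3), 200.0), ((0, 5), (0, 5))))
        b = _map(np.pad(np.full((3, 3), 200.0), ((5, 0), (5, 0))))
        inter = tm.intersection_map(a, b)
        assert tm.map_area(inter, 1e-6) == 0.0

    def test_min_max_area_identity_at_any_threshold(self):
        """area(A) + area(B) - area(min) = area(max), cell-counting oracle."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = _random_map(rng), _random_map(rng)
            for t in (30.0, 50.0, 150.0):
                lhs = tm.map_area(a, t) + tm.map_area(b, t) - tm.map_area(
                    tm.intersection_map(a, b), t
                )
                assert lhs == pytest.approx(tm.map_area(tm.union_map(a, b), t))

    def test_geometry_mismatch_is_error(self):
        a = _map(np.zeros((4, 4)))
        b = _map(np.zeros((4, 4)), origin=(1.0, 0.0))
        with pytest.raises(ValueError):
            tm.intersection_map(a, b)


class TestOverlapDegreeFormulas:
    def test_two_map_hand_substitution(self):
        od = tm.overlap_degree_two(tm.OverlapInputs(x1=100.0, x2=80.0, x12=40.0))
        assert od == pytest.approx(40.0 * 100.0 / 140.0, abs=1e-9)

    def test_two_map_degenerate_cases(self):
        assert tm.overlap_degree_two(
            tm.OverlapInputs(x1=100.0, x2=100.0, x12=100.0)
        ) == pytest.approx(100.0)
        assert tm.overlap_degree_two(tm.OverlapInputs(x1=5.0, x2=9.0, x12=0.0)) == 0.0
        assert math.isnan(
            tm.overlap_degree_two(tm.OverlapInputs(x1=0.0, x2=0.0, x12=0.0))
        )

    def test_three_map_hand_substitution(self):
        inp = tm.OverlapInputs(
            x1=100.0, x2=100.0, x3=100.0, x12=50.0, x13=50.0, x23=50.0, x123=25.0
        )
        assert tm.overlap_degree_three(inp) == pytest.approx(
            25.0 * 100.0 / 175.0, abs=1e-9
        )

    def test_three_map_degenerate_cases(self):
        same = tm.OverlapInputs(
            x1=7.0, x2=7.0, x3=7.0, x12=7.0, x13=7.0, x23=7.0, x123=7.0
        )
        assert tm.overlap_degree_three(same) == pytest.approx(100.0)
        none = tm.OverlapInputs(
            x1=10.0, x2=10.0, x3=10.0, x12=1.0, x13=1.0, x23=1.0, x123=0.0
        )
        assert tm.overlap_degree_three(none) == 0.0

    def test_symmetry_and_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x1, x2 = rng.uniform(10.0, 200.0, 2)
            x12 = rng.uniform(0.0, min(x1, x2))
            a = tm.overlap_degree_two(tm.OverlapInputs(x1=x1, x2=x2, x12=x12))
            b = tm.overlap_degree_two(tm.OverlapInputs(x1=x2, x2=x1, x12=x12))
            assert a == pytest.approx(b)
            assert 0.0 <= a <= 100.0
            bigger = tm.overlap_degree_two(
                tm.OverlapInputs(x1=x1, x2=x2, x12=min(x1, x2))
            )
            assert bigger >= a

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            tm.OverlapInputs(x1=10.0, x2=10.0, x12=20.0)
        with pytest.raises(ValueError):
            tm.OverlapInputs(x1=-1.0, x2=1.0, x12=0.0)


class TestCategorizeOd:
    @pytest.mark.parametrize(
        "od, expected",
        [
            (0.0, OdCategory.negligible),
            (15.0, OdCategory.negligible),
            (20.0, OdCategory.negligible),
            (20.01, OdCategory.low),
            (40.0, OdCategory.low),
            (55.0, OdCategory.medium),
            (60.0, OdCategory.medium),
            (75.0, OdCategory.high),
            (80.01, OdCategory.very_high),
            (100.0, OdCategory.very_high),
        ],
    )
    def test_band_assignment(self, od, expected):
        assert tm.categorize_od(od) is expected

    @pytest.mark.parametrize("od", [-0.1, 100.1, float("nan")])
    def test_out_of_range_rejected(self, od):
        with pytest.raises(ValueError):
            tm.categorize_od(od)


class TestCentroidDistance:
    def test_identical_maps_zero(self):
        rng = np.random.default_rng(3)
        a = _random_map(rng)
        assert tm.centroid_distance(a, a, 50.0) == 0.0

    def test_translation_by_3_4_gives_5(self):
        grid = np.zeros((12, 12))
        grid[2:5, 2:5] = 200.0
        a = _map(grid)
        b = _map(grid, origin=(3.0, 4.0))
        # identical grids shifted in space: must resample onto one geometry
        ca = tm.map_centroid(a, 50.0)
        cb = tm.map_centroid(b, 50.0)
        assert math.hypot(ca[0] - cb[0], ca[1] - cb[1]) == pytest.approx(5.0)

    def test_undefined_centroid_gives_nan(self):
        a = _map(np.zeros((4, 4)))
        b = _map(np.full((4, 4), 100.0))
        assert math.isnan(tm.centroid_distance(a, b, 50.0))


class TestEarthMoversDistance:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(4)
        a = _random_map(rng)
        assert tm.earth_movers_distance(a, a, 50.0) == pytest.approx(0.0, abs=1e-9)

    def test_two_point_masses(self):
        a = _map(np.zeros((3, 12)))
        b = _map(np.zeros((3, 12)))
        a.grid[1, 0] = 100.0
        b.grid[1, 10] = 100.0
        assert tm.earth_movers_distance(a, b, 50.0) == pytest.approx(10.0, abs=1e-9)

    def test_empty_distribution_undefined(self):
        a = _map(np.zeros((4, 4)))
        b = _map(np.full((4, 4), 100.0))
        assert math.isnan(tm.earth_movers_distance(a, b, 50.0))

    def test_matches_dense_lp_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = _random_map(rng, shape=(4, 4))
            b = _random_map(rng, shape=(4, 4))
            got = tm.earth_movers_distance(a, b, 50.0)
            pa, wa = _distribution_of(a)
            pb, wb = _distribution_of(b)
            assert got == pytest.approx(dense_lp_emd(pa, wa, pb, wb), abs=1e-6)

    def test_metric_axioms_on_small_grids(self):
        rng = np.random.default_rng(6)
        maps = [_random_map(rng, shape=(3, 3)) for _ in range(6)]
        d = {}
        for i, j in itertools.combinations(range(6), 2):
            d[i, j] = d[j, i] = tm.earth_movers_distance(maps[i], maps[j], 50.0)
            assert d[i, j] >= 0.0
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_coarsening_preserves_bulk_distance(self):
        a = _map(np.zeros((8, 24)))
        b = _map(np.zeros((8, 24)))
        a.grid[2:6, 0:4] = 100.0
        b.grid[2:6, 20:24] = 100.0
        fine = tm.earth_movers_distance(a, b, 50.0)
        coarse = tm.earth_movers_distance(a, b, 50.0, coarsen=2)
        assert coarse == pytest.approx(fine, abs=1.0)


def _distribution_of(m, threshold=50.0):
    yy, xx = np.nonzero(m.grid > threshold)
    w = m.grid[yy, xx]
    pos = np.column_stack(
        [m.origin[0] + xx * m.resolution, m.origin[1] + yy * m.resolution]
    )
    return pos, w / w.sum()


class TestOverlapReport:
    def _three_maps(self, rng):
        maps = {}
        for k, name in enumerate(["FCR", "FPB", "ADM"]):
            grid = np.zeros((14, 14))
            grid[2 + k : 9 + k, 2 + k : 9 + k] = 100.0 + 40.0 * k
            maps[name] = _map(grid, muscle=name)
        return maps

    def test_nine_records_per_kind_for_three_maps(self):
        rng = np.random.default_rng(7)
        report = tm.overlap_report(self._three_maps(rng), threshold_uv=50.0)
        assert len(report) == 18  # 9 per kind x {area, volume}
        for kind in ("area", "volume"):
            sub = report[report["kind"] == kind]
            assert len(sub) == 9
            assert (sub["adjacent_set"] == "ALL").sum() == 3

    def test_identical_triplicate_maps_full_overlap(self):
        rng = np.random.default_rng(8)
        base = _random_map(rng, shape=(10, 10))
        maps = {n: _map(base.grid.copy(), muscle=n) for n in ["a", "b", "c"]}
        report = tm.overlap_report(maps, threshold_uv=50.0)
        assert np.allclose(report["od_pct"], 100.0)
        assert set(report.loc[report["adjacent_set"] != "ALL", "emd_mm"]) == {0.0}
        assert np.allclose(report["centroid_dist_mm"], 0.0)
        assert report.loc[report["adjacent_set"] == "ALL", "emd_mm"].isna().all()

    def test_two_maps_give_two_records_per_kind(self):
        rng = np.random.default_rng(9)
        maps = {"a": _random_map(rng), "b": _random_map(rng)}
        report = tm.overlap_report(maps, threshold_uv=50.0)
        assert len(report) == 4
        assert (report["adjacent_set"] == "ALL").sum() == 0

    def test_od_values_symmetric_between_targets(self):
        rng = np.random.default_rng(10)
        maps = self._three_maps(rng)
        report = tm.overlap_report(maps, threshold_uv=50.0)
        area = report[report["kind"] == "area"]
        ab = area[(area.target == "FCR") & (area.adjacent_set == "FPB")].od_pct.iloc[0]
        ba = area[(area.target == "FPB") & (area.adjacent_set == "FCR")].od_pct.iloc[0]
        assert ab == pytest.approx(ba)
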