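"""Land-use change mathematics: areas, structure change, dynamic degrees,
transfer matrices and kappa."""
import numpy as np
import pandas as pd
import pytest

from rseikit import (
    AreaTable,
    LandUseRaster,
    class_areas,
    cohen_kappa,
    comprehensive_dynamics,
    delta_i,
    single_dynamics,
    structure_change_rate,
    transfer_matrix,
    validate_transfer_matrix,
)
from rseikit.datasets import caohai_transfer_matrix
from rseikit.errors import AlignmentError, ConfigurationError, EmptyInputError
from rseikit.landuse import dynamics_report
from rseikit.synth import default_scene_spec, generate_landuse_pair
from rseikit.types import (
    ALL_CLASSES,
    CONSTRUCTION,
    CULTIVATED,
    FOREST,
    GRASSLAND,
    UNUSED,
    WATER,
)


class TestClassAreas:
    def test_single_class(self):
        lu = LandUseRaster(np.full((3, 3), WATER, dtype=int), cell_area=0.0009)
        at = class_areas(lu)
        assert at.areas[WATER] == pytest.approx(0.0081)
        assert at.areas.drop(WATER).sum() == 0

    def test_counts_with_nodata(self):
        grid = np.array([[WATER, FOREST], [FOREST, 0]])
        at = class_areas(LandUseRaster(grid, cell_area=1.0))
        assert at.areas[WATER] == 1 and at.areas[FOREST] == 2
        assert at.total == 3  # nodata excluded

    def test_all_nodata_raises(self):
        with pytest.raises(EmptyInputError):
            class_areas(LandUseRaster(np.zeros((2, 2), dtype=int)))

    def test_generator_bookkeeping(self):
        spec = default_scene_spec((50, 50))
        lu_a, _, _ = generate_landuse_pair(spec, seed=3)
        at = class_areas(lu_a)
        for c, n in spec.class_counts.items():
            assert at.areas[c] == pytest.approx(n * spec.cell_area)


# Printed change-rate columns (percentage points). Two cells of the
# published 2000–2020 column are rounding-inconsistent with the areas
# (water prints 1.51, grassland 2.96; the areas give 1.50/2.95 under every
# self-consistent convention), so those two are checked at |Δ| ≤ 0.015.
K_COLUMNS = {
    (2000, 2010): {WATER: 1.06, CONSTRUCTION: 2.27, GRASSLAND: -4.91,
                   CULTIVATED: 1.27, FOREST: -0.06, UNUSED: 0.36},
    (2010, 2020): {WATER: 0.44, CONSTRUCTION: 4.50, GRASSLAND: 7.86,
                   CULTIVATED: -12.29, FOREST: 1.69, UNUSED: -2.21},
    (2000, 2020): {WATER: 1.51, CONSTRUCTION: 6.77, GRASSLAND: 2.96,
                   CULTIVATED: -11.02, FOREST: 1.63, UNUSED: -1.85},
}
_ROUNDING_INCONSISTENT = {((2000, 2020), WATER), ((2000, 2020), GRASSLAND)}


class TestStructureChange:
    @pytest.mark.parametrize("pair", sorted(K_COLUMNS))
    def test_reproduces_published_columns(self, caohai_tables, pair):
        a, b = pair
        k = structure_change_rate(caohai_tables[a], caohai_tables[b])
        for c, expected in K_COLUMNS[pair].items():
            tol = 0.015 if (pair, c) in _ROUNDING_INCONSISTENT else 0.005
            assert k[c] == pytest.approx(expected, abs=tol), (pair, c)

    def test_identity_is_zero(self, caohai_tables):
        k = structure_change_rate(caohai_tables[2000], caohai_tables[2000])
        assert np.allclose(k, 0)

    def test_sums_to_zero(self, caohai_tables, rng):
        # proportions each sum to 1, so the K column always sums to 0
        for _ in range(20):
            a = AreaTable("a", pd.Series(rng.uniform(0.1, 50, 6), index=list(ALL_CLASSES)))
            b = AreaTable("b", pd.Series(rng.uniform(0.1, 50, 6), index=list(ALL_CLASSES)))
            assert structure_change_rate(a, b).sum() == pytest.approx(0, abs=1e-9)


class TestSingleDynamics:
    # published per-class change values over 2000–2020 (km²)
    CHANGE_2000_2020 = {WATER: 1.494, CONSTRUCTION: 6.721, GRASSLAND: 2.933,
                       FOREST: 1.621, UNUSED: -1.832}

    def test_change_values(self, caohai_tables):
        out = single_dynamics(caohai_tables[2000], caohai_tables[2020], 20)
        for c, expected in self.CHANGE_2000_2020.items():
            assert out.loc[c, "change_km2"] == pytest.approx(expected, abs=5e-4)

    def test_no_change(self, caohai_tables):
        out = single_dynamics(caohai_tables[2010], caohai_tables[2010], 10)
        assert np.allclose(out, 0)

    def test_annualized_rate_formula(self, caohai_tables):
        # literal evaluation: 100·(1.494/21.974)/20 for water over 20 years
        out = single_dynamics(caohai_tables[2000], caohai_tables[2020], 20)
        assert out.loc[WATER, "annual_rate_pct"] == pytest.approx(
            100 * (1.494 / 21.974) / 20, abs=1e-6
        )
        assert round(out.loc[WATER, "annual_rate_pct"], 2) == 0.34

    def test_zero_base_is_undefined(self):
        a = AreaTable.from_mapping("a", {"water": 0.0, "forest": 1.0})
        b = AreaTable.from_mapping("b", {"water": 2.0, "forest": 1.0})
        out = single_dynamics(a, b, 10)
        assert out.loc[WATER, "change_km2"] == 2.0
        assert np.isnan(out.loc[WATER, "annual_rate_pct"])


class TestComprehensiveDynamics:
    def test_year_2000_value(self, caohai_tables):
        assert round(comprehensive_dynamics(caohai_tables[2000]), 2) == 214.37

    @pytest.mark.parametrize(
        "cls,expected", [(UNUSED, 100.0), (CONSTRUCTION, 400.0)]
    )
    def test_bounds_attained(self, cls, expected):
        at = AreaTable("x", pd.Series({cls: 10.0}))
        assert comprehensive_dynamics(at) == pytest.approx(expected)

    def test_increases_when_area_upgrades(self, caohai_tables):
        base = caohai_tables[2000]
        shifted = base.areas.copy()
        shifted[UNUSED] -= 1.0
        shifted[CONSTRUCTION] += 1.0
        assert comprehensive_dynamics(AreaTable("x", shifted)) > comprehensive_dynamics(base)

    def test_missing_grade_raises(self):
        at = AreaTable.from_mapping("x", {"water": 1.0, "forest": 1.0})
        with pytest.raises(ConfigurationError):
            comprehensive_dynamics(at, grading={WATER: 2})


class TestDeltaI:
    def test_developing_phase(self):
        d, label = delta_i(214.37, 218.82)
        assert d == pytest.approx(4.45) and label == "developing"

    def test_stable(self):
        assert delta_i(200.0, 200.0) == (0.0, "stable")

    def test_composition_with_recomputed_k2(self, caohai_tables):
        k2 = {y: comprehensive_dynamics(t) for y, t in caohai_tables.items()}
        d, label = delta_i(k2[2010], k2[2020])
        assert d == pytest.approx(k2[2020] - k2[2010])
        assert label == "declining"  # intensity falls as cultivated land reverts


class TestTransferMatrix:
    def test_identity_pair_is_diagonal(self):
        grid = np.array([[WATER, FOREST], [GRASSLAND, CULTIVATED]])
        lu = LandUseRaster(grid, cell_area=1.0)
        tm = transfer_matrix(lu, lu)
        assert np.all(tm.reduce_area == 0) and np.all(tm.add_area == 0)
        assert tm.grand_total == 4

    def test_hand_enumerated_toy(self):
        a = LandUseRaster(np.array([[1, 1, 3], [3, 3, 5], [5, 0, 2]]), cell_area=2.0)
        b = LandUseRaster(np.array([[1, 3, 3], [3, 4, 5], [5, 2, 0]]), cell_area=2.0)
        tm = transfer_matrix(a, b)
        # cell-by-cell: 1→1, 1→3, 3→3, 3→3, 3→4, 5→5, 5→5; two nodata cells drop
        assert tm.cells.loc[1, 1] == 2.0
        assert tm.cells.loc[1, 3] == 2.0
        assert tm.cells.loc[3, 3] == 4.0
        assert tm.cells.loc[3, 4] == 2.0
        assert tm.cells.loc[5, 5] == 4.0
        assert tm.grand_total == 14.0  # 7 jointly valid cells × 2 km²

    def test_matches_exhaustive_tally(self, rng):
        for shape in [(7, 9), (40, 40), (100, 100)]:
            ga = rng.integers(0, 7, shape)
            gb = rng.integers(0, 7, shape)
            tm = transfer_matrix(
                LandUseRaster(ga, cell_area=1.0), LandUseRaster(gb, cell_area=1.0)
            )
            brute = np.zeros((7, 7))
            for i in range(shape[0]):
                for j in range(shape[1]):
                    brute[ga[i, j], gb[i, j]] += 1
            assert np.array_equal(tm.cells.values, brute[1:, 1:])

    def test_marginals_reproduce_class_areas(self, rng):
        ga, gb = rng.integers(1, 7, (30, 30)), rng.integers(1, 7, (30, 30))
        # unit cell area: marginals are integer counts, equality is exact
        lu_a, lu_b = LandUseRaster(ga, 1.0), LandUseRaster(gb, 1.0)
        tm = transfer_matrix(lu_a, lu_b)
        assert np.array_equal(tm.row_totals.values, class_areas(lu_a).areas.values)
        assert np.array_equal(tm.col_totals.values, class_areas(lu_b).areas.values)
        # fractional cell area: exact up to float summation order
        lu_a, lu_b = LandUseRaster(ga, 0.0009), LandUseRaster(gb, 0.0009)
        tm = transfer_matrix(lu_a, lu_b)
        np.testing.assert_allclose(
            tm.row_totals.values, class_areas(lu_a).areas.values, rtol=1e-13
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            transfer_matrix(
                LandUseRaster(np.ones((2, 2), dtype=int)),
                LandUseRaster(np.ones((3, 3), dtype=int)),
            )


class TestValidateTransferMatrix:
    def test_published_2000_2010_marginals(self, caohai_tables):
        tm = caohai_transfer_matrix(2000, 2010)
        # water row: off-diagonal sum equals the printed "reduce" column
        assert tm.reduce_area[WATER] == pytest.approx(0.553, abs=1e-9)
        report = validate_transfer_matrix(
            tm, caohai_tables[2000], caohai_tables[2010], tol=0.005
        )
        assert report.passed, report.as_frame()

    @pytest.mark.parametrize("pair", [(2010, 2020), (2000, 2020)])
    def test_published_later_pairs(self, caohai_tables, pair):
        tm = caohai_transfer_matrix(*pair)
        report = validate_transfer_matrix(
            tm, caohai_tables[pair[0]], caohai_tables[pair[1]], tol=0.005
        )
        assert report.passed, report.as_frame()

    def test_construction_net_change_2000_2020(self, caohai_tables):
        tm = caohai_transfer_matrix(2000, 2020)
        # printed marginals: add 7.787 − reduce 1.066 = 6.721 net; the cells
        # themselves reproduce that within 3-dp print rounding
        net = tm.add_area[CONSTRUCTION] - tm.reduce_area[CONSTRUCTION]
        assert net == pytest.approx(7.787 - 1.066, abs=0.002)
        assert net == pytest.approx(9.034 - 2.313, abs=0.002)

    def test_diagonal_matrix_zero_residuals(self, caohai_tables):
        at = caohai_tables[2000]
        cells = pd.DataFrame(
            np.diag(at.areas.values), index=list(ALL_CLASSES), columns=list(ALL_CLASSES)
        )
        from rseikit.types import TransferMatrix

        report = validate_transfer_matrix(
            TransferMatrix("a", "b", cells), at, AreaTable("b", at.areas), tol=1e-12
        )
        assert report.passed
        assert all(c.max_residual <= 1e-12 for c in report.checks)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(np.diag([5, 7, 9])) == pytest.approx(1.0)

    def test_chance_agreement(self):
        # rows proportional to column marginals → observed = chance → 0
        m = np.outer([0.3, 0.7], [40, 60])
        assert cohen_kappa(m) == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        m = [[30, 5], [10, 55]]
        p_o = 85 / 100
        p_e = (35 / 100) * (40 / 100) + (65 / 100) * (60 / 100)
        assert cohen_kappa(m) == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_matches_sklearn_on_labels(self, rng):
        from sklearn.metrics import cohen_kappa_score, confusion_matrix

        y1 = rng.integers(0, 4, 500)
        y2 = np.where(rng.random(500) < 0.7, y1, rng.integers(0, 4, 500))
        assert cohen_kappa(confusion_matrix(y1, y2)) == pytest.approx(
            cohen_kappa_score(y1, y2)
        )

    def test_degenerate_single_category(self):
        assert np.isnan(cohen_kappa([[10, 0], [0, 0]]))


def test_dynamics_report_roundtrip(caohai_tables):
    rep = dynamics_report(caohai_tables[2000], caohai_tables[2010], 10)
    d = rep.to_dict()
    assert d["k2"]["2000"] == 214.37
    assert d["phase"] == "developing"
    assert d["change_km2"]["construction"] == pytest.approx(2.255)
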