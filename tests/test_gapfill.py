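"""Gap-filling: component assembly, the two linear relations, series completion."""

import numpy as np
import pytest

from cropdep import (AnnualField, GridSpec, WorldConfig, assemble_total,
                     complete_series, degrade_to_anchors, fit_eq2,
                     generate_world, interp_eq1, predict_eq2)
from cropdep.gapfill import EARLY_ANCHORS, LATE_ANCHORS


def _grid():
    return GridSpec(np.array([-30.0, 30.0]), np.array([-90.0, 0.0, 90.0]))


def _field(grid, values, year=None, units="kg N ha-1 yr-1"):
    return AnnualField(grid, np.asarray(values, dtype=float), units=units, year=year)


class TestAssembleTotal:
    def test_component_sum(self):
        g = _grid()
        parts = [_field(g, np.full(g.shape, v), year=2000) for v in (1, 2, 3, 4)]
        assert np.all(assemble_total(*parts).values == 10.0)

    def test_zero_components_give_zero(self):
        g = _grid()
        parts = [_field(g, np.zeros(g.shape), year=2000) for _ in range(4)]
        assert np.all(assemble_total(*parts).values == 0.0)

    def test_grid_mismatch_rejected(self):
        g = _grid()
        other = GridSpec(np.array([-10.0, 10.0]), np.array([-90.0, 0.0, 90.0]))
        parts = [_field(g, np.zeros(g.shape), year=2000) for _ in range(3)]
        with pytest.raises(ValueError, match="grid"):
            assemble_total(*parts, _field(other, np.zeros(other.shape), year=2000))

    def test_commutes_with_national_aggregation(self, small_world):
        from cropdep import national_rate
        rng = np.random.default_rng(2)
        g = small_world.grid
        comps = [_field(g, rng.uniform(0, 5, g.shape), year=2000) for _ in range(4)]
        crop = small_world.cropland_series[2000]
        total_then_agg = national_rate(assemble_total(*comps), crop, small_world.mask)
        agg_then_total = sum(national_rate(c, crop, small_world.mask) for c in comps)
        np.testing.assert_allclose(total_then_agg.values, agg_then_total.values,
                                   rtol=1e-12)


class TestInterpEq1:
    def test_midpoint_of_line(self):
        g = _grid()
        out = interp_eq1(_field(g, np.full(g.shape, 5.0)),
                         _field(g, np.full(g.shape, 15.0)), 1965)
        assert np.all(out.values == 10.0)

    def test_constant_anchors_stay_constant(self):
        g = _grid()
        for y in range(1961, 1970):
            out = interp_eq1(_field(g, np.full(g.shape, 7.0)),
                             _field(g, np.full(g.shape, 7.0)), y)
            np.testing.assert_allclose(out.values, 7.0, rtol=1e-14)

    def test_two_point_line_at_1961(self):
        # line through (1960, 5) and (1970, 15): 5 + (1961-1960)*1 = 6
        g = _grid()
        out = interp_eq1(_field(g, np.full(g.shape, 5.0)),
                         _field(g, np.full(g.shape, 15.0)), 1961)
        np.testing.assert_allclose(out.values, 6.0, rtol=1e-14)

    @pytest.mark.parametrize("year", [1960, 1970, 1975])
    def test_year_outside_open_interval_rejected(self, year):
        g = _grid()
        with pytest.raises(ValueError):
            interp_eq1(_field(g, np.zeros(g.shape)), _field(g, np.ones(g.shape)), year)


class TestFitPredictEq2:
    def test_exact_affine_relation_recovered(self):
        g = _grid()
        emis = {y: _field(g, np.full(g.shape, float(y - 1960)), units="kg N")
                for y in EARLY_ANCHORS}
        dep = {y: _field(g, 2.0 + 0.5 * emis[y].values) for y in EARLY_ANCHORS}
        params = fit_eq2(dep, emis)
        np.testing.assert_allclose(params.beta0, 2.0, atol=1e-12)
        np.testing.assert_allclose(params.beta1, 0.5, atol=1e-12)

    def test_constant_deposition_gives_zero_slope(self):
        g = _grid()
        emis = {y: _field(g, np.full(g.shape, float(y)), units="kg N")
                for y in EARLY_ANCHORS}
        dep = {y: _field(g, np.full(g.shape, 3.25)) for y in EARLY_ANCHORS}
        params = fit_eq2(dep, emis)
        np.testing.assert_allclose(params.beta1, 0.0, atol=1e-12)
        np.testing.assert_allclose(params.beta0, 3.25, atol=1e-12)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        g = _grid()
        years = list(LATE_ANCHORS)
        E = {y: _field(g, rng.uniform(1, 10, g.shape), units="kg N") for y in years}
        D = {y: _field(g, 1.5 + 0.8 * E[y].values + rng.normal(0, 0.3, g.shape))
             for y in years}
        params = fit_eq2(D, E)
        for i in range(g.nlat):
            for j in range(g.nlon):
                x = np.array([E[y].values[i, j] for y in years])
                y_ = np.array([D[y].values[i, j] for y in years])
                n = len(x)
                A = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
                rhs = np.array([y_.sum(), (x * y_).sum()])
                b0, b1 = np.linalg.solve(A, rhs)
                assert abs(params.beta0[i, j] - b0) < 1e-10
                assert abs(params.beta1[i, j] - b1) < 1e-10

    def test_degenerate_cells_fall_back_to_anchor_mean(self):
        g = _grid()
        emis = {y: _field(g, np.full(g.shape, 4.0), units="kg N") for y in EARLY_ANCHORS}
        dep = {y: _field(g, np.full(g.shape, float(y - 1960))) for y in EARLY_ANCHORS}
        params = fit_eq2(dep, emis)
        assert params.degenerate.all()
        expected = np.mean([y - 1960 for y in EARLY_ANCHORS])
        np.testing.assert_allclose(params.beta0, expected, rtol=1e-12)
        np.testing.assert_allclose(params.beta1, 0.0)

    def test_fewer_than_two_anchors_rejected(self):
        g = _grid()
        one = {1970: _field(g, np.ones(g.shape))}
        with pytest.raises(ValueError, match="anchor"):
            fit_eq2(one, {1970: _field(g, np.ones(g.shape), units="kg N")})

    def test_predict_evaluates_and_clips(self):
        g = _grid()
        emis8 = _field(g, np.full(g.shape, 8.0), units="kg N", year=1985)
        params = fit_eq2(
            {y: _field(g, 2.0 + 0.5 * np.full(g.shape, float(y - 1960)))
             for y in EARLY_ANCHORS},
            {y: _field(g, np.full(g.shape, float(y - 1960)), units="kg N")
             for y in EARLY_ANCHORS})
        np.testing.assert_allclose(predict_eq2(params, emis8).values, 6.0, rtol=1e-12)
        params.beta0[:] = -5.0
        params.beta1[:] = 0.0
        assert np.all(predict_eq2(params, emis8).values == 0.0)

    def test_predict_grid_mismatch_rejected(self):
        g = _grid()
        params = fit_eq2(
            {y: _field(g, np.full(g.shape, float(y))) for y in (1970, 1980)},
            {y: _field(g, np.full(g.shape, float(y)), units="kg N")
             for y in (1970, 1980)})
        other = GridSpec(np.array([-10.0, 10.0]), np.array([-90.0, 0.0, 90.0]))
        with pytest.raises(ValueError, match="grid"):
            predict_eq2(params, _field(other, np.ones(other.shape), units="kg N"))


class TestCompleteSeries:
    def test_regime_provenance_labels(self, small_world):
        anchors = degrade_to_anchors(small_world.deposition_truth)
        series = complete_series(anchors, small_world.emissions)
        assert series.provenance[1985] == "eq2-interp"
        assert series.provenance[2016] == "eq2-extrap"
        assert series.provenance[2020] == "held"
        assert series.provenance[1965] == "eq1-interp"
        assert series.provenance[2003] == "observed-anchor"

    def test_constant_world_stays_constant(self):
        g = _grid()
        anchors = {y: _field(g, np.full(g.shape, 9.0), year=y)
                   for y in (1960,) + EARLY_ANCHORS + LATE_ANCHORS}
        emis = {y: _field(g, np.full(g.shape, float(y)), units="kg N", year=y)
                for y in range(1970, 2019)}
        series = complete_series(anchors, emis)
        for y in range(1961, 2021):
            np.testing.assert_allclose(series[y].values, 9.0, rtol=1e-12)

    def test_exact_recovery_of_withheld_years(self, small_world):
        anchors = degrade_to_anchors(small_world.deposition_truth)
        series = complete_series(anchors, small_world.emissions)
        for y in range(1961, 2021):
            np.testing.assert_allclose(series[y].values,
                                       small_world.deposition_truth[y].values,
                                       rtol=0, atol=1e-9)

    def test_anchor_years_pass_through_bit_identical(self, small_world):
        anchors = degrade_to_anchors(small_world.deposition_truth)
        series = complete_series(anchors, small_world.emissions)
        for y in (1970, 1980, 1990, 2000, 2013):
            assert series[y].values is anchors[y].values

    def test_missing_anchor_error_names_the_year(self, small_world):
        anchors = degrade_to_anchors(small_world.deposition_truth)
        del anchors[1960]
        with pytest.raises(ValueError, match="1960"):
            complete_series(anchors, small_world.emissions)

    def test_output_never_negative_and_clipping_counted(self):
        g = _grid()
        rng = np.random.default_rng(3)
        # steeply falling deposition vs emission -> negative extrapolations
        anchors = {}
        for y in (1960,) + EARLY_ANCHORS + LATE_ANCHORS:
            anchors[y] = _field(g, np.maximum(0.1, 20.0 - 0.4 * (y - 1960)
                                              + rng.normal(0, 0.1, g.shape)), year=y)
        emis = {y: _field(g, np.full(g.shape, float(y - 1960)), units="kg N", year=y)
                for y in range(1970, 2019)}
        series = complete_series(anchors, emis)
        for y in range(1961, 2021):
            assert series[y].values.min() >= 0.0
        assert sum(series.n_clipped.values()) > 0


class TestDegradeToAnchors:
    def test_pattern_retention_count(self, small_world):
        anchors = degrade_to_anchors(small_world.deposition_truth)
        # 1960 + {1970, 1980, 1990} + 1997-2013 = 21 anchor maps
        assert len(anchors) == 21
        assert sum(1 for y in anchors if 1961 <= y <= 2020) == 20

    def test_full_pattern_is_identity(self, small_world):
        truth = small_world.deposition_truth
        full = degrade_to_anchors(truth, pattern=tuple(truth.years))
        assert full.keys() == set(truth.years)

    def test_retained_years_bit_equal(self, small_world):
        anchors = degrade_to_anchors(small_world.deposition_truth)
        for y, fld in anchors.items():
            assert fld is small_world.deposition_truth[y]

    def test_empty_pattern_rejected(self, small_world):
        with pytest.raises(ValueError):
            degrade_to_anchors(small_world.deposition_truth, pattern=())
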