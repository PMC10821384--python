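"""Deviation statistics and the temporal uncertainty U_V(t)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radonmetry import (
    CONSERVATIVE_UV,
    RadonSeries,
    TemporalUncertaintyCurve,
    TemporalUncertaintyEstimator,
    build_ensemble,
    conservative_uv,
    deviations,
    estimate_uv,
    estimate_uv_curve,
    nearest_rank_percentile,
    pool_deviations,
)
from radonmetry.errors import SpotMeasurementError


def _pool_from(values_by_t, n_rooms=1):
    from radonmetry.temporal import DeviationPool

    return DeviationPool(
        pools={t: np.asarray(v, float) for t, v in values_by_t.items()},
        n_rooms=n_rooms,
        annual_averages=(200.0,) * n_rooms,
    )


class TestDeviations:
    def test_constant_series_gives_zero_deviations(self, constant_series):
        ens = build_ensemble(constant_series, [48.0, 168.0])
        d = deviations(ens, 120.0)
        for arr in d.values():
            np.testing.assert_allclose(arr, 0.0)

    def test_ratio_formula(self, constant_series):
        ens = build_ensemble(constant_series, [48.0])
        # C_AA twice the windowed value -> D = 1; half -> D = -0.5
        assert deviations(ens, 240.0)[48.0][0] == pytest.approx(1.0)
        assert deviations(ens, 60.0)[48.0][0] == pytest.approx(-0.5)

    def test_deviations_bounded_below(self, sim_room):
        ens = build_ensemble(sim_room, [48.0, 720.0])
        d = deviations(ens, float(sim_room.values.mean()))
        assert all((arr > -1.0).all() for arr in d.values())

    def test_zero_floor_applied(self):
        s = RadonSeries(values=np.zeros(2920), step_hours=3.0)
        ens = build_ensemble(s, [48.0])
        d = deviations(ens, 100.0, zero_floor=0.1)
        np.testing.assert_allclose(d[48.0], 100.0 / 0.1 - 1.0)
        with pytest.raises(ValueError):
            deviations(ens, 100.0, zero_floor=0.0)

    def test_nonpositive_annual_average_rejected(self, constant_series):
        ens = build_ensemble(constant_series, [48.0])
        with pytest.raises(ValueError):
            deviations(ens, 0.0)


class TestNearestRankPercentile:
    def test_uniform_grid_order_statistic(self):
        pool = [0.01 * k for k in range(1, 101)]
        assert nearest_rank_percentile(pool, 95.0) == pytest.approx(0.95)

    def test_two_level_distribution(self):
        # exactly 5% of the mass above 1.2 -> the 95th percentile sits at 1.2
        pool = np.concatenate([np.full(94, 0.1), [1.2], np.full(5, 2.0)])
        rng = np.random.default_rng(0)
        rng.shuffle(pool)
        assert nearest_rank_percentile(pool, 95.0) == pytest.approx(1.2)

    @given(
        values=st.lists(
            st.floats(min_value=-0.9, max_value=10.0, allow_nan=False),
            min_size=1, max_size=300,
        ),
        p=st.floats(min_value=1.0, max_value=100.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_inverted_cdf_quantile(self, values, p):
        # independent route: numpy's inverted-CDF quantile is the same
        # order statistic
        ours = nearest_rank_percentile(values, p)
        ref = np.percentile(values, p, method="inverted_cdf")
        assert ours == pytest.approx(float(ref))

    @given(
        values=st.lists(
            st.floats(min_value=-0.9, max_value=10.0, allow_nan=False),
            min_size=5, max_size=300,
        ),
        p=st.floats(min_value=50.0, max_value=99.9),
    )
    @settings(max_examples=80, deadline=None)
    def test_exceedance_guarantee(self, values, p):
        q = nearest_rank_percentile(values, p)
        frac_above = np.mean(np.asarray(values) > q)
        assert frac_above <= (100.0 - p) / 100.0 + 1e-12


class TestEstimateUv:
    def test_all_zero_deviations(self):
        pool = _pool_from({48.0: np.zeros(100)})
        assert estimate_uv(pool, 48.0) == 0.0

    def test_negative_percentile_clipped_at_zero(self):
        pool = _pool_from({48.0: np.full(100, -0.4)})
        assert estimate_uv(pool, 48.0) == 0.0

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(5)
        pool = _pool_from({48.0: rng.lognormal(0, 0.5, 500) - 1.0})
        uvs = [estimate_uv(pool, 48.0, percentile=p) for p in (50, 75, 90, 95, 99)]
        assert uvs == sorted(uvs)

    def test_pure_function_of_pooled_multiset(self, sim_ensemble_matrix):
        rooms = [
            RadonSeries(values=row, step_hours=3.0) for row in sim_ensemble_matrix
        ]
        ensembles = [build_ensemble(s, [48.0]) for s in rooms]
        c_aas = [float(s.values.mean()) for s in rooms]
        pooled = pool_deviations(ensembles, c_aas)
        # manual concatenation in a different room order gives the same U_V
        reordered = pool_deviations(ensembles[::-1], c_aas[::-1])
        assert estimate_uv(pooled, 48.0) == pytest.approx(
            estimate_uv(reordered, 48.0)
        )

    def test_missing_interval_raises(self):
        pool = _pool_from({48.0: np.zeros(100)})
        with pytest.raises(KeyError):
            estimate_uv(pool, 168.0)


class TestConservativeCurve:
    def test_printed_knots(self):
        assert conservative_uv(48.0) == 1.0
        assert conservative_uv(168.0) == 0.7

    def test_spot_measurement_rejected(self):
        with pytest.raises(SpotMeasurementError):
            conservative_uv(2.0)

    def test_log_linear_interpolation(self):
        t = 84.0
        expected = 1.0 - 0.3 * math.log(t / 48.0) / math.log(168.0 / 48.0)
        assert conservative_uv(t) == pytest.approx(expected)

    def test_constant_extrapolation_beyond_last_knot(self):
        assert conservative_uv(720.0) == 0.7

    def test_user_extended_table(self):
        table = TemporalUncertaintyCurve(
            knots=((48.0, 1.0), (168.0, 0.7), (720.0, 0.4), (4320.0, 0.15)),
            source="conservative",
        )
        assert conservative_uv(720.0, table) == pytest.approx(0.4)
        assert conservative_uv(8000.0, table) == pytest.approx(0.15)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            TemporalUncertaintyCurve(knots=((168.0, 0.7), (48.0, 1.0)))
        with pytest.raises(ValueError):
            TemporalUncertaintyCurve(knots=((48.0, -0.1),))


class TestEstimator:
    def test_fit_predict_and_in_sample_coverage(self, sim_ensemble_matrix):
        est = TemporalUncertaintyEstimator(
            intervals_hours=[48.0, 168.0, 720.0], step_hours=3.0
        ).fit(sim_ensemble_matrix)
        assert est.uv_values_.shape == (3,)
        assert (est.uv_values_ >= 0).all()
        # in-sample exceedance of the 95th-percentile value is at most 5%
        for t in est.intervals_:
            d = est.pool_.pools[float(t)]
            uv = estimate_uv(est.pool_, float(t))
            assert np.mean(d > uv) <= 0.05
        # predict interpolates between fitted knots
        uv_pred = est.predict([48.0, 100.0, 720.0, 2000.0])
        assert uv_pred[0] == pytest.approx(est.uv_values_[0])
        assert uv_pred[3] == pytest.approx(est.uv_values_[2])
        assert est.uv_values_[1] <= uv_pred[1] <= est.uv_values_[0]

    def test_wrapper_matches_estimator(self, sim_ensemble_matrix):
        rooms = [
            RadonSeries(values=row, step_hours=3.0) for row in sim_ensemble_matrix
        ]
        curve = estimate_uv_curve(rooms, [48.0, 168.0])
        est = TemporalUncertaintyEstimator(
            intervals_hours=[48.0, 168.0], step_hours=3.0
        ).fit(sim_ensemble_matrix)
        assert curve.to_rows() == est.curve_.to_rows()

    def test_uv_decreases_with_duration(self, sim_ensemble_matrix):
        est = TemporalUncertaintyEstimator(
            intervals_hours=[6.0, 24.0, 48.0, 168.0, 336.0, 720.0],
            step_hours=3.0,
        ).fit(sim_ensemble_matrix)
        diffs = np.diff(est.uv_values_)
        assert (diffs <= 1e-9).all()
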