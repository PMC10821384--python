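"""Instrumental uncertainty: counting and track-etch devices."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radonmetry import (
    DeviceCountData,
    TrackExposureData,
    calibrate_sensitivity,
    concentration_from_counts,
    expanded_uncertainty_counting,
    expanded_uncertainty_track,
    measure_counting,
    measure_track,
    rate_uncertainty,
    track_concentration,
)
from radonmetry.errors import NoSignalError
from radonmetry.instrument import (
    counting_uncertainty_components,
    track_uncertainty_components,
)


def gum_oracle_u_c(d):
    """Independent route: propagate u(r_g), u(r_0), u_rel(eps) through
    C = (r_g - r_0)/eps by the standard quadrature rule, in absolute units."""
    u_rg = math.sqrt(d.n_g) / d.t
    u_r0 = math.sqrt(d.n_0) / d.t_0
    c = (d.r_g - d.r_0) / d.epsilon
    return math.sqrt(
        (u_rg**2 + u_r0**2) / d.epsilon**2
        + d.u_rel_epsilon**2 * c**2
    )


class TestConcentration:
    def test_worked_example(self, example_device):
        # (0.1 - 0.01) / 9e-4 = 100 Bq/m3
        assert concentration_from_counts(example_device) == pytest.approx(100.0)

    def test_zero_net_rate(self):
        d = DeviceCountData(n_g=100, t=1e3, n_0=100, t_0=1e3, epsilon=1e-3)
        assert concentration_from_counts(d) == 0.0

    def test_below_background_clips_and_flags(self):
        d = DeviceCountData(n_g=50, t=1e3, n_0=100, t_0=1e3, epsilon=1e-3)
        m = measure_counting(d)
        assert m.C == 0.0 and m.below_background and m.undefined_uncertainty

    def test_linearity_in_inverse_sensitivity(self, example_device):
        from dataclasses import replace

        doubled = replace(example_device, epsilon=2 * example_device.epsilon)
        assert concentration_from_counts(doubled) == pytest.approx(
            concentration_from_counts(example_device) / 2
        )


class TestCalibration:
    def test_inverts_worked_example(self):
        assert calibrate_sensitivity(0.1, 0.01, 100.0) == pytest.approx(9e-4)

    def test_round_trip(self):
        eps = calibrate_sensitivity(0.25, 0.02, 460.0)
        d = DeviceCountData(n_g=0.25 * 1e4, t=1e4, n_0=0.02 * 1e4, t_0=1e4,
                            epsilon=eps)
        assert concentration_from_counts(d) == pytest.approx(460.0)

    def test_no_net_signal_rejected(self):
        with pytest.raises(NoSignalError):
            calibrate_sensitivity(0.01, 0.01, 100.0)


class TestRateUncertainty:
    def test_zero_counts(self):
        assert rate_uncertainty(0, 100.0) == 0.0

    def test_sqrt_n_over_t(self):
        assert rate_uncertainty(100, 100.0) == pytest.approx(0.1)

    @given(n=st.integers(min_value=0, max_value=10**8),
           t=st.floats(min_value=1.0, max_value=1e7))
    @settings(max_examples=50, deadline=None)
    def test_algebraic_identity(self, n, t):
        assert rate_uncertainty(n, t) * t == pytest.approx(math.sqrt(n))


class TestExpandedUncertaintyCounting:
    def test_worked_example(self, example_device):
        u_d, u_c = expanded_uncertainty_counting(example_device)
        assert u_d == pytest.approx(0.1242, abs=5e-4)
        assert u_c == pytest.approx(u_d * 100.0 / 2.0)

    def test_random_term_vanishes_at_large_counts(self):
        d = DeviceCountData(n_g=1e12, t=1e10, n_0=0, t_0=1e10, epsilon=1.0,
                            u_rel_epsilon=0.0)
        u_d, _ = expanded_uncertainty_counting(d)
        assert u_d < 1e-4

    def test_long_duration_limit_is_background_plus_systematic(self):
        # as t grows with t_0 fixed, only the background and calibration
        # terms survive
        eps, r_g, r_0, t_0, u_eps = 1e-3, 0.1, 0.01, 1e4, 0.05
        big_t = 1e12
        d = DeviceCountData(n_g=r_g * big_t, t=big_t, n_0=r_0 * t_0, t_0=t_0,
                            epsilon=eps, u_rel_epsilon=u_eps)
        u_d, _ = expanded_uncertainty_counting(d)
        limit = 2 * math.sqrt((r_0 / t_0) / (r_g - r_0) ** 2 + u_eps**2)
        assert u_d == pytest.approx(limit, rel=1e-3)

    def test_undefined_below_background(self):
        d = DeviceCountData(n_g=50, t=1e3, n_0=100, t_0=1e3, epsilon=1e-3)
        u_d, u_c = expanded_uncertainty_counting(d)
        assert math.isinf(u_d) and math.isinf(u_c)

    @given(
        n_g=st.integers(min_value=1, max_value=10**6),
        n_0=st.integers(min_value=0, max_value=10**5),
        t=st.floats(min_value=10.0, max_value=1e6),
        t_0=st.floats(min_value=10.0, max_value=1e6),
        eps=st.floats(min_value=1e-5, max_value=1.0),
        u_eps=st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_consistent_with_gum_propagation_oracle(
        self, n_g, n_0, t, t_0, eps, u_eps
    ):
        d = DeviceCountData(n_g=n_g, t=t, n_0=n_0, t_0=t_0, epsilon=eps,
                            u_rel_epsilon=u_eps)
        if d.r_g <= d.r_0:
            return
        u_d, u_c = expanded_uncertainty_counting(d)
        c = concentration_from_counts(d)
        oracle = gum_oracle_u_c(d)
        assert u_c == pytest.approx(oracle, rel=1e-9)
        assert u_d == pytest.approx(d.k * oracle / c, rel=1e-9)

    def test_rate_based_record_uses_explicit_uncertainties(self):
        d = DeviceCountData.from_rates(
            r_g=0.1, r_0=0.01, epsilon=9e-4, u_r_g=1e-3, u_r_0=1e-4,
            u_rel_epsilon=0.0,
        )
        rand, _ = counting_uncertainty_components(d)
        expected = math.sqrt(1e-6 + 1e-8) / 0.09
        assert rand == pytest.approx(expected)

    def test_component_split_recombines(self, example_device):
        rand, syst = counting_uncertainty_components(example_device)
        u_d, _ = expanded_uncertainty_counting(example_device)
        assert u_d == pytest.approx(2 * math.hypot(rand, syst))


class TestTrackDevices:
    def test_concentration_worked_example(self):
        d = TrackExposureData(n_g=1100, n_0=100, epsilon=2e-6, t=5e5)
        assert track_concentration(d) == pytest.approx(1000.0)

    def test_zero_net_tracks(self):
        d = TrackExposureData(n_g=100, n_0=100, epsilon=2e-6, t=5e5)
        assert track_concentration(d) == 0.0

    def test_linear_in_net_tracks(self):
        base = TrackExposureData(n_g=1100, n_0=100, epsilon=2e-6, t=5e5)
        double = TrackExposureData(n_g=2100, n_0=100, epsilon=2e-6, t=5e5)
        assert track_concentration(double) == pytest.approx(
            2 * track_concentration(base)
        )

    def test_expanded_uncertainty_worked_example(self):
        d = TrackExposureData(n_g=1100, n_0=100, epsilon=2e-6, t=5e5,
                              u_rel_epsilon=0.1, u_rel_t=0.02)
        # 2 * sqrt(1200/1e6 + 0.01 + 4e-4)
        assert expanded_uncertainty_track(d) == pytest.approx(0.2154, abs=5e-4)

    def test_zero_duration_uncertainty_reduces_to_ssntd(self):
        kw = dict(n_g=1100, n_0=100, epsilon=2e-6, t=5e5, u_rel_epsilon=0.1)
        with_t = TrackExposureData(u_rel_t=0.02, **kw)
        without = TrackExposureData(u_rel_t=0.0, **kw)
        assert expanded_uncertainty_track(without) < expanded_uncertainty_track(
            with_t
        )
        assert expanded_uncertainty_track(without) == pytest.approx(
            2 * math.sqrt(1200 / 1e6 + 0.01)
        )

    def test_poisson_term_shrinks_with_net_tracks(self):
        uds = [
            expanded_uncertainty_track(
                TrackExposureData(n_g=n, n_0=100, epsilon=2e-6, t=5e5,
                                  u_rel_epsilon=0.1)
            )
            for n in (300, 1100, 11000)
        ]
        assert uds == sorted(uds, reverse=True)

    def test_below_background_flagged(self):
        d = TrackExposureData(n_g=50, n_0=100, epsilon=2e-6, t=5e5)
        m = measure_track(d)
        assert m.C == 0.0 and m.below_background and m.undefined_uncertainty
        rand, _ = track_uncertainty_components(d)
        assert math.isinf(rand)
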