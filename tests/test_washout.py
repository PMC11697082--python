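"""The sinc^2 washout relation, its multi-branch inverse and pulse detection."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hrtoct as h
from hrtoct.stack import SubareaSeries


def series_from_drops(drops, dt_ms=49.0):
    drops = np.asarray(drops, dtype=float)
    t = np.arange(drops.size) * dt_ms
    return SubareaSeries(
        timestamps_ms=t,
        mean_intensity=drops * 0.02,
        snr=drops * 100.0,
        reference_snr=100.0,
        snr_drop=drops,
    )


class TestForward:
    def test_zero_velocity_has_no_washout(self, washout_params):
        assert h.forward_washout(0.0, washout_params) == 1.0

    def test_first_null_at_half_wavelength_displacement(self, washout_params):
        v = np.pi / washout_params.scale  # dz = lambda / 2
        assert h.forward_washout(v, washout_params) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_wavelength_value(self, washout_params):
        v = (np.pi / 2) / washout_params.scale
        assert h.forward_washout(v, washout_params) == pytest.approx((2 / np.pi) ** 2, rel=1e-12)

    def test_negative_velocity_rejected(self, washout_params):
        with pytest.raises(h.InvalidInputError):
            h.forward_washout(-1e-6, washout_params)


class TestInvert:
    def test_no_drop_means_zero_velocity(self, washout_params):
        assert h.invert_washout(1.0, washout_params) == [(0, 0.0)]

    def test_quarter_wavelength_closed_form(self, washout_params):
        # drop = (2/pi)^2 <=> dz = lambda/4, i.e. v = lambda / (4 n t).
        sols = h.invert_washout((2 / np.pi) ** 2, washout_params)
        expected = 880e-9 / (4 * 1.36 * 44.8e-6)
        assert sols[0][1] == pytest.approx(expected, rel=1e-9)
        assert sols[0][1] * 1000.0 == pytest.approx(3.611, abs=2e-3)  # mm/s

    def test_half_drop_against_grid_scan_oracle(self, washout_params):
        # Brute-force scan of sinc^2 at 1e-6 resolution in x.
        x = np.arange(0.0, np.pi, 1e-6)
        f = np.sinc(x / np.pi) ** 2
        x_oracle = x[np.argmin(np.abs(f - 0.5))]
        sols = h.invert_washout(0.5, washout_params)
        x_found = sols[0][1] * washout_params.scale
        assert x_found == pytest.approx(1.39156, abs=1e-5)
        assert x_found == pytest.approx(x_oracle, abs=2e-6)

    @pytest.mark.parametrize("t_int", [44.8e-6, 11.2e-6])
    def test_round_trip_identity_over_drop_range(self, t_int):
        wp = h.WashoutParams.from_scan(h.ScanParams(integration_time_s=t_int))
        for drop in np.linspace(0.01, 1.0, 223):
            for nsi, v in h.invert_washout(float(drop), wp):
                assert h.forward_washout(v, wp) == pytest.approx(float(drop), abs=1e-9)

    @given(st.floats(1e-4, 1.0))
    def test_branch_zero_round_trip(self, drop):
        wp = h.WashoutParams.from_scan(h.ScanParams())
        v0 = h.invert_washout(drop, wp)[0][1]
        assert h.forward_washout(v0, wp) == pytest.approx(drop, abs=1e-9)

    def test_velocity_increases_with_branch_index(self, washout_params):
        sols = h.invert_washout(0.01, washout_params)
        assert len(sols) >= 3
        vs = [v for _, v in sols]
        assert all(b > a for a, b in zip(vs, vs[1:]))
        assert [nsi for nsi, _ in sols] == list(range(len(sols)))

    def test_branch_count_non_increasing_in_drop(self, washout_params):
        counts = [len(h.invert_washout(d, washout_params)) for d in np.linspace(0.005, 1.0, 120)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_velocity_scaling_law_with_integration_time(self):
        # Halving t doubles every branch velocity; the 44.8 -> 11.2 us step
        # quadruples them (the 20 kHz vs 85 kHz regimes).
        wp_slow = h.WashoutParams.from_scan(h.ScanParams(integration_time_s=44.8e-6))
        wp_fast = h.WashoutParams.from_scan(h.ScanParams(integration_time_s=11.2e-6))
        for drop in (0.02, 0.3, 0.8):
            slow = h.invert_washout(drop, wp_slow)
            fast = h.invert_washout(drop, wp_fast)
            assert len(slow) == len(fast)
            for (_, vs), (_, vf) in zip(slow, fast):
                assert vf == pytest.approx(4.0 * vs, rel=1e-9)

    def test_out_of_range_drop_rejected(self, washout_params):
        for bad in (0.0, -0.1, 1.0001):
            with pytest.raises(h.InvalidInputError):
                h.invert_washout(bad, washout_params)


class TestFlowProfile:
    def test_constant_drop_gives_flat_profile(self, washout_params):
        _, prof = h.build_flow_profile(series_from_drops([0.6] * 8), washout_params)
        assert np.allclose(prof.envelope_v, prof.envelope_v[0])
        assert np.allclose(prof.gradient, 0.0)

    def test_round_trip_of_smooth_waveform(self, washout_params):
        # Velocities inside the principal lobe invert uniquely to 1e-9.
        t = np.linspace(0, 2000, 40)
        v_true = (1.2e-3 + 0.8e-3 * np.sin(2 * np.pi * t / 900.0)) * 1.0
        drops = h.forward_washout(v_true, washout_params)
        sols, prof = h.build_flow_profile(series_from_drops(drops), washout_params)
        v0 = np.array([frame[0][1] for frame in sols.solutions])
        assert np.allclose(v0, v_true, rtol=1e-9)

    def test_linear_envelope_has_constant_gradient(self, washout_params):
        v = np.linspace(1e-3, 2e-3, 12)
        drops = h.forward_washout(v, washout_params)
        _, prof = h.build_flow_profile(series_from_drops(drops, dt_ms=50.0), washout_params)
        slope = (v[-1] - v[0]) / (50.0 * 11)
        assert np.allclose(prof.gradient, slope, rtol=1e-6)

    def test_invalid_drop_rejected(self, washout_params):
        with pytest.raises(h.InvalidInputError):
            h.build_flow_profile(series_from_drops([0.5, 0.0, 0.7]), washout_params)


class TestDetectPulseArrivals:
    def make_profile(self, t, env):
        t = np.asarray(t, dtype=float)
        env = np.asarray(env, dtype=float)
        grad = np.empty_like(env)
        grad[0] = (env[1] - env[0]) / (t[1] - t[0])
        grad[-1] = (env[-1] - env[-2]) / (t[-1] - t[-2])
        grad[1:-1] = (env[2:] - env[:-2]) / (t[2:] - t[:-2])
        return h.FlowProfile(t, env, grad)

    def test_sawtooth_rises_located_within_one_frame(self):
        from scipy.special import expit

        dt, period = 13.4, 850.0
        t = np.arange(0, 7 * period, dt)  # exactly seven heart-rate bins
        rises = 200.0 + period * np.arange(7)
        env = np.zeros_like(t)
        for r in rises:
            u = t - r
            env += np.where(u >= 0, np.exp(-u / 250.0), 0.0) * expit(u / 2.0)
        prof = self.make_profile(t, env)
        events = h.detect_pulse_arrivals(prof, period)
        assert len(events) == len(rises)
        err = np.abs(events.times_ms[:, None] - rises[None, :]).min(axis=1)
        assert err.max() <= dt + 1e-9

    def test_single_bin_monotone_profile_tie_breaks_earlier(self):
        t = np.arange(0, 500, 50.0)
        prof = self.make_profile(t, t.copy())  # exactly constant gradient
        events = h.detect_pulse_arrivals(prof, 1000.0)
        assert len(events) == 1
        assert events.times_ms[0] == t[0]

    def test_short_profile_emits_single_event(self):
        t = np.array([0.0, 50.0, 100.0, 150.0])
        prof = self.make_profile(t, np.array([0.0, 0.1, 0.5, 0.6]))
        events = h.detect_pulse_arrivals(prof, 10_000.0)
        assert len(events) == 1

    def test_sparse_bins_emit_nothing(self):
        t = np.array([0.0, 60.0])
        prof = h.FlowProfile(t, np.array([0.0, 1.0]), np.array([0.01, 0.01]))
        events = h.detect_pulse_arrivals(prof, 100.0)
        assert len(events) == 0

    def test_at_most_one_event_per_bin_and_increasing(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 7000, 49.0)
        env = rng.uniform(0, 1, t.size)
        prof = self.make_profile(t, env)
        events = h.detect_pulse_arrivals(prof, 857.0)
        assert len(events) <= int(np.ceil(7000 / 857.0))
        assert np.all(np.diff(events.times_ms) > 0)
        bins = np.floor((events.times_ms - t[0]) / 857.0).astype(int)
        assert np.unique(bins).size == bins.size
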