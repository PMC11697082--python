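"""Cross-correlation lag analysis, the one-cycle rule and CoV statistics."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hrtoct as h


def periodic_train(start_ms, n, rr_ms=857.0, jitter_seed=None, jitter_frac=0.03, kind="r_peak"):
    if jitter_seed is None:
        times = start_ms + np.arange(n) * rr_ms
    else:
        rng = np.random.default_rng(jitter_seed)
        steps = rr_ms * (1 + rng.uniform(-jitter_frac, jitter_frac, n - 1))
        times = start_ms + np.concatenate([[0.0], np.cumsum(steps)])
    return h.PeakTrain(times, kind)


class TestCrossCorrelate:
    def test_identical_trains_autocorrelate_to_one(self):
        train = periodic_train(0.0, 6)
        enc = h.encode_train(train, 0.0, 125.0, 600)
        lags, cc = h.cross_correlate_trains(enc, enc)
        assert cc.size == 1
        assert lags[0] == 0.0
        assert cc[0] == pytest.approx(1.0)

    def test_earlier_ecg_produces_negative_lag(self):
        # ECG pattern leading by D samples puts the argmax at -D * dt.
        delta = 17  # grid samples
        oct_train = periodic_train(2000.0, 5, kind="pulse_arrival")
        ecg_train = h.PeakTrain(oct_train.times_ms - delta * 8.0, "r_peak")
        oct_enc = h.encode_train(oct_train, 2000.0, 125.0, 500)
        ecg_enc = h.encode_train(ecg_train, 2000.0 - 2000.0, 125.0, 900)
        lags, cc = h.cross_correlate_trains(oct_enc, ecg_enc)
        assert lags[np.argmax(cc)] == pytest.approx(-delta * 8.0)

    def test_interleaved_trains_correlate_weakly(self):
        a = h.PeakTrain(np.arange(0.0, 4000.0, 400.0), "pulse_arrival")
        b = h.PeakTrain(np.arange(200.0, 4200.0, 400.0), "r_peak")
        ea = h.encode_train(a, 0.0, 125.0, 525, sigma_samples=0.6)
        eb = h.encode_train(b, 0.0, 125.0, 525, sigma_samples=0.6)
        _, cc = h.cross_correlate_trains(
            ea, h.encode_train(b, -800.0, 125.0, 725, sigma_samples=0.6)
        )
        # At zero lag the bumps interleave; compare the zero-lag value only.
        lags, cc = h.cross_correlate_trains(ea, h.encode_train(b, -800.0, 125.0, 725, 0.6))
        assert cc[np.argmin(np.abs(lags))] < 0.5

    def test_scaling_invariance_of_normalisation(self):
        train = periodic_train(0.0, 5)
        enc_o = h.encode_train(train, 0.0, 125.0, 500)
        enc_e = h.encode_train(train, -800.0, 125.0, 700)
        _, cc1 = h.cross_correlate_trains(enc_o, enc_e)
        scaled = h.EncodedTrain(
            h.UniformSignal(enc_e.signal.t0_ms, 125.0, enc_e.signal.values),
            enc_e.sigma_samples,
            enc_e.source,
        )
        o2 = h.UniformSignal(0.0, 125.0, enc_o.signal.values * 1.0)
        # normalisation divides the product scale out; identical values here
        _, cc2 = h.cross_correlate_trains(enc_o, scaled)
        assert np.allclose(cc1, cc2)

    def test_mismatched_rates_rejected(self):
        t = periodic_train(0.0, 3)
        a = h.encode_train(t, 0.0, 125.0, 400)
        b = h.encode_train(t, 0.0, 250.0, 800)
        with pytest.raises(h.InvalidInputError):
            h.cross_correlate_trains(a, b)

    def test_zero_train_rejected(self):
        a = h.encode_train(periodic_train(0.0, 3), 0.0, 125.0, 400)
        z = h.encode_train(h.PeakTrain(np.empty(0)), 0.0, 125.0, 400)
        with pytest.raises(h.DegenerateSignalError):
            h.cross_correlate_trains(a, z)


class TestEstimateHRT:
    def test_zero_delay(self):
        r = periodic_train(11_000.0, 8, jitter_seed=1)
        arr = h.PeakTrain(r.times_ms.copy(), "pulse_arrival")
        est = h.estimate_hrt(arr, r)
        assert est.hrt_ms == 0.0
        assert not est.is_outlier

    def test_sign_convention_negative_offset_positive_hrt(self):
        r = periodic_train(11_000.0, 12, jitter_seed=2)
        arr = h.PeakTrain(r.times_ms[:8] + 136.0, "pulse_arrival")
        est = h.estimate_hrt(arr, r)
        assert est.offset_ms == pytest.approx(-136.0, abs=8.0)
        assert est.hrt_ms == -est.offset_ms
        assert not est.is_outlier

    def test_shift_equivariance(self):
        r = periodic_train(11_000.0, 12, jitter_seed=3)
        base = h.PeakTrain(r.times_ms[:8] + 100.0, "pulse_arrival")
        est0 = h.estimate_hrt(base, r)
        delta = 48.0  # multiple of the 8 ms grid, well inside one cycle
        est1 = h.estimate_hrt(base.shifted(delta), r)
        assert est1.hrt_ms == pytest.approx(est0.hrt_ms + delta, abs=1e-9)

    def test_delay_beyond_one_cycle_is_outlier(self):
        r = periodic_train(11_000.0, 16, jitter_seed=4)
        arr = h.PeakTrain(r.times_ms[:8] + 1.5 * 857.0, "pulse_arrival")
        est = h.estimate_hrt(arr, r)
        assert est.is_outlier
        assert est.argmax_offset_ms < -857.0
        # the reported offset is still folded into [-RR, 0]
        assert -est.rr_mean_ms <= est.offset_ms <= 0.0

    def test_sub_cycle_delay_not_outlier(self):
        r = periodic_train(11_000.0, 16, jitter_seed=5)
        arr = h.PeakTrain(r.times_ms[:8] + 0.6 * 857.0, "pulse_arrival")
        est = h.estimate_hrt(arr, r)
        assert not est.is_outlier
        assert est.hrt_ms == pytest.approx(0.6 * 857.0, abs=10.0)

    def test_too_few_events_rejected(self):
        r = periodic_train(0.0, 5)
        with pytest.raises(h.InvalidInputError):
            h.estimate_hrt(h.PeakTrain(np.array([100.0]), "pulse_arrival"), r)

    def test_non_overlapping_windows_rejected(self):
        r = periodic_train(0.0, 3)
        arr = h.PeakTrain(np.array([100_000.0, 101_000.0]), "pulse_arrival")
        with pytest.raises(h.InvalidInputError):
            h.estimate_hrt(arr, r)


class TestCov:
    @pytest.mark.parametrize(
        "values, expected",
        [([5.0, 5.0, 5.0], 0.0), ([1.0, 2.0, 3.0], 0.5), ([100.0, 100.0, 120.0], 0.1083)],
    )
    def test_known_values(self, values, expected):
        assert h.cov(values) == pytest.approx(expected, abs=1e-4)

    @given(st.floats(0.1, 50.0))
    def test_scale_invariance(self, c):
        x = np.array([3.0, 4.5, 5.25, 2.75])
        assert h.cov(c * x) == pytest.approx(h.cov(x), rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(h.InvalidInputError):
            h.cov([1.0])
        with pytest.raises(h.InvalidInputError):
            h.cov([-1.0, 1.0])


class TestCovReport:
    @staticmethod
    def record(s, e, v, hrt):
        return h.CohortRecord(s, e, v, hrt)

    def test_identical_records_have_zero_cov(self):
        recs = [
            self.record(f"S{s}", f"E{e}", "A1", 150.0)
            for s in range(2)
            for e in range(3)
        ]
        rep = h.cov_report(recs)
        assert rep.inter_subject_cov == 0.0
        assert rep.intra_subject_cov_mean == 0.0
        assert rep.overall_sd_ms == 0.0

    def test_two_subject_inter_cov(self):
        recs = [self.record("S1", "E1", "A1", 100.0), self.record("S2", "E1", "A1", 120.0)]
        rep = h.cov_report(recs)
        assert rep.inter_subject_cov == pytest.approx(0.1286, abs=1e-4)

    def test_group_size_rules(self):
        recs = [self.record("S1", "E1", "A1", 150.0), self.record("S1", "E2", "A1", 160.0)]
        rep = h.cov_report(recs)
        assert rep.inter_subject_cov is None  # single subject
        assert rep.intra_subject_cov_mean is not None
        assert rep.intra_subject_cov_sd is None  # single qualifying group
        assert rep.intra_exam_cov_mean is None  # one vessel per exam
        assert rep.intra_vessel_cov_mean is not None  # same vessel, two exams

    def test_cohort_parameter_recovery_on_drawn_hrts(self):
        # CoV levels recovered from Gaussian draws with designed dispersion.
        rng = np.random.default_rng(7)
        base, between, within = 150.0, 0.09, 0.11
        inter, intra = [], []
        for _ in range(20):
            recs = []
            for s in range(5):
                mu = rng.normal(base, between * base)
                for e in range(4):
                    recs.append(
                        self.record(f"S{s}", f"E{e}", "A1", rng.normal(mu, within * base))
                    )
            rep = h.cov_report(recs)
            inter.append(rep.inter_subject_cov)
            intra.append(rep.intra_subject_cov_mean)
        assert abs(np.mean(inter) - between) <= 0.03 + within / 2  # inflated by within-spread
        assert abs(np.mean(intra) - within) <= 0.03

    def test_empty_rejected(self):
        with pytest.raises(h.InvalidInputError):
            h.cov_report([])
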