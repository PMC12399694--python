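import numpy as np
import pytest
from hypothesis import given, strategies as st

import fwave as fw
from fwave.metrics import (
    EnvelopePair,
    FwaMeasurement,
    PatientEpochPair,
    compute_fwa,
    detect_extrema,
    estimate_envelopes,
    mean_fwa,
    measure_fwa,
    relative_change,
)

FS = 2000.0


def sine(freq, amp, duration, fs=FS):
    t = np.arange(round(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestDetectExtrema:
    def test_sinusoid_crest_values(self):
        x = sine(6.0, 0.04, 5.0)
        ext = detect_extrema(x, FS, window_ms=100)
        # one crest per cycle: ~30 of each kind over 5 s at 6 Hz
        assert 28 <= len(ext.max_idx) <= 31
        np.testing.assert_allclose(ext.max_val, 0.04, rtol=0.01)
        np.testing.assert_allclose(ext.min_val, -0.04, rtol=0.01)

    def test_crest_per_window_when_period_matches(self):
        # at 10 Hz every 100-ms window holds exactly one crest
        x = sine(10.0, 1.0, 60.0)
        ext = detect_extrema(x, FS, window_ms=100)
        assert ext.n_windows == 600
        assert len(ext.max_idx) == 600

    def test_constant_signal_extrema_equal_constant(self):
        x = np.full(round(60 * FS), 0.7)
        ext = detect_extrema(x, FS, window_ms=100)
        assert ext.n_windows == 600
        np.testing.assert_array_equal(ext.max_val, 0.7)
        np.testing.assert_array_equal(ext.min_val, 0.7)

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(fw.ValidationError, match="window"):
            detect_extrema(np.zeros(100), FS, window_ms=100)


class TestEnvelopes:
    def test_sinusoid_envelopes_flat_at_amplitude(self):
        x = sine(6.0, 0.03, 10.0)
        ext = detect_extrema(x, FS)
        env = estimate_envelopes(ext, len(x), FS)
        n = len(x)
        sl = slice(n // 10, -n // 10)
        np.testing.assert_allclose(env.upper[sl], 0.03, rtol=0.05)
        np.testing.assert_allclose(env.lower[sl], -0.03, rtol=0.05)

    def test_constant_signal_envelopes_equal_constant(self):
        x = np.full(round(10 * FS), 0.5)
        ext = detect_extrema(x, FS)
        env = estimate_envelopes(ext, len(x), FS)
        np.testing.assert_allclose(env.upper, 0.5, rtol=1e-9)
        np.testing.assert_allclose(env.lower, 0.5, rtol=1e-9)

    def test_slow_am_tracked_centrally(self):
        t = np.arange(round(20 * FS)) / FS
        a_t = 0.05 * (1 + 0.5 * np.sin(2 * np.pi * 0.2 * t))
        x = a_t * np.sin(2 * np.pi * 6.0 * t)
        ext = detect_extrema(x, FS)
        env = estimate_envelopes(ext, len(x), FS)
        n = len(x)
        sl = slice(n // 10, -n // 10)
        np.testing.assert_allclose(env.upper[sl], a_t[sl], rtol=0.10)

    def test_too_few_extrema_rejected(self):
        x = sine(6.0, 1.0, 0.3)
        ext = detect_extrema(x, FS)
        with pytest.raises(fw.ValidationError, match="maxima"):
            estimate_envelopes(ext, len(x), FS)


class TestComputeFwa:
    def test_constant_envelopes(self):
        env = EnvelopePair(np.full(100, 0.02), np.full(100, -0.02))
        assert compute_fwa(env) == pytest.approx(0.04)

    def test_equal_envelopes_give_zero(self):
        env = EnvelopePair(np.full(100, 0.3), np.full(100, 0.3))
        assert compute_fwa(env) == 0.0

    def test_full_chain_on_sinusoid_recovers_twice_amplitude(self):
        x = sine(6.0, 0.025, 60.0)
        ext = detect_extrema(x, FS)
        env = estimate_envelopes(ext, len(x), FS)
        assert compute_fwa(env, central_frac=0.8) == pytest.approx(0.050, abs=0.003)

    def test_negative_difference_floored_at_zero(self):
        env = EnvelopePair(np.full(10, -0.1), np.full(10, 0.1))
        assert compute_fwa(env) == 0.0


class TestAggregation:
    def test_mean_fwa_trivial_cases(self):
        m = FwaMeasurement({"I": 0.04, "II": 0.04}, 0.04)
        assert mean_fwa(m) == pytest.approx(0.04)
        m2 = FwaMeasurement({"I": 0.02, "II": 0.06}, 0.04)
        assert mean_fwa(m2) == pytest.approx(0.04)

    def test_mean_fwa_matches_summation_oracle(self, rng):
        vals = rng.uniform(0.01, 0.08, 12)
        leads = tuple(fw.STANDARD_LEADS)
        m = FwaMeasurement(dict(zip(leads, vals)), float(np.mean(vals)))
        oracle = sum(vals) / len(vals)  # independent brute-force mean
        assert mean_fwa(m) == pytest.approx(oracle, rel=1e-12)

    def test_missing_lead_named_in_error(self):
        m = FwaMeasurement({"I": 0.04}, 0.04)
        with pytest.raises(fw.ValidationError, match="'V1'"):
            mean_fwa(m, leads=("I", "V1"))

    def test_measure_fwa_subset_and_meanfwa_consistency(self, clean_record):
        rec, _ = clean_record
        m = measure_fwa(rec, central_frac=0.8)
        assert m.meanfwa == pytest.approx(np.mean(list(m.per_lead_fwa.values())))
        sub = measure_fwa(rec, leads=("II", "V1"), central_frac=0.8)
        assert set(sub.per_lead_fwa) == {"II", "V1"}


class TestRelativeChange:
    def _pair(self, base, end):
        return PatientEpochPair(
            "p",
            FwaMeasurement({"II": base}, base, "baseline"),
            FwaMeasurement({"II": end}, end, "endWPVI"),
        )

    @pytest.mark.parametrize(
        "base, end, delta",
        [(0.040, 0.036, -10.0), (0.040, 0.040, 0.0), (0.044, 0.0506, 15.0)],
    )
    def test_delta_arithmetic(self, base, end, delta):
        change = relative_change(self._pair(base, end))
        assert change.meanfwa_delta_pct == pytest.approx(delta, abs=1e-9)
        assert change.decrease_pct == pytest.approx(-delta, abs=1e-9)

    def test_zero_baseline_rejected(self):
        with pytest.raises(fw.ValidationError):
            relative_change(self._pair(0.0, 0.04))


class TestMetricProperties:
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, k):
        x = sine(6.0, 0.02, 8.0) + 0.3 * sine(11.0, 0.01, 8.0)
        ext1 = detect_extrema(x, FS)
        ext2 = detect_extrema(k * x, FS)
        f1 = compute_fwa(estimate_envelopes(ext1, len(x), FS))
        f2 = compute_fwa(estimate_envelopes(ext2, len(x), FS))
        assert f2 == pytest.approx(k * f1, rel=1e-9)

    def test_fwa_monotone_in_generator_amplitude(self):
        amplitudes = [0.01, 0.03, 0.05, 0.08, 0.10]
        means = []
        for a in amplitudes:
            vals = []
            for seed in range(10):
                params = fw.preset_params(
                    "clean", seed=seed, duration_s=10.0,
                    f_wave_amplitude_per_lead=a,
                )
                rec, _ = fw.simulate_af_ecg(params)
                vals.append(
                    measure_fwa(rec, leads=("II",), central_frac=0.8).meanfwa
                )
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)
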