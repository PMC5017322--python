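"""Gait-parameter computations: spatiotemporal quotients, RMS/RMSR,
unbiased autocorrelation, regularity, symmetry, and the full pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaittool import (
    AccelerationTrace,
    DomainError,
    GateEvents,
    StepCountResult,
    WalkSession,
    WindowError,
)
from gaittool.config import AnalysisConfig
from gaittool.metrics import (
    AXES,
    analyze_walk,
    axis_rms,
    regularity,
    rmsr,
    spatiotemporal,
    symmetry,
    unbiased_autocorrelation,
)
from gaittool.simulate import GaitSimParams, simulate_walk


def _steps(total):
    return StepCountResult(
        integer_step_count=int(total),
        initial_step_fraction=total - int(total),
        last_step_fraction=0.0,
        total_step_count=total,
        peak_times=[],
        mean_step_interval_s=0.43,
    )


def _sine_trace(amp=0.2, freq=2.0, fs=100.0, n=1000, axis="ap"):
    t = np.arange(n) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    channels = {a: np.zeros(n) for a in AXES}
    channels[axis] = x
    return AccelerationTrace(fs, t, channels["ap"], channels["ml"], channels["v"])


class TestSpatiotemporal:
    def test_paper_regime_quotients(self):
        v, c, sl = spatiotemporal(_steps(8.7), GateEvents(0.0, 3.731), 5.0)
        assert v == pytest.approx(5.0 / 3.731, abs=1e-9)
        assert v == pytest.approx(1.34, abs=1e-3)
        v, c, sl = spatiotemporal(_steps(8.7), GateEvents(0.0, 3.7), 5.0)
        assert c == pytest.approx(8.7 * 60 / 3.7, abs=1e-9)
        assert c == pytest.approx(141.08, abs=0.005)
        assert sl == pytest.approx(500 / 8.7, abs=1e-9)
        assert sl == pytest.approx(57.47, abs=0.005)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            spatiotemporal(_steps(8.7), GateEvents(0.0, 1.0), 0.0)
        with pytest.raises(DomainError):
            spatiotemporal(_steps(0.0), GateEvents(0.0, 1.0), 5.0)


class TestAxisRms:
    def test_pure_sine_rms_is_amplitude_over_sqrt2(self):
        trace = _sine_trace(amp=0.2, freq=2.0, n=1000)
        rms_ap, _, _ = axis_rms(trace, GateEvents(0.0, 9.99))
        assert rms_ap == pytest.approx(0.2 / math.sqrt(2), rel=0.005)

    def test_constant_signal_has_zero_rms_after_demeaning(self):
        n, fs = 500, 100.0
        t = np.arange(n) / fs
        trace = AccelerationTrace(fs, t, np.full(n, 0.7), np.zeros(n), np.zeros(n))
        rms_ap, _, _ = axis_rms(trace, GateEvents(0.5, 4.5))
        assert rms_ap == 0.0


class TestRmsr:
    def test_equal_axes_give_one_over_sqrt3(self):
        n, fs = 800, 100.0
        t = np.arange(n) / fs
        x = 0.1 * np.sin(2 * np.pi * 2.0 * t)
        trace = AccelerationTrace(fs, t, x, x.copy(), x.copy())
        gates = GateEvents(0.0, 7.99)
        for axis in AXES:
            assert rmsr(trace, gates, axis) == pytest.approx(1 / math.sqrt(3), abs=1e-9)

    def test_zero_ml_channel_gives_zero_ml_rmsr(self):
        trace = _sine_trace(axis="ap")
        assert rmsr(trace, GateEvents(0.0, 9.99), "ml") == 0.0

    def test_all_zero_window_is_domain_error(self):
        n, fs = 400, 100.0
        t = np.arange(n) / fs
        trace = AccelerationTrace(fs, t, np.zeros(n), np.zeros(n), np.zeros(n))
        with pytest.raises(DomainError):
            rmsr(trace, GateEvents(0.5, 3.5), "ml")

    @given(seed=st.integers(0, 10_000))
    def test_sum_of_squared_rmsr_is_one(self, seed):
        rng = np.random.default_rng(seed)
        n, fs = 400, 100.0
        t = np.arange(n) / fs
        trace = AccelerationTrace(
            fs, t, rng.normal(0, 0.2, n), rng.normal(0, 0.1, n), rng.normal(0, 0.3, n)
        )
        gates = GateEvents(0.2, 3.8)
        total = sum(rmsr(trace, gates, ax) ** 2 for ax in AXES)
        assert total == pytest.approx(1.0, abs=1e-6)


def _brute_force_autocorr(x, max_lag):
    """Quadratic-time reference for the unbiased normalized autocorrelation."""
    n = len(x)
    denom = sum(v * v for v in x) / n
    out = []
    for k in range(max_lag + 1):
        s = 0.0
        for i in range(n - k):
            s += x[i] * x[i + k]
        out.append((s / (n - k)) / denom)
    return np.array(out)


class TestUnbiasedAutocorrelation:
    def test_lag_zero_is_exactly_one(self, rng):
        ac = unbiased_autocorrelation(rng.normal(size=300), 1.0, 100.0)
        assert ac.coefficients[0] == 1.0

    def test_pure_sine_at_one_period(self):
        fs, freq = 100.0, 2.5
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * freq * t)
        ac = unbiased_autocorrelation(x, 0.5, fs)
        lag = int(round(fs / freq))
        assert ac.coefficients[lag] >= 0.99

    def test_white_noise_stays_small(self, rng):
        x = rng.normal(size=400)
        ac = unbiased_autocorrelation(x, 0.5, 100.0)
        assert np.all(np.abs(ac.coefficients[1:]) < 0.2)

    def test_matches_quadratic_time_oracle_on_50_random_series(self, rng):
        for _ in range(50):
            x = rng.normal(size=100)
            ac = unbiased_autocorrelation(x, 0.3, 100.0)
            ref = _brute_force_autocorr(x, 30)
            np.testing.assert_allclose(ac.coefficients, ref, atol=1e-10)

    def test_window_too_short_is_range_error(self, rng):
        with pytest.raises(WindowError):
            unbiased_autocorrelation(rng.normal(size=50), 0.5, 100.0)


class TestRegularity:
    def test_symmetric_noise_free_walk_is_near_perfect(self, clean_walk):
        params, session, _ = clean_walk
        for axis in AXES:
            step_reg, stride_reg, _ = regularity(
                session.trace, session.gates, axis, params.step_interval_s
            )
            assert step_reg >= 0.99, axis
            assert stride_reg >= 0.99, axis

    def test_amplitude_asymmetry_lowers_step_but_not_stride_regularity(self):
        params = GaitSimParams(noise_sd_g=0.0, asymmetry=0.3)
        session, _ = simulate_walk(params)
        step_reg, stride_reg, _ = regularity(
            session.trace, session.gates, "ap", params.step_interval_s
        )
        assert step_reg < stride_reg
        assert stride_reg >= 0.99

    def test_step_regularity_monotone_in_asymmetry(self):
        values = []
        for asym in (0.0, 0.1, 0.2, 0.3, 0.4):
            params = GaitSimParams(noise_sd_g=0.0, asymmetry=asym)
            session, _ = simulate_walk(params)
            step_reg, _, _ = regularity(
                session.trace, session.gates, "ap", params.step_interval_s
            )
            values.append(step_reg)
        assert all(b <= a + 1e-9 for a, b in zip(values, values[1:]))

    def test_white_noise_has_low_regularity(self, rng):
        n, fs = 600, 100.0
        t = np.arange(n) / fs
        trace = AccelerationTrace(
            fs, t, rng.normal(0, 0.2, n), rng.normal(0, 0.2, n), rng.normal(0, 0.2, n)
        )
        step_reg, stride_reg, _ = regularity(trace, GateEvents(0.2, 5.8), "ap", 0.43)
        assert (math.isnan(step_reg) or step_reg < 0.3)
        assert (math.isnan(stride_reg) or stride_reg < 0.3)

    def test_ml_step_extremum_is_negative_and_reported_as_magnitude(self, clean_walk):
        params, session, _ = clean_walk
        cfg_abs = AnalysisConfig()
        cfg_raw = AnalysisConfig(ml_abs=False)
        step_abs, _, _ = regularity(
            session.trace, session.gates, "ml", params.step_interval_s, cfg_abs
        )
        step_raw, _, _ = regularity(
            session.trace, session.gates, "ml", params.step_interval_s, cfg_raw
        )
        # trunk sway flips sign every step: raw step-lag autocorrelation is
        # negative; the reported magnitude is near 1
        assert step_abs >= 0.99
        assert math.isnan(step_raw) or step_raw < step_abs


class TestSymmetry:
    def test_ratio_arithmetic(self):
        assert symmetry(0.75, 0.6)[0] == pytest.approx(80.0, abs=1e-9)
        assert symmetry(0.6, 0.6)[0] == pytest.approx(100.0, abs=1e-9)

    def test_zero_step_regularity_is_domain_error(self):
        with pytest.raises(DomainError):
            symmetry(0.0, 0.5)

    def test_blowup_capped_with_warning(self):
        value, warnings = symmetry(1e-4, 0.9, cap_pct=999.0)
        assert value == 999.0
        assert warnings

    def test_nan_propagates_silently(self):
        value, warnings = symmetry(float("nan"), 0.5)
        assert math.isnan(value) and not warnings


class TestAnalyzeWalk:
    def test_profile_internal_consistency(self, noisy_walk):
        _, session, _ = noisy_walk
        p = analyze_walk(session)
        total = p.steps.total_step_count
        wt = p.walking_time_s
        assert p.velocity_mps == pytest.approx(session.distance_m / wt, abs=1e-9)
        assert p.cadence_spm == pytest.approx(60 * total / wt, abs=1e-9)
        assert p.step_length_cm == pytest.approx(100 * session.distance_m / total, abs=1e-9)
        assert p.is_complete

    def test_symmetric_walk_recovers_cadence_and_symmetry(self, clean_walk):
        params, session, truth = clean_walk
        p = analyze_walk(session)
        assert p.cadence_spm == pytest.approx(truth.true_cadence_spm, rel=0.02)
        assert p.cadence_spm == pytest.approx(140.87, rel=0.02)
        for axis in AXES:
            assert getattr(p, f"symmetry_{axis}_pct") == pytest.approx(100.0, abs=1.0)

    def test_mild_noise_recovers_cadence_and_step_length_within_2pct(self):
        params = GaitSimParams(noise_sd_g=0.02, seed=9)
        session, truth = simulate_walk(params)
        p = analyze_walk(session)
        assert p.cadence_spm == pytest.approx(truth.true_cadence_spm, rel=0.02)
        assert p.step_length_cm == pytest.approx(truth.true_step_length_cm, rel=0.02)

    def test_scale_invariance(self, noisy_walk):
        _, session, _ = noisy_walk
        p1 = analyze_walk(session)
        c = 2.7
        scaled = WalkSession(
            AccelerationTrace(
                session.trace.sample_rate, session.trace.time,
                c * session.trace.ap, c * session.trace.ml, c * session.trace.v,
            ),
            session.gates, session.distance_m,
        )
        p2 = analyze_walk(scaled)
        assert p2.rms_ap_g == pytest.approx(c * p1.rms_ap_g, rel=1e-9)
        assert p2.rmsr_ml == pytest.approx(p1.rmsr_ml, abs=1e-9)
        for axis in AXES:
            assert getattr(p2, f"step_regularity_{axis}") == pytest.approx(
                getattr(p1, f"step_regularity_{axis}"), abs=1e-9
            )
            assert getattr(p2, f"symmetry_{axis}_pct") == pytest.approx(
                getattr(p1, f"symmetry_{axis}_pct"), abs=1e-7
            )

    def test_time_shift_invariance(self, noisy_walk):
        _, session, _ = noisy_walk
        p1 = analyze_walk(session).as_dict()
        p2 = analyze_walk(session.shifted(31.4)).as_dict()
        for key, val in p1.items():
            assert p2[key] == pytest.approx(val, abs=1e-7), key

    def test_manual_gates_equal_ir_gates_with_same_timestamps(self, noisy_walk):
        _, session, _ = noisy_walk
        manual = WalkSession(
            session.trace,
            GateEvents(session.gates.t_start, session.gates.t_end, source="manual"),
            session.distance_m,
        )
        assert analyze_walk(manual).as_dict() == analyze_walk(session).as_dict()
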