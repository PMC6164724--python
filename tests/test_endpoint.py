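"""Baseline gate, smoothed derivative, clot-endpoint detection, rigidity."""

import dataclasses

import numpy as np
import pytest

from qcmcoag import (
    DissipationTrace,
    baseline_stable,
    detect_endpoint,
    rigidity_check,
    simulate_trace,
    smoothed_derivative,
)
from qcmcoag.errors import (
    InsufficientBaselineError,
    NoClotError,
    ParameterError,
)
from qcmcoag.simulate import TraceScenario, with_seed


def _trace(times, diss, events=(("starter", None),)):
    times = np.asarray(times, dtype=float)
    evs = [(label, times[-1] / 2 if t is None else t) for label, t in events]
    return DissipationTrace(times=times, dissipation=np.asarray(diss, float),
                            events=evs)


class TestBaselineStable:
    def test_constant_trace_passes_with_zero_drift(self):
        t = np.arange(0, 200, 2.0)
        trace = _trace(t, np.full(t.size, 5e-4), [("starter", 150.0)])
        report = baseline_stable(trace, window=60.0)
        assert report.stable
        assert report.drift_per_min == pytest.approx(0.0, abs=1e-18)

    def test_fast_ramp_fails_and_measures_its_slope(self):
        t = np.arange(0, 200, 2.0)
        ramp = 5e-4 + 4e-6 / 60.0 * t  # 4e-6 per minute
        report = baseline_stable(_trace(t, ramp, [("starter", 150.0)]),
                                 window=60.0)
        assert not report.stable
        assert report.drift_per_min == pytest.approx(4e-6, rel=0.05)

    def test_slow_ramp_passes(self):
        t = np.arange(0, 200, 2.0)
        ramp = 5e-4 + 1e-6 / 60.0 * t
        assert baseline_stable(_trace(t, ramp, [("starter", 150.0)]),
                               window=60.0).stable

    def test_window_exceeding_preevent_span_is_an_error(self):
        t = np.arange(0, 200, 2.0)
        trace = _trace(t, np.full(t.size, 5e-4), [("starter", 30.0)])
        with pytest.raises(InsufficientBaselineError):
            baseline_stable(trace, window=60.0)


class TestSmoothedDerivative:
    def test_linear_trace_recovers_slope(self):
        t = np.arange(0, 100, 1.0)
        m = 3.2e-7
        deriv = smoothed_derivative(_trace(t, 1e-4 + m * t), smooth_window=11)
        assert np.allclose(deriv[10:-10], m, rtol=1e-9)

    def test_logistic_peaks_at_center(self):
        t = np.arange(0, 400, 1.0)
        center = 200.0
        d = 1e-4 / (1 + np.exp(-(t - center) / 10.0))
        deriv = smoothed_derivative(_trace(t, d), smooth_window=11)
        assert abs(t[np.argmax(deriv)] - center) <= 1.0

    def test_sine_matches_analytic_cosine(self):
        # >= 50 samples per period
        t = np.arange(0, 300, 1.0)
        period = 75.0
        w = 2 * np.pi / period
        deriv = smoothed_derivative(_trace(t, np.sin(w * t)), smooth_window=3)
        core = slice(5, -5)
        err = deriv[core] - w * np.cos(w * t[core])
        assert np.sqrt(np.mean(err**2)) / w < 0.02

    @pytest.mark.parametrize("window", [2, 1, 9999])
    def test_window_violations_rejected(self, window):
        t = np.arange(0, 100, 1.0)
        with pytest.raises(ParameterError):
            smoothed_derivative(_trace(t, t * 0.0 + 1), smooth_window=window)


class TestDetectEndpoint:
    @pytest.mark.parametrize("clot", [60.0, 150.0, 300.0, 600.0])
    @pytest.mark.parametrize("width", [5.0, 15.0, 30.0])
    def test_noiseless_recovery_grid(self, scenario_factory, clot, width):
        scn = scenario_factory(sigmoid_center_t=60.0 + clot,
                               sigmoid_width=width,
                               duration=60.0 + clot + 8 * width + 60.0)
        sim = simulate_trace(scn)
        result = detect_endpoint(sim.trace, "starter")
        assert abs(result.clot_time - sim.true_clot_time) <= scn.sample_interval

    def test_loading_artifact_inside_blanking_is_ignored(self, scenario_factory):
        # artifact steeper than the clot burst, fully inside the blanking
        scn = scenario_factory(artifact_amplitude=2e-4, artifact_duration=6.0)
        sim = simulate_trace(scn)
        result = detect_endpoint(sim.trace, "starter", blanking=20.0,
                                 smooth_window=3)
        clean = detect_endpoint(
            simulate_trace(
                dataclasses.replace(scn, artifact_amplitude=0.0)).trace,
            "starter", blanking=20.0, smooth_window=3)
        assert result.end_time == clean.end_time
        assert abs(result.clot_time - sim.true_clot_time) <= scn.sample_interval

    def test_noisy_monte_carlo_recovery(self):
        # liquid-level noise: within +-3 samples of truth in >= 95 of 100
        hits = 0
        for seed in range(100):
            scn = with_seed(TraceScenario(), seed)
            sim = simulate_trace(scn)
            result = detect_endpoint(sim.trace, "starter")
            if abs(result.end_time - sim.true_end_time) <= 3 * scn.sample_interval:
                hits += 1
        assert hits >= 95

    def test_missing_event_label_rejected(self, scenario_factory):
        sim = simulate_trace(scenario_factory())
        with pytest.raises(ParameterError, match="no event"):
            detect_endpoint(sim.trace, "activator")

    def test_flat_trace_raises_no_clot(self):
        t = np.arange(0, 300, 2.0)
        trace = _trace(t, 5e-4 - 1e-9 * t, [("starter", 60.0)])
        with pytest.raises(NoClotError):
            detect_endpoint(trace, "starter")

    def test_time_shift_equivariance(self, scenario_factory):
        sim = simulate_trace(scenario_factory())
        shift = 37.0
        moved = DissipationTrace(
            times=sim.trace.times + shift,
            dissipation=sim.trace.dissipation,
            events=[(l, t + shift) for l, t in sim.trace.events])
        a = detect_endpoint(sim.trace, "starter")
        b = detect_endpoint(moved, "starter")
        assert b.start_time == pytest.approx(a.start_time + shift)
        assert b.end_time == pytest.approx(a.end_time + shift)
        assert b.clot_time == pytest.approx(a.clot_time)

    def test_amplitude_scale_invariance_of_end_time(self):
        sim = simulate_trace(TraceScenario(seed=8))
        scaled = DissipationTrace(times=sim.trace.times,
                                  dissipation=sim.trace.dissipation * 137.0,
                                  events=list(sim.trace.events))
        a = detect_endpoint(sim.trace, "starter")
        b = detect_endpoint(scaled, "starter")
        assert a.end_time == b.end_time
        assert a.qc_flags == b.qc_flags

    def test_longer_blanking_never_moves_endpoint_earlier(self):
        sim = simulate_trace(TraceScenario(seed=3))
        ends = [detect_endpoint(sim.trace, "starter", blanking=b).end_time
                for b in (0.0, 10.0, 40.0, 120.0)]
        assert all(b >= a for a, b in zip(ends, ends[1:]))


class TestRigidityCheck:
    def test_rigid_film(self):
        res = rigidity_check(0.5e-6, 10.0)
        assert res.classification == "rigid"
        assert res.ratio == pytest.approx(0.5e-6)

    def test_coagulation_regime_is_viscoelastic(self):
        # the coagulating-plasma ratio of 2.5e-6 per 10 Hz
        res = rigidity_check(2.5e-6, 10.0)
        assert res.classification == "viscoelastic"
        assert res.ratio == pytest.approx(2.5e-6)

    def test_boundary_is_viscoelastic(self):
        assert rigidity_check(1e-6, 10.0).classification == "viscoelastic"

    def test_zero_frequency_change_rejected(self):
        with pytest.raises(ParameterError, match="delta_f"):
            rigidity_check(1e-6, 0.0)

    def test_simulator_coupling_round_trips_through_check(self):
        # frequency channel encodes D at the coagulation coupling ratio
        scn = TraceScenario(noise_sd=0.0)
        sim = simulate_trace(scn)
        d0, d1 = sim.trace.dissipation[0], sim.trace.dissipation[-1]
        f0, f1 = sim.trace.frequency[0], sim.trace.frequency[-1]
        res = rigidity_check(d1 - d0, f1 - f0)
        assert res.classification == "viscoelastic"
        assert res.ratio == pytest.approx(10.0 / scn.freq_coupling, rel=1e-9)
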