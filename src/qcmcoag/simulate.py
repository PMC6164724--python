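"""Seeded coagulation-trace simulator.

Generates dissipation/frequency time series with the morphology of a real
QCM coagulation run — stable drifting baseline, pipetting artifact at the
reagent-addition event, slow fibrin-attachment rise, logistic thrombin-burst
rise, plateau — plus white Gaussian noise at the instrument's measured
stability level.  The logistic centre is the ground-truth endpoint (its
maximum-slope instant), which downstream detection must recover.

Defaults describe a plasma APTT-style run on a 10 MHz crystal: one
dissipation sample every 2 s (one frequency sweep per sample), liquid-phase
noise of 2.5e-6, a total burst amplitude of 1e-4 and a frequency channel
coupled at the coagulation ratio of 2.5e-6 dissipation per 10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .endpoint import DissipationTrace
from .errors import ScenarioError

__all__ = ["TraceScenario", "SimulationResult", "simulate_trace", "with_seed",
           "NOISE_SD_AIR", "NOISE_SD_LIQUID"]

#: short-term dissipation stability, empty chamber
NOISE_SD_AIR = 1e-6
#: short-term dissipation stability, PBS-covered electrode
NOISE_SD_LIQUID = 2.5e-6


@dataclass(frozen=True)
class TraceScenario:
    """Ground-truth description of one simulated coagulation run.

    All dissipation quantities are dimensionless (reported externally in
    1e-6 units); times in seconds.  ``sigmoid_center_t`` is the absolute
    ground-truth endpoint; ``event_times`` labels reagent additions, the
    first of which is conventionally the assay start.  ``freq_coupling`` is
    the frequency drop (Hz) per unit dissipation rise; the default is the
    inverse of the coagulation-regime ratio of 2.5e-6 per 10 Hz.
    """

    baseline_D: float = 5e-4
    drift_rate: float = 1e-6  # dissipation per minute
    artifact_amplitude: float = 5e-6
    artifact_duration: float = 8.0  # s
    slow_rise_rate: float = 1e-7  # dissipation per s
    sigmoid_amplitude: float = 1e-4
    sigmoid_center_t: float = 360.0  # s, absolute ground-truth endpoint
    sigmoid_width: float = 5.0  # s, logistic time constant
    noise_sd: float = NOISE_SD_LIQUID
    event_times: tuple[tuple[str, float], ...] = (("starter", 60.0),)
    sample_interval: float = 2.0  # s
    duration: float = 600.0  # s
    freq_coupling: float = 4e6  # Hz per unit dissipation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ScenarioError("sample_interval must be positive")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be non-negative")
        if self.sigmoid_width <= 0:
            raise ScenarioError("sigmoid_width must be positive")
        if not self.event_times:
            raise ScenarioError("at least one reagent-addition event is required")
        for label, t in self.event_times:
            if not (0.0 <= t < self.duration):
                raise ScenarioError(
                    f"event {label!r} at t={t} s lies outside the run "
                    f"duration of {self.duration} s"
                )
        if self.sigmoid_center_t <= self.start_time:
            raise ScenarioError(
                "sigmoid_center_t must fall after the start event"
            )

    @property
    def start_time(self) -> float:
        """Time of the first (start) event."""
        return min(t for _, t in self.event_times)


@dataclass(frozen=True)
class SimulationResult:
    """A simulated trace together with its noise-free ground truth."""

    trace: DissipationTrace
    true_end_time: float  # s, max-slope instant of the noiseless curve
    noiseless: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def true_clot_time(self) -> float:
        start = min(t for _, t in self.trace.events)
        return self.true_end_time - start


def _noiseless_curve(scn: TraceScenario, t: np.ndarray,
                     include_artifact: bool = True) -> np.ndarray:
    t0 = scn.start_time
    d = np.full_like(t, scn.baseline_D)
    d += scn.drift_rate / 60.0 * t
    after = t > t0
    d += np.where(after, scn.slow_rise_rate * (t - t0), 0.0)
    # logistic thrombin-burst rise, max slope at sigmoid_center_t
    d += scn.sigmoid_amplitude / (
        1.0 + np.exp(-(t - scn.sigmoid_center_t) / scn.sigmoid_width)
    )
    if include_artifact and scn.artifact_amplitude > 0 and scn.artifact_duration > 0:
        # raised-cosine pipetting bump immediately after the start event
        u = (t - t0) / scn.artifact_duration
        bump = np.where(
            (u > 0) & (u < 1),
            0.5 * scn.artifact_amplitude * (1.0 - np.cos(2.0 * np.pi * u)),
            0.0,
        )
        d += bump
    return d


def simulate_trace(scenario: TraceScenario) -> SimulationResult:
    """Simulate one coagulation run; deterministic for a given seed.

    The trace is the noiseless morphological curve plus white Gaussian noise
    on the dissipation channel; the frequency channel is the resonator
    frequency minus ``freq_coupling`` times the dissipation rise above
    baseline.  The reported ground-truth end time is the maximum-slope
    instant of the noiseless, artifact-free curve on the sample grid.
    """
    n = int(np.floor(scenario.duration / scenario.sample_interval)) + 1
    t = np.arange(n) * scenario.sample_interval
    clean = _noiseless_curve(scenario, t)
    rng = np.random.default_rng(scenario.seed)
    noise = rng.normal(0.0, scenario.noise_sd, size=n) if scenario.noise_sd > 0 \
        else np.zeros(n)
    dissipation = clean + noise
    frequency = 10e6 - scenario.freq_coupling * (clean + noise - scenario.baseline_D)

    morph = _noiseless_curve(scenario, t, include_artifact=False)
    slope = np.gradient(morph, t)
    true_end = float(t[int(np.argmax(slope))])

    trace = DissipationTrace(
        times=t,
        dissipation=dissipation,
        frequency=frequency,
        events=[(label, float(tt)) for label, tt in scenario.event_times],
    )
    return SimulationResult(trace=trace, true_end_time=true_end, noiseless=clean)


def with_seed(scenario: TraceScenario, seed: int) -> TraceScenario:
    """Copy of ``scenario`` with a different random seed."""
    return replace(scenario, seed=seed)
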