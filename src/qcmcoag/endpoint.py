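"""Clot-time endpoint detection on dissipation time series.

A coagulation run traced by QCM dissipation has a characteristic morphology:
a stable baseline, a loading fluctuation when the reagent is pipetted in, a
slow rise while fibrin starts to attach, a rapid sigmoidal rise during the
thrombin burst, and a plateau once the clot is formed.  The assay start point
is the reagent-addition instant; the end point is the peak of the first-order
derivative of the dissipation curve (the moment of fastest fibrin formation);
the clot time (APTT or PT) is the elapsed time between them.

The module also provides the baseline-stability gate applied before each
measurement and the Sauerbrey-regime rigidity check that motivates tracking
dissipation rather than frequency during coagulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InsufficientBaselineError, NoClotError, ParameterError, ScenarioError

__all__ = [
    "DissipationTrace",
    "ClotResult",
    "BaselineReport",
    "RigidityResult",
    "baseline_stable",
    "smoothed_derivative",
    "detect_endpoint",
    "rigidity_check",
]

#: baseline drift tolerance, dissipation per minute
DEFAULT_BASELINE_THRESHOLD = 2e-6
#: post-start blanking to skip the loading artifact, seconds
DEFAULT_BLANKING = 10.0
#: moving-average width for derivative smoothing, samples (odd)
DEFAULT_SMOOTH_WINDOW = 11
#: nominal thrombin-burst rise time used by the minimum-peak-slope gate, s
NOMINAL_RISE_TIME = 30.0


@dataclass
class DissipationTrace:
    """Time series of dissipation (and optionally frequency) with events.

    ``times`` are seconds, strictly increasing; ``dissipation`` is the
    dimensionless dissipation factor; ``frequency`` (Hz) is an optional
    parallel channel; ``events`` labels reagent-addition instants.
    """

    times: np.ndarray
    dissipation: np.ndarray
    frequency: np.ndarray | None = None
    events: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dissipation = np.asarray(self.dissipation, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ScenarioError("trace needs at least two samples")
        if self.dissipation.shape != self.times.shape:
            raise ScenarioError("dissipation and times lengths differ")
        if not np.all(np.diff(self.times) > 0):
            raise ScenarioError("times must be strictly increasing")
        if self.frequency is not None:
            self.frequency = np.asarray(self.frequency, dtype=float)
            if self.frequency.shape != self.times.shape:
                raise ScenarioError("frequency and times lengths differ")
        for label, t in self.events:
            if not (self.times[0] <= t <= self.times[-1]):
                raise ScenarioError(
                    f"event {label!r} at t={t} s outside the trace span"
                )

    def event_time(self, label: str) -> float:
        for name, t in self.events:
            if name == label:
                return float(t)
        raise ParameterError(f"no event labelled {label!r} in trace")


@dataclass(frozen=True)
class ClotResult:
    """Detected start/end points and the resulting clot time."""

    start_time: float  # s
    end_time: float  # s
    clot_time: float  # s
    peak_slope: float  # dissipation per s
    blanking_used: float  # s
    qc_flags: tuple[str, ...] = ()
    start_event: str = ""  # which reagent-addition event defined the start

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ParameterError("end_time must exceed start_time")
        if abs(self.clot_time - (self.end_time - self.start_time)) > 1e-9:
            raise ParameterError("clot_time must equal end_time - start_time")


@dataclass(frozen=True)
class BaselineReport:
    stable: bool
    drift_per_min: float  # signed least-squares slope, dissipation / min
    residual_ptp: float  # peak-to-peak residual about the fitted line


@dataclass(frozen=True)
class RigidityResult:
    classification: str  # "rigid" or "viscoelastic"
    ratio: float  # |dD| per 10 Hz of |df|


def baseline_stable(
    trace: DissipationTrace,
    window: float = 60.0,
    threshold: float = DEFAULT_BASELINE_THRESHOLD,
) -> BaselineReport:
    """Assess pre-event baseline drift against a dissipation-per-minute gate.

    Fits a straight line to the last ``window`` seconds before the first
    event; the baseline passes iff the |slope| is at most ``threshold``
    (dissipation per minute) and the peak-to-peak residual about the line is
    at most ``threshold * window / 60``.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    if not trace.events:
        raise InsufficientBaselineError("trace has no events; baseline undefined")
    t_first = min(t for _, t in trace.events)
    mask = (trace.times < t_first) & (trace.times >= t_first - window)
    if t_first - window < trace.times[0] or mask.sum() < 5:
        raise InsufficientBaselineError(
            f"baseline window of {window} s needs >= 5 samples and must fit "
            f"before the first event at {t_first} s"
        )
    t = trace.times[mask]
    d = trace.dissipation[mask]
    slope, intercept = np.polyfit(t, d, 1)
    residual = d - (slope * t + intercept)
    drift_per_min = slope * 60.0
    ptp = float(np.ptp(residual))
    stable = abs(drift_per_min) <= threshold and ptp <= threshold * window / 60.0
    return BaselineReport(stable=bool(stable), drift_per_min=float(drift_per_min),
                          residual_ptp=ptp)


def smoothed_derivative(
    trace: DissipationTrace, smooth_window: int = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """Moving-average smoothing followed by finite-difference differentiation.

    Central differences in the interior, one-sided at the ends; the output has
    the same length as the input and units of dissipation per second.
    """
    n = trace.times.size
    if smooth_window % 2 == 0 or smooth_window < 3 or smooth_window >= n:
        raise ParameterError(
            f"smooth_window must be odd, >= 3 and < {n}, got {smooth_window}"
        )
    smoothed = uniform_filter1d(trace.dissipation, size=smooth_window,
                                mode="nearest")
    return np.gradient(smoothed, trace.times)


def _estimate_noise_sd(trace: DissipationTrace, t_start: float) -> float:
    """MAD-based noise estimate from first differences (pre-start if possible)."""
    pre = trace.dissipation[trace.times < t_start]
    samples = pre if pre.size >= 10 else trace.dissipation
    diffs = np.diff(samples)
    if diffs.size == 0:
        return 0.0
    # sd of x from sd of successive differences: sd(dx) = sqrt(2) sd(x)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_endpoint(
    trace: DissipationTrace,
    start_event_label: str,
    blanking: float = DEFAULT_BLANKING,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    baseline_window: float = 60.0,
    baseline_threshold: float = DEFAULT_BASELINE_THRESHOLD,
    min_peak_slope: float | None = None,
) -> ClotResult:
    """Locate the clot endpoint as the post-blanking derivative-peak instant.

    The start point is the named reagent-addition event; the end point is the
    global maximum of the smoothed first derivative restricted to
    ``t > start + blanking`` (the blanking interval excludes the pipetting
    artifact).  QC flags record baseline failure, a peak pinned at the search
    boundary, and a peak slope below ``min_peak_slope`` (defaulting to five
    noise standard deviations per nominal 30 s rise time).
    """
    if blanking < 0:
        raise ParameterError("blanking must be non-negative")
    start_time = trace.event_time(start_event_label)
    search = trace.times > start_time + blanking
    if search.sum() < 3:
        raise ParameterError(
            "trace must extend beyond the blanking interval after the start event"
        )
    deriv = smoothed_derivative(trace, smooth_window)
    idx = np.flatnonzero(search)
    rel_peak = int(np.argmax(deriv[idx]))
    peak_i = idx[rel_peak]
    peak_slope = float(deriv[peak_i])
    if peak_slope <= 0:
        raise NoClotError("no positive dissipation slope after blanking (no clot)")
    end_time = float(trace.times[peak_i])

    flags: list[str] = []
    try:
        report = baseline_stable(trace, window=baseline_window,
                                 threshold=baseline_threshold)
        if not report.stable:
            flags.append("baseline_unstable")
    except InsufficientBaselineError:
        flags.append("baseline_unassessed")
    if rel_peak == 0 or rel_peak == idx.size - 1:
        flags.append("peak_at_boundary")
    if min_peak_slope is None:
        min_peak_slope = 5.0 * _estimate_noise_sd(trace, start_time) / NOMINAL_RISE_TIME
    if peak_slope < min_peak_slope:
        flags.append("low_peak_slope")

    return ClotResult(
        start_time=start_time,
        end_time=end_time,
        clot_time=end_time - start_time,
        peak_slope=peak_slope,
        blanking_used=float(blanking),
        qc_flags=tuple(flags),
        start_event=start_event_label,
    )


def rigidity_check(delta_D: float, delta_f: float) -> RigidityResult:
    """Classify a film as Sauerbrey-rigid or viscoelastic.

    The ratio is |dD| per 10 Hz of |df|; films below 1e-6 per 10 Hz are in
    the rigid (Sauerbrey) regime, anything at or above is viscoelastic —
    coagulating plasma runs around 2.5e-6 per 10 Hz.
    """
    if delta_f == 0:
        raise ParameterError("delta_f must be non-zero: ratio undefined")
    ratio = abs(delta_D) / (abs(delta_f) / 10.0)
    classification = "rigid" if ratio < 1e-6 else "viscoelastic"
    return RigidityResult(classification=classification, ratio=float(ratio))
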