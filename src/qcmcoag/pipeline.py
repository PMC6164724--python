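"""End-to-end seeded experiments chaining simulator, detection, calibration."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibrate import CalibrationModel, fit_calibration
from .endpoint import detect_endpoint
from .simulate import NOISE_SD_LIQUID, TraceScenario, simulate_trace

__all__ = ["CalibrationExperiment", "run_calibration_experiment"]


@dataclass(frozen=True)
class CalibrationExperiment:
    """Outcome of a simulated device-vs-reference calibration study."""

    reference_times: np.ndarray  # s, assigned reference clot times
    true_device_times: np.ndarray  # s, programmed device clot times
    detected_times: np.ndarray  # s, clot times recovered by detection
    model: CalibrationModel  # reference = f(detected device time)


def run_calibration_experiment(
    reference_times=None,
    device_slope: float = 8.0,
    device_intercept: float = 20.0,
    noise_sd: float = NOISE_SD_LIQUID,
    seed: int = 0,
    scenario: TraceScenario | None = None,
) -> CalibrationExperiment:
    """Simulate paired device/reference measurements and fit the calibration.

    Each assigned reference clot time ``r`` is mapped to a programmed device
    clot time ``device_slope * r + device_intercept`` (the device, run at
    room temperature, reads consistently prolonged), a full coagulation
    trace is simulated at that endpoint with liquid-level noise, the clot
    time is recovered by derivative-peak detection, and the detected times
    are regressed against the reference values.  A faithful pipeline
    recovers the inverse affine map with adjusted R² near 1.
    """
    if reference_times is None:
        reference_times = np.linspace(25.0, 47.0, 12)  # typical APTT span, s
    reference_times = np.asarray(reference_times, dtype=float)
    base = scenario if scenario is not None else TraceScenario()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=reference_times.size)

    true_dev = device_slope * reference_times + device_intercept
    detected = np.empty_like(true_dev)
    for i, clot in enumerate(true_dev):
        start = base.start_time
        scn = replace(
            base,
            sigmoid_center_t=start + clot,
            duration=start + clot + 60.0,
            noise_sd=noise_sd,
            seed=int(seeds[i]),
        )
        sim = simulate_trace(scn)
        label = scn.event_times[0][0]
        result = detect_endpoint(sim.trace, start_event_label=label)
        detected[i] = result.clot_time

    model = fit_calibration(detected, reference_times)
    return CalibrationExperiment(
        reference_times=reference_times,
        true_device_times=true_dev,
        detected_times=detected,
        model=model,
    )
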