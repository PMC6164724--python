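"""Cross-calibration of device clot times against a reference analyzer.

Device clot times (measured at a controlled room temperature, hence
consistently prolonged relative to 37 °C reference instruments) map onto
reference APTT/PT values by ordinary least squares, reference = slope ·
device + intercept.  The reported goodness of fit is the adjusted R²; the
consistent temperature prolongation is absorbed by the affine map, so no
separate temperature term is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = ["CalibrationModel", "fit_calibration", "apply_calibration",
           "invert_calibration"]


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map from device clot time to reference-scale time."""

    slope: float  # dimensionless
    intercept: float  # s
    r_squared: float  # adjusted R-squared
    n: int  # number of calibration pairs
    r_squared_plain: float = float("nan")  # unadjusted, logged alongside

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ParameterError("a calibration needs at least 3 pairs")


def fit_calibration(device_times, reference_times) -> CalibrationModel:
    """Ordinary least squares of reference times on device times.

    Requires at least three pairs (the adjusted R² is undefined below that)
    and non-constant device times.
    """
    x = np.asarray(device_times, dtype=float)
    y = np.asarray(reference_times, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("device and reference times must be 1-D, same length")
    n = x.size
    if n < 3:
        raise ParameterError(
            f"degenerate fit: need >= 3 pairs for an adjusted R^2, got {n}"
        )
    if np.ptp(x) == 0:
        raise ParameterError("degenerate fit: device times are constant")
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2_adj),
        n=n,
        r_squared_plain=float(r2),
    )


def apply_calibration(model: CalibrationModel, device_time: float) -> float:
    """Map a device clot time onto the reference-instrument scale."""
    return model.slope * np.asarray(device_time, dtype=float) + model.intercept


def invert_calibration(model: CalibrationModel, reference_time: float) -> float:
    """Inverse map: reference-scale time back to the device scale."""
    if model.slope == 0:
        raise ParameterError("cannot invert a zero-slope calibration")
    return (np.asarray(reference_time, dtype=float) - model.intercept) / model.slope
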