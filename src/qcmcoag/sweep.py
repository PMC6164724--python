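"""Per-frequency quadrature measurement protocol and sweep emulation.

The instrument measures the resonator's magnitude frequency response one
point at a time.  At each frequency it mixes the pathway output with 0° and
90° references and low-pass filters, recording two DC voltages, for three
pathways in turn:

1. *dark* — switches open: electronic offset/noise only;
2. *calibration* — a unit-gain reference path: zero-point calibration;
3. *measurement* — the crystal path.

The relative magnitude at that frequency is then

    Magnitude = Mmea - Mcali,   Mx = 20 log10 |v_x - v_dark|

with the dark-corrected (0°, 90°) voltage pairs treated as 2-vectors.  The
dark subtraction removes constant offsets exactly, and any gain common to
the calibration and measurement paths cancels in the difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, ParameterError

__all__ = [
    "SweepConfig",
    "QuadraturePoint",
    "MagnitudeSpectrum",
    "MAGNITUDE_FLOOR_DB",
    "magnitude_at",
    "demodulate_point",
    "acquire_point",
    "run_sweep",
]

#: sentinel for an exactly-zero dark-corrected measurement vector
MAGNITUDE_FLOOR_DB = -200.0

_PATHWAYS = ("dark", "calibration", "measurement")


@dataclass(frozen=True)
class SweepConfig:
    """Linear frequency grid of the sweep, endpoints included."""

    f_start: float = 9.98e6  # Hz
    f_stop: float = 10.02e6  # Hz
    n_points: int = 200

    def __post_init__(self) -> None:
        if not self.f_start < self.f_stop:
            raise ParameterError("f_start must be below f_stop")
        if self.n_points < 8:
            raise ParameterError("n_points must be at least 8")

    def frequencies(self) -> np.ndarray:
        return np.linspace(self.f_start, self.f_stop, self.n_points)


@dataclass(frozen=True)
class QuadraturePoint:
    """Six-voltage record of one frequency point (volts, arbitrary units)."""

    freq: float
    v_dark_0: float
    v_dark_90: float
    v_cali_0: float
    v_cali_90: float
    v_mea_0: float
    v_mea_90: float

    def __post_init__(self) -> None:
        for name in ("v_dark_0", "v_dark_90", "v_cali_0", "v_cali_90",
                     "v_mea_0", "v_mea_90"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class MagnitudeSpectrum:
    """Relative magnitude (dB) versus frequency (Hz), ascending grid."""

    freqs: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "magnitudes",
                           np.asarray(self.magnitudes, dtype=float))
        if self.freqs.shape != self.magnitudes.shape or self.freqs.ndim != 1:
            raise ParameterError("freqs and magnitudes must be 1-D, same length")
        if not np.all(np.diff(self.freqs) > 0):
            raise ParameterError("freqs must be strictly increasing")


def magnitude_at(point: QuadraturePoint) -> float:
    """Calibrated relative magnitude (dB) of one six-voltage record.

    0 dB means the measurement path equals the calibration path.  A zero
    dark-corrected calibration vector is unrecoverable; a zero dark-corrected
    measurement vector returns the documented floor sentinel (−200 dB)
    instead of −inf so downstream fitting stays total.
    """
    cali = complex(point.v_cali_0 - point.v_dark_0,
                   point.v_cali_90 - point.v_dark_90)
    mea = complex(point.v_mea_0 - point.v_dark_0,
                  point.v_mea_90 - point.v_dark_90)
    if cali == 0:
        raise CalibrationError(
            f"zero dark-corrected calibration vector at {point.freq} Hz"
        )
    if mea == 0:
        return MAGNITUDE_FLOOR_DB
    m_mea = 20.0 * math.log10(abs(mea))
    m_cali = 20.0 * math.log10(abs(cali))
    return m_mea - m_cali


def demodulate_point(
    device,
    freq: float,
    pathway: str,
    noise_sd: float = 0.0,
    rng=None,
    gain: float = 1.0,
) -> tuple[float, float]:
    """Emulate one pathway's post-LPF (in-phase, quadrature) voltage pair.

    ``device`` maps frequency (Hz) to the complex transfer value H.  The
    dark pathway yields noise only; calibration yields the reference gain on
    the in-phase channel; measurement yields ``gain * (Re H, Im H)``.
    """
    if freq <= 0:
        raise ParameterError("freq must be strictly positive")
    if pathway not in _PATHWAYS:
        raise ParameterError(
            f"unknown pathway {pathway!r}; expected one of {_PATHWAYS}"
        )
    if pathway == "dark":
        v0, v90 = 0.0, 0.0
    elif pathway == "calibration":
        v0, v90 = gain, 0.0
    else:
        h = complex(device(freq))
        v0, v90 = gain * h.real, gain * h.imag
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        n0, n90 = rng.normal(0.0, noise_sd, size=2)
        v0, v90 = v0 + n0, v90 + n90
    return float(v0), float(v90)


def acquire_point(
    device,
    freq: float,
    noise_sd: float = 0.0,
    rng=None,
    cal_gain: float = 1.0,
    mea_gain: float = 1.0,
) -> QuadraturePoint:
    """Run the full dark/calibration/measurement protocol at one frequency."""
    rng = np.random.default_rng(rng)
    vd = demodulate_point(device, freq, "dark", noise_sd, rng)
    vc = demodulate_point(device, freq, "calibration", noise_sd, rng, cal_gain)
    vm = demodulate_point(device, freq, "measurement", noise_sd, rng, mea_gain)
    return QuadraturePoint(freq, vd[0], vd[1], vc[0], vc[1], vm[0], vm[1])


def run_sweep(
    config: SweepConfig,
    device,
    noise_sd: float = 0.0,
    seed: int | None = None,
    cal_gain: float = 1.0,
    mea_gain: float = 1.0,
) -> MagnitudeSpectrum:
    """Sweep the full protocol over the configured grid; seeded, deterministic."""
    rng = np.random.default_rng(seed)
    freqs = config.frequencies()
    mags = np.empty_like(freqs)
    for i, f in enumerate(freqs):
        point = acquire_point(device, f, noise_sd, rng, cal_gain, mea_gain)
        mags[i] = magnitude_at(point)
    return MagnitudeSpectrum(freqs=freqs, magnitudes=mags)
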