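"""Physics of the loaded shear-mode resonator.

A quartz crystal microbalance (QCM) driven at its fundamental thickness-shear
resonance radiates a damped shear wave into the contacting liquid.  Two
closed-form results govern the sensing physics:

* the shear-wave penetration (sensing) depth in a Newtonian liquid,
  ``delta = sqrt(eta / (pi * f0 * rho))``, which limits the probed region to a
  few hundred nanometres at 10 MHz; and
* the dissipation shift of the crystal loaded by that liquid plus a thin
  Kelvin–Voigt viscoelastic film (spring ``mu1`` and dashpot ``eta1`` in
  parallel, thickness ``h1``) at its surface.

The module also provides the idealised single-peak (Lorentzian) transfer
function used by the sweep emulator; its normative property is that the −3 dB
fractional bandwidth equals the programmed dissipation factor, ``BW/fs = D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "ResonatorParams",
    "LiquidParams",
    "FilmParams",
    "sensing_depth",
    "dissipation_shift_kelvin_voigt",
    "magnitude_response",
    "resonator_transfer",
]


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ParameterError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ResonatorParams:
    """Unloaded crystal: resonant frequency, intrinsic Q, density, thickness.

    Defaults describe an AT-cut quartz crystal with a 10 MHz fundamental
    (``rho0`` and ``h0`` are standard AT-cut values, assumed not measured).
    The intrinsic dissipation is ``1 / Q0``.
    """

    f0: float = 10e6  # Hz
    Q0: float = 1e5  # dimensionless
    rho0: float = 2648.0  # kg/m^3
    h0: float = 1.67e-4  # m

    def __post_init__(self) -> None:
        for name in ("f0", "Q0", "rho0", "h0"):
            _require_positive(name, getattr(self, name))

    @property
    def intrinsic_dissipation(self) -> float:
        return 1.0 / self.Q0


@dataclass(frozen=True)
class LiquidParams:
    """Bulk Newtonian liquid: shear viscosity (Pa·s) and density (kg/m³).

    Defaults are the plasma values used for the sensing-depth estimate.
    """

    eta: float = 1.42e-3  # Pa·s
    rho: float = 1.03e3  # kg/m^3

    def __post_init__(self) -> None:
        _require_positive("eta", self.eta)
        _require_positive("rho", self.rho)


@dataclass(frozen=True)
class FilmParams:
    """Kelvin–Voigt surface film: thickness, shear elasticity, viscosity."""

    h1: float = 0.0  # m
    mu1: float = 0.0  # Pa
    eta1: float = 0.0  # Pa·s

    def __post_init__(self) -> None:
        for name in ("h1", "mu1", "eta1"):
            if getattr(self, name) < 0:
                raise ParameterError(
                    f"{name} must be non-negative, got {getattr(self, name)!r}"
                )
        if self.h1 > 0 and self.mu1 == 0 and self.eta1 == 0:
            raise ParameterError(
                "degenerate film: h1 > 0 requires mu1 or eta1 to be non-zero"
            )


def sensing_depth(liquid: LiquidParams, f0: float) -> float:
    """Shear-wave penetration depth ``sqrt(eta / (pi * f0 * rho))`` in metres.

    Strictly increasing in viscosity, strictly decreasing in frequency and
    density; ~210 nm for plasma on a 10 MHz crystal.
    """
    _require_positive("f0", f0)
    return math.sqrt(liquid.eta / (math.pi * f0 * liquid.rho))


def dissipation_shift_kelvin_voigt(
    res: ResonatorParams, liquid: LiquidParams, film: FilmParams
) -> float:
    """Dissipation shift of the crystal under liquid + Kelvin–Voigt film load.

    Returns the dimensionless shift

        dD = (1 / (pi f0 rho0 h0)) * { eta/delta
             + 2 h1 (eta/delta)^2 * eta1 w / (mu1^2 + w^2 eta1^2) }

    with ``delta`` the sensing depth in the bulk liquid and ``w = 2 pi f0``.
    The first term is the semi-infinite-liquid loss; the second, the extra
    loss in the film, vanishes for ``h1 = 0`` and is linear in ``h1``.
    """
    delta = sensing_depth(liquid, res.f0)
    omega = 2.0 * math.pi * res.f0
    eta_over_delta = liquid.eta / delta
    liquid_term = eta_over_delta
    if film.h1 > 0:
        film_term = (
            2.0
            * film.h1
            * eta_over_delta**2
            * film.eta1
            * omega
            / (film.mu1**2 + omega**2 * film.eta1**2)
        )
    else:
        film_term = 0.0
    prefactor = 1.0 / (math.pi * res.f0 * res.rho0 * res.h0)
    return prefactor * (liquid_term + film_term)


def magnitude_response(res: ResonatorParams, loaded_D: float, freq):
    """Complex transfer value of the loaded resonance at ``freq`` (Hz).

    A symmetric Lorentzian ``H(f) = 1 / (1 + 2j (f - fs) / (D fs))`` with
    ``fs = res.f0``: unit magnitude and zero phase at resonance, −3 dB full
    width exactly ``loaded_D * fs``.  Accepts scalar or array ``freq``.
    """
    _require_positive("loaded_D", loaded_D)
    freq = np.asarray(freq, dtype=float)
    if np.any(freq <= 0):
        raise ParameterError("freq must be strictly positive")
    fs = res.f0
    h = 1.0 / (1.0 + 2j * (freq - fs) / (loaded_D * fs))
    return complex(h) if np.ndim(h) == 0 else h


def resonator_transfer(res: ResonatorParams, loaded_D: float):
    """Return ``freq -> H(freq)`` for use as a sweep-emulator device model."""
    _require_positive("loaded_D", loaded_D)

    def device(freq):
        return magnitude_response(res, loaded_D, freq)

    return device
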