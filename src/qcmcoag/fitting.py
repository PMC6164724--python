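"""Resonance-curve fitting: (fs, BW, D) from a magnitude spectrum.

The dissipation factor of the crystal is the reciprocal quality factor,

    D = 1 / Q = BW / fs,

with ``fs`` the resonant frequency and ``BW`` the −3 dB (half-power,
20·log10(√2) ≈ 3.0103 dB) full bandwidth of the magnitude response.  Both
descriptors are determined from a third-order polynomial fitted to the swept
spectrum in a local window around the peak.

The polynomial is fitted to the *reciprocal power* 10^(−dB/10) rather than
to the dB values: for a Lorentzian resonance the reciprocal power is exactly
quadratic in frequency, so the cubic fit recovers ``fs`` (the vertex) and
the half-power crossings (roots of ``p(f) = 2·p(fs)``) without grid-scale
interpolation error even when the bandwidth spans only a few grid points.
The half-power rule on reciprocal power is identical to the −3.0103 dB rule
on magnitude, and a constant dB offset rescales the polynomial without
moving its vertex or crossing ratios, so the estimate is offset-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError
from .sweep import MagnitudeSpectrum

__all__ = ["ResonanceFit", "fit_resonance", "dissipation_from_fit"]

#: half-power level in dB, 20*log10(sqrt(2))
HALF_POWER_DB = 10.0 * np.log10(2.0)

#: minimum grid points kept on each side of the peak in the fit window
_MIN_SIDE = 2


@dataclass(frozen=True)
class ResonanceFit:
    """Fitted resonance descriptors of one spectrum."""

    fs: float  # Hz
    bw: float  # Hz, -3 dB full width
    dissipation: float  # bw / fs
    peak_db: float  # fitted peak magnitude, dB
    fit_window: tuple[float, float]  # Hz
    rms_residual: float  # dB, over the fit window

    def __post_init__(self) -> None:
        if not self.bw > 0:
            raise FitError("fitted bandwidth must be positive")
        if not (self.fit_window[0] <= self.fs <= self.fit_window[1]):
            raise FitError("fitted fs lies outside the fit window")


def _window_indices(mags: np.ndarray, i_pk: int) -> tuple[int, int]:
    """Peak window: out to the first point 6 dB below the grid maximum.

    Falls back to the nearest 25% of points per side where the spectrum
    never drops 6 dB, and always keeps at least two points per side.
    """
    n = mags.size
    level = mags[i_pk] - 6.0
    i_lo = None
    for j in range(i_pk - 1, -1, -1):
        if mags[j] <= level:
            i_lo = j
            break
    if i_lo is None:
        i_lo = max(0, i_pk - max(_MIN_SIDE, n // 4))
    i_hi = None
    for j in range(i_pk + 1, n):
        if mags[j] <= level:
            i_hi = j
            break
    if i_hi is None:
        i_hi = min(n - 1, i_pk + max(_MIN_SIDE, n // 4))
    i_lo = min(i_lo, max(i_pk - _MIN_SIDE, 0))
    i_hi = max(i_hi, min(i_pk + _MIN_SIDE, n - 1))
    return i_lo, i_hi


def fit_resonance(spectrum: MagnitudeSpectrum) -> ResonanceFit:
    """Fit one resonance peak and extract (fs, BW, D).

    Steps: locate the grid maximum (ties resolved to the lowest frequency);
    select the local window around it; least-squares fit a cubic to the
    reciprocal power in the window; take ``fs`` as the polynomial's interior
    minimum of reciprocal power (i.e. the magnitude peak) and the −3 dB
    crossings as the roots of the polynomial at twice its minimum; then
    ``D = BW / fs``.

    Raises ``FitError('no resonance')`` for spectra without a strict interior
    maximum, and ``FitError('bandwidth exceeds sweep')`` when a half-power
    crossing falls outside the sweep span.
    """
    f = spectrum.freqs
    m = spectrum.magnitudes
    n = f.size
    if n < 8:
        raise FitError("spectrum needs at least 8 points")
    i_pk = int(np.argmax(m))  # first max -> lowest-frequency tie-break
    if i_pk == 0 or i_pk == n - 1:
        raise FitError("no resonance: spectrum maximum is not interior")

    i_lo, i_hi = _window_indices(m, i_pk)
    fw = f[i_lo : i_hi + 1]
    mw = m[i_lo : i_hi + 1]
    if fw.size < 4:
        raise FitError("no resonance: fit window too small for a cubic")

    # scaled local coordinate keeps the Vandermonde matrix well conditioned
    # and makes the fit exactly equivariant under frequency-axis shifts
    f_ref = f[i_pk]
    scale = fw[-1] - fw[0]
    x = (fw - f_ref) / scale
    q = 10.0 ** (-mw / 10.0)  # reciprocal power
    coeffs = np.polyfit(x, q, 3, w=1.0 / q)

    # interior minimum of the cubic = magnitude peak
    crit = np.roots(np.polyder(coeffs))
    crit = crit[np.isreal(crit)].real
    crit = crit[(crit >= x[0]) & (crit <= x[-1])]
    if crit.size == 0:
        raise FitError("no resonance: fitted polynomial has no interior peak")
    vals = np.polyval(coeffs, crit)
    x_min = float(crit[np.argmin(vals)])
    q_min = float(np.min(vals))
    if q_min <= 0:
        raise FitError("no resonance: fitted power is non-positive at the peak")
    fs = f_ref + scale * x_min
    peak_db = -10.0 * np.log10(q_min)

    # half-power crossings: p(x) = 2 q_min
    shifted = coeffs.copy()
    shifted[-1] -= 2.0 * q_min
    roots = np.roots(shifted)
    roots = roots[np.isreal(roots)].real
    x_span = ((f[0] - f_ref) / scale, (f[-1] - f_ref) / scale)
    lo = roots[(roots < x_min) & (roots >= x_span[0])]
    hi = roots[(roots > x_min) & (roots <= x_span[1])]
    if lo.size == 0 or hi.size == 0:
        raise FitError("bandwidth exceeds sweep: half-power level not crossed "
                       "inside the sweep span")
    x_lo = float(lo.max())
    x_hi = float(hi.min())
    bw = scale * (x_hi - x_lo)

    q_fit = np.polyval(coeffs, x)
    good = q_fit > 0
    resid = mw[good] - (-10.0 * np.log10(q_fit[good]))
    rms = float(np.sqrt(np.mean(resid**2))) if good.any() else float("nan")

    return ResonanceFit(
        fs=float(fs),
        bw=float(bw),
        dissipation=float(bw / fs),
        peak_db=float(peak_db),
        fit_window=(float(fw[0]), float(fw[-1])),
        rms_residual=rms,
    )


def dissipation_from_fit(fit: ResonanceFit) -> float:
    """Dissipation factor D = BW / fs = 1/Q of a fitted resonance."""
    return fit.bw / fit.fs
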