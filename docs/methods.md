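# Methods

This note documents the models, default parameters and numerical choices in
`qcmcoag`, and what the synthetic traces do and do not establish about real
blood measurements.

## Sensor physics

The loaded-resonator model covers a 10 MHz fundamental-mode, AT-cut quartz
crystal in a Newtonian liquid, optionally carrying a thin Kelvin–Voigt
viscoelastic film. Two closed forms are implemented:

* **Sensing depth** `δ = sqrt(η / (π f₀ ρ))` — the 1/e decay length of the
  radiated shear wave. For plasma (η = 1.42·10⁻³ Pa·s, ρ = 1.03·10³ kg/m³)
  at 10 MHz this is 209.5 nm, i.e. ~210 nm: the crystal only probes the
  first protein layers at its surface, which is why fibrin capture at the
  electrode dominates the signal.
* **Kelvin–Voigt dissipation shift**
  `ΔD ≈ (1/(π f₀ ρ₀ h₀)) · { η/δ + 2 h₁ (η/δ)² η₁ω/(μ₁² + ω²η₁²) }` with
  ω = 2π f₀. The first term is the semi-infinite liquid load; the film term
  is linear in film thickness h₁ and vanishes for h₁ = 0. A film with
  h₁ > 0 but μ₁ = η₁ = 0 is rejected as degenerate.

Crystal density ρ₀ = 2648 kg/m³ and thickness h₀ = 1.67·10⁻⁴ m are **AT-cut
quartz assumptions** (a 10 MHz fundamental), not measured values; they enter
only the absolute scale of ΔD, never the clot-time pipeline.

Only the fundamental resonance is modelled — no overtones, no
Butterworth–Van-Dyke circuit, no temperature-dependent viscosity.

## Resonance transfer function

The instrument's swept read-out needs a curve family. We use the symmetric
Lorentzian `H(f) = 1 / (1 + 2j (f − fs)/(D·fs))`: unit magnitude and zero
phase at resonance, and — the normative contract — a −3 dB full width of
exactly `D·fs`, so the 3 dB rule `D = BW/fs` inverts it identically. Any
other single-peak family satisfying that contract would serve equally; no
circuit component values are asserted.

## Sweep and quadrature demodulation

Each frequency point is measured in three pathway states (dark /
calibration / measurement), each mixed with 0° and 90° references and
ideally low-pass filtered, giving six voltages. The relative magnitude is
`M_mea − M_cali` with `M_x = 20·log10 |v_x − v_dark|` on the complex-valued
voltage pairs. Consequences, all tested: dark subtraction removes any
constant offset exactly; a gain common to calibration and measurement paths
cancels; the result is invariant under a common phase rotation. Voltages
are arbitrary-unit (only ratios matter); ADC quantisation, LPF transients
and dwell times are deliberately not modelled. An exactly zero
dark-corrected measurement vector returns a **−200 dB floor sentinel**
rather than −∞ so downstream fitting stays total; a zero calibration vector
is an unrecoverable error.

The grid is linear and endpoint-inclusive, default 9.98–10.02 MHz with 200
points (spacing ≈ 201 Hz).

## Resonance fitting: the "third polynomial" reading

`fit_resonance` locates the grid maximum (ties → lowest frequency), selects
a window out to the first point 6 dB below the peak on each side (fallback:
25% of points per side; always ≥ 2 points per side), and least-squares fits
a **cubic polynomial to the reciprocal power** `10^(−dB/10)` in a shifted,
scaled local coordinate. fs is the polynomial's interior minimum of
reciprocal power; the −3 dB crossings (half-power, exactly
20·log10(√2) ≈ 3.0103 dB) are the roots of `p(f) = 2·p(fs)`; `D = BW/fs`.

Why reciprocal power rather than a cubic on the dB values: for a Lorentzian
the reciprocal power is *exactly quadratic in frequency*, so the fit
recovers fs and BW to machine precision at any grid density — including
D = 10⁻⁵, whose 100 Hz bandwidth spans less than one 201 Hz grid step, where
any interpolation of the sampled dB curve is off by >100%. The fit is
weighted by 1/power so that multiplicative (dB-additive) noise enters
near-homoscedastically, which keeps the estimator unbiased at the 0.01 dB
noise level (verified over 200 seeded replicates). A constant dB offset
rescales the polynomial without moving vertex or crossing ratios, and the
shifted local coordinate makes the fit exactly equivariant under frequency
translations; both properties are tested.

Error taxonomy: "no resonance" when the spectrum maximum is not strictly
interior (monotone or boundary-peaked spectra); "bandwidth exceeds sweep"
when a half-power crossing falls outside the sweep span.

## Trace simulator

`simulate_trace` builds the noiseless morphology of a coagulation run —

* baseline dissipation + linear drift,
* a raised-cosine pipetting bump immediately after the reagent event,
* a slow linear fibrin-attachment rise after the event,
* a logistic burst `A / (1 + exp(−(t − t_c)/w))` whose centre t_c is the
  ground-truth endpoint (the logistic's maximum-slope instant),
* a plateau (the logistic's own saturation) —

plus white Gaussian noise on the dissipation channel, and a frequency
channel `f = f₀ − k·(D(t) − D_baseline)`. Seeding is explicit and
mandatory; identical seeds give bitwise-identical traces.

Default study conditions (units in parentheses; all config-exposed):

| parameter | default | rationale |
|---|---|---|
| baseline_D | 5·10⁻⁴ | Kelvin–Voigt liquid term for plasma on the assumed crystal |
| drift_rate | 1·10⁻⁶/min | a settled chip, inside the 2·10⁻⁶/min acceptance gate |
| noise_sd | 2.5·10⁻⁶ | measured liquid-phase (PBS) stability; 1·10⁻⁶ in air |
| artifact | 5·10⁻⁶ over 8 s | pipetting fluctuation, inside the 10 s blanking |
| slow_rise_rate | 1·10⁻⁷/s | early fibrin attachment |
| sigmoid_amplitude | 1·10⁻⁴ | total burst ΔD, well above the noise floor as in real clots |
| sigmoid_width | 5 s | thrombin-burst sharpness |
| sample_interval | 2 s | one full 200-point sweep per dissipation sample |
| freq_coupling | 4·10⁶ Hz per unit D | inverse of the coagulation ratio 2.5·10⁻⁶ per 10 Hz |

Dissipation is stored dimensionless and conventionally displayed in 10⁻⁶
units.

What the simulator does **not** emulate: non-white instrument noise,
temperature excursions, bubble artifacts, non-uniform fibrin adhesion,
sample-to-sample biology (fibrinogen level, hematocrit), or reagent lot
effects. Tests passing on these traces therefore validate the *signal
pipeline* — that the implemented algorithms recover what the model
generates — not clinical performance on donor blood.

## Endpoint detection

* **Baseline gate**: straight-line fit to the last `window` (default 60 s)
  seconds before the first event; stable iff |slope| ≤ threshold (default
  2·10⁻⁶/min) and peak-to-peak residual ≤ threshold·window/60. With
  liquid-level noise the residual rule fails by construction (noise ptp
  exceeds 2·10⁻⁶), so on noisy traces the gate acts as a conservative QC
  flag rather than a hard stop.
* **Derivative**: moving-average smoothing (default 11 samples, odd)
  followed by `numpy.gradient` (central differences, one-sided ends).
* **Endpoint**: start = the named reagent event; end = global maximum of
  the smoothed derivative restricted to t > start + blanking (default
  10 s, which excludes the pipetting artifact); clot time = end − start.
  The global (not first-local) maximum is used because the thrombin burst
  produces the single dominant derivative peak. QC flags record baseline
  failure, a peak pinned at the search boundary, and a peak slope below
  5·σ̂/30 s (σ̂ a MAD-based noise estimate from first differences of the
  pre-start samples; 30 s a nominal burst rise time) — this gate keeps flat
  or anticoagulated traces from yielding spurious endpoints, and scales
  with the data so amplitude rescaling changes nothing.
* **Rigidity check**: ratio |ΔD| per 10 Hz of |Δf|; strictly below 1·10⁻⁶
  is Sauerbrey-rigid, at or above is viscoelastic (boundary counts as
  viscoelastic because the rigid criterion is "less than"). Coagulating
  plasma runs near 2.5·10⁻⁶ per 10 Hz — the reason dissipation, not
  frequency, is the traced quantity.

Detection is exactly time-shift equivariant, amplitude-scale invariant in
its end time, and monotone in blanking; all three are property-tested.

## Calibration

Ordinary least squares of reference times on device times (the device
reading is the point-of-care predictor). The reported statistic is the
**adjusted R²**, `1 − (1 − R²)(n − 1)/(n − 2)` (plain R² is logged
alongside); n ≥ 3 is required since the adjustment is undefined at n = 2.
The consistent clot-time prolongation from running at room temperature is
absorbed by the affine map — no separate temperature term. The intercept is
unconstrained. The simulated 12-run study (reference values 25–47 s, device
= 8·reference + 20 s, liquid-level noise) recovers the inverse map with
adjusted R² ≈ 0.999; this is a *structural analogue* of a clinical
cross-calibration, not a reproduction of any clinical value.

## Numerical and design choices

* −3 dB is exactly `20·log10(√2)`; half-power, not 3.0.
* Grid-maximum ties break to the lowest frequency.
* Writers emit shortest-round-trip float reprs: write → read → write is
  byte-identical, and all formats are plain CSV/YAML.
* Problem sizes throughout the suite (200-point sweeps, 100-replicate
  Monte-Carlo, 12-run calibration studies, 10⁴-sample noise statistics)
  were chosen as the smallest sizes at which the tested statistics are
  stable.

## Limitations

* Fibrinogen (FIB) and thrombin-time assays are out of scope.
* The fitter handles a single resonance; multi-mode or strongly asymmetric
  spectra are not supported.
* The acceptance of a trace rests on the morphology assumptions above;
  traces dominated by drift or bubbles will be flagged but not corrected.
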