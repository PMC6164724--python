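"""Plain-text file formats for traces, spectra, results and calibrations.

All formats are CSV with exact (shortest round-trip) float formatting, so a
write → read → write cycle is byte-identical.  Trace files embed reagent
events as ``# event,<label>,<time_s>`` comment lines ahead of the header.
Scenario files are flat ``key: value`` YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .calibrate import CalibrationModel
from .endpoint import ClotResult, DissipationTrace
from .errors import TraceFormatError
from .simulate import TraceScenario
from .sweep import MagnitudeSpectrum, QuadraturePoint

__all__ = [
    "read_trace", "write_trace",
    "read_result", "write_result",
    "read_pairs", "write_pairs",
    "read_spectrum", "write_spectrum",
    "read_sweep_record", "write_sweep_record",
    "read_scenario", "write_scenario",
    "read_calibration", "write_calibration",
]

TRACE_HEADER = "time_s,dissipation,frequency_hz"
RESULT_HEADER = "start_time_s,end_time_s,clot_time_s,peak_slope,blanking_used_s,start_event,flags"
PAIRS_HEADER = "device_time_s,reference_time_s"
SPECTRUM_HEADER = "freq_hz,magnitude_db"
SWEEP_HEADER = "freq_hz,v_dark_0,v_dark_90,v_cali_0,v_cali_90,v_mea_0,v_mea_90"
CALIBRATION_HEADER = "slope,intercept_s,r_squared_adj,n"


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_float(text: str, line: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise TraceFormatError(f"unparseable {what}: {text!r}", line) from None


def write_trace(trace: DissipationTrace, path) -> None:
    lines = []
    for label, t in trace.events:
        lines.append(f"# event,{label},{_fmt(t)}")
    lines.append(TRACE_HEADER)
    freq = trace.frequency
    for i, (t, d) in enumerate(zip(trace.times, trace.dissipation)):
        f = "" if freq is None else _fmt(freq[i])
        lines.append(f"{_fmt(t)},{_fmt(d)},{f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path) -> DissipationTrace:
    events: list[tuple[str, float]] = []
    times: list[float] = []
    diss: list[float] = []
    freq: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("event,"):
                parts = body.split(",")
                if len(parts) != 3:
                    raise TraceFormatError(f"malformed event line: {raw!r}", lineno)
                events.append((parts[1],
                               _parse_float(parts[2], lineno, "event time")))
            continue
        if not header_seen:
            if line != TRACE_HEADER:
                raise TraceFormatError(
                    f"expected header {TRACE_HEADER!r}, got {line!r}", lineno)
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise TraceFormatError(f"expected 3 columns, got {len(parts)}", lineno)
        t = _parse_float(parts[0], lineno, "time")
        if times and t <= times[-1]:
            raise TraceFormatError(
                f"non-monotone time: {t} follows {times[-1]}", lineno)
        times.append(t)
        diss.append(_parse_float(parts[1], lineno, "dissipation"))
        if parts[2] != "":
            freq.append(_parse_float(parts[2], lineno, "frequency"))
    if not header_seen or len(times) < 2:
        raise TraceFormatError("trace file has no data rows")
    if freq and len(freq) != len(times):
        raise TraceFormatError("frequency column is partially filled")
    for label, t in events:
        if not (times[0] <= t <= times[-1]):
            raise TraceFormatError(
                f"event {label!r} at t={t} s outside the sampled span")
    return DissipationTrace(
        times=np.array(times),
        dissipation=np.array(diss),
        frequency=np.array(freq) if freq else None,
        events=events,
    )


def write_result(result: ClotResult, path) -> None:
    flags = ";".join(result.qc_flags)
    row = ",".join([
        _fmt(result.start_time), _fmt(result.end_time), _fmt(result.clot_time),
        _fmt(result.peak_slope), _fmt(result.blanking_used),
        result.start_event, flags,
    ])
    Path(path).write_text(RESULT_HEADER + "\n" + row + "\n")


def read_result(path) -> ClotResult:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if len(lines) != 2 or lines[0] != RESULT_HEADER:
        raise TraceFormatError(f"expected header {RESULT_HEADER!r} and one row")
    parts = lines[1].split(",")
    if len(parts) != 7:
        raise TraceFormatError(f"expected 7 columns, got {len(parts)}", 2)
    return ClotResult(
        start_time=_parse_float(parts[0], 2, "start_time"),
        end_time=_parse_float(parts[1], 2, "end_time"),
        clot_time=_parse_float(parts[2], 2, "clot_time"),
        peak_slope=_parse_float(parts[3], 2, "peak_slope"),
        blanking_used=_parse_float(parts[4], 2, "blanking_used"),
        start_event=parts[5],
        qc_flags=tuple(f for f in parts[6].split(";") if f),
    )


def write_pairs(device_times, reference_times, path) -> None:
    lines = [PAIRS_HEADER]
    for d, r in zip(device_times, reference_times, strict=True):
        lines.append(f"{_fmt(d)},{_fmt(r)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pairs(path) -> tuple[np.ndarray, np.ndarray]:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines or lines[0] != PAIRS_HEADER:
        raise TraceFormatError(f"expected header {PAIRS_HEADER!r}")
    if len(lines) == 1:
        raise TraceFormatError("pairs file contains no data rows")
    dev, ref = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 2:
            raise TraceFormatError(f"expected 2 columns, got {len(parts)}", lineno)
        dev.append(_parse_float(parts[0], lineno, "device time"))
        ref.append(_parse_float(parts[1], lineno, "reference time"))
    return np.array(dev), np.array(ref)


def write_spectrum(spectrum: MagnitudeSpectrum, path) -> None:
    lines = [SPECTRUM_HEADER]
    for f, m in zip(spectrum.freqs, spectrum.magnitudes):
        lines.append(f"{_fmt(f)},{_fmt(m)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> MagnitudeSpectrum:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines or lines[0] != SPECTRUM_HEADER:
        raise TraceFormatError(f"expected header {SPECTRUM_HEADER!r}")
    freqs, mags = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 2:
            raise TraceFormatError(f"expected 2 columns, got {len(parts)}", lineno)
        freqs.append(_parse_float(parts[0], lineno, "frequency"))
        mags.append(_parse_float(parts[1], lineno, "magnitude"))
    return MagnitudeSpectrum(freqs=np.array(freqs), magnitudes=np.array(mags))


def write_sweep_record(points: list[QuadraturePoint], path) -> None:
    lines = [SWEEP_HEADER]
    for p in points:
        lines.append(",".join(_fmt(v) for v in (
            p.freq, p.v_dark_0, p.v_dark_90, p.v_cali_0, p.v_cali_90,
            p.v_mea_0, p.v_mea_90)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sweep_record(path) -> list[QuadraturePoint]:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines or lines[0] != SWEEP_HEADER:
        raise TraceFormatError(f"expected header {SWEEP_HEADER!r}")
    points = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 7:
            raise TraceFormatError(f"expected 7 columns, got {len(parts)}", lineno)
        vals = [_parse_float(p, lineno, "voltage") for p in parts]
        points.append(QuadraturePoint(*vals))
    return points


def write_scenario(scenario: TraceScenario, path) -> None:
    data = dataclasses.asdict(scenario)
    data["event_times"] = [[label, t] for label, t in scenario.event_times]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_scenario(path) -> TraceScenario:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise TraceFormatError("scenario file must be a flat key/value mapping")
    known = {f.name for f in dataclasses.fields(TraceScenario)}
    unknown = set(data) - known
    if unknown:
        raise TraceFormatError(f"unknown scenario fields: {sorted(unknown)}")
    if "event_times" in data:
        data["event_times"] = tuple(
            (str(label), float(t)) for label, t in data["event_times"])
    return TraceScenario(**data)


def write_calibration(model: CalibrationModel, path) -> None:
    row = ",".join([_fmt(model.slope), _fmt(model.intercept),
                    _fmt(model.r_squared), str(model.n)])
    Path(path).write_text(CALIBRATION_HEADER + "\n" + row + "\n")


def read_calibration(path) -> CalibrationModel:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if len(lines) != 2 or lines[0] != CALIBRATION_HEADER:
        raise TraceFormatError(f"expected header {CALIBRATION_HEADER!r} and one row")
    parts = lines[1].split(",")
    if len(parts) != 4:
        raise TraceFormatError(f"expected 4 columns, got {len(parts)}", 2)
    return CalibrationModel(
        slope=_parse_float(parts[0], 2, "slope"),
        intercept=_parse_float(parts[1], 2, "intercept"),
        r_squared=_parse_float(parts[2], 2, "r_squared"),
        n=int(parts[3]),
    )
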