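"""Exception taxonomy shared across the package."""


class QcmError(Exception):
    """Base class for all qcmcoag errors."""


class ParameterError(QcmError, ValueError):
    """A physical parameter is outside its admissible domain."""


class ScenarioError(QcmError, ValueError):
    """A trace scenario violates its invariants (events, timing, noise)."""


class CalibrationError(QcmError, ValueError):
    """The dark-corrected calibration vector is unusable (zero length)."""


class FitError(QcmError, RuntimeError):
    """Resonance fitting failed: no peak, or bandwidth outside the sweep."""


class NoClotError(QcmError, RuntimeError):
    """The dissipation trace never develops a positive slope (no clot)."""


class InsufficientBaselineError(QcmError, ValueError):
    """Not enough pre-event samples to assess baseline stability."""


class TraceFormatError(QcmError, ValueError):
    """A trace/result/pairs file is malformed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
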