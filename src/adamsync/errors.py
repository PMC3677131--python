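"""Exception types shared across the package."""


class AdamError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AdamError, ValueError):
    """Invalid argument or malformed data (exit code 3 in the CLI)."""


class DegenerateTimingError(AdamError, RuntimeError):
    """A simulated interval or timekeeper period became non-positive.

    Raised instead of clamping so that instability experiments (e.g. a
    phase-correction gain above 2) report divergence explicitly.  The
    offending cycle index, when known, is stored in ``cycle``.
    """

    def __init__(self, message: str, cycle: int | None = None):
        super().__init__(message)
        self.cycle = cycle
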