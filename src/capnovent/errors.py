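"""Exception hierarchy shared across the package."""


class CapnoventError(Exception):
    """Base class for package-specific failures."""


class ConfigError(CapnoventError, ValueError):
    """A configuration is internally inconsistent or out of range."""


class DomainError(CapnoventError, ValueError):
    """Inputs are syntactically valid but physiologically impossible."""


class NumericalError(CapnoventError, RuntimeError):
    """An iterative numerical procedure failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AliasingError(CapnoventError, ValueError):
    """Sample rate too low for the requested frequency content."""


class SingularFrequencyError(CapnoventError, ValueError):
    """A spectral estimate is undefined at a component frequency."""

    def __init__(self, frequency_hz: float):
        super().__init__(
            f"flow auto-spectrum below numeric floor at {frequency_hz:g} Hz"
        )
        self.frequency_hz = frequency_hz
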