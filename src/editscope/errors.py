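"""Exception hierarchy shared across the package."""


class EditscopeError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(EditscopeError, ValueError):
    """A caller-supplied argument is out of its documented domain."""


class ConfigError(EditscopeError, ValueError):
    """A simulation or classifier configuration is internally inconsistent."""


class FormatError(EditscopeError, ValueError):
    """A file does not conform to the documented dialect."""


class ValidationError(EditscopeError, ValueError):
    """Well-formed input with semantically invalid content (carries line info)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PlacementError(EditscopeError, RuntimeError):
    """Target sites could not be placed on the fixture without overlap."""


class EmptyProfileError(EditscopeError, ValueError):
    """A positional profile was requested from an empty junction set."""
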