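"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration errors are usage errors
(exit 2), format/data errors are exit 3, statistical precondition failures
are exit 4.
"""


class SigtomeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SigtomeError):
    """A simulation or run configuration violates its invariants."""


class FormatError(SigtomeError):
    """A file does not conform to its expected on-disk format.

    Carries the offending line number when one is known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DataError(SigtomeError):
    """Input values are structurally valid but semantically inconsistent."""


class StatError(SigtomeError):
    """A statistical precondition is not met (undefined quantity)."""
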