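"""Exception types shared across the package."""


class HeartError(Exception):
    """Base class for all package errors."""


class ValidationError(HeartError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(HeartError, IOError):
    """A file is missing or not in the expected on-disk format."""
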