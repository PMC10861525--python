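"""Exception types shared across the package."""


class RotwaveError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RotwaveError, ValueError):
    """A file does not match the expected on-disk schema.

    The message names the first offending field or file.
    """


class ValidationError(RotwaveError, ValueError):
    """In-memory data violates a container invariant (shape, finiteness...)."""
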