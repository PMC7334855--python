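"""Exception hierarchy shared across the package."""


class EpimarkError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EpimarkError, ValueError):
    """An input record or argument violates a documented invariant."""


class ParseError(EpimarkError, ValueError):
    """A file could not be parsed in the declared format."""
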