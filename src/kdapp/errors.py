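"""Exception hierarchy shared across the package."""


class KdappError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(KdappError):
    """The titration design is internally inconsistent (e.g. dilution factor <= 1)."""


class TableFormatError(KdappError):
    """An input table does not match the expected schema."""


class NormalizationError(KdappError):
    """Total-signal normalization cannot be applied (e.g. an all-zero channel)."""


class DomainError(KdappError):
    """An argument lies outside the mathematical domain of a model function."""
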