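"""Exception hierarchy shared across the package.

Every reader and operation raises a named error instead of silently
dropping data, so that pipeline failures are attributable to a specific
input defect.
"""


class BarcodeAuditError(Exception):
    """Base class for all package errors."""


class FormatError(BarcodeAuditError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(BarcodeAuditError):
    """Input parsed but violates a domain invariant (duplicates, bad symbols)."""


class UndefinedDistanceError(BarcodeAuditError):
    """A pairwise distance has no comparable sites."""


class SaturationWarning(UserWarning):
    """A K2P distance is undefined because the logarithm argument is <= 0.

    The distance is reported as +infinity; downstream clustering treats
    such pairs as always split.
    """


class GenerationError(BarcodeAuditError):
    """The synthetic-data generator could not satisfy its divergence
    targets within the retry budget."""
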