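"""Exception types shared across the pipeline."""


class NcrSpliceError(Exception):
    """Base class for all package errors."""


class UndefinedExpressionError(NcrSpliceError):
    """Relative expression requested for an undetected Ct value."""


class UndefinedProfileError(NcrSpliceError):
    """Variant percentages cannot be formed (all-zero or undefined inputs)."""


class BarcodeError(NcrSpliceError):
    """A TCGA-style barcode could not be parsed."""


class UnknownAcronymError(NcrSpliceError):
    """A cancer study acronym has no organ-cluster assignment."""


class DegenerateVarianceError(NcrSpliceError):
    """Paired differences have zero variance; the t statistic is undefined."""


class ValidationError(NcrSpliceError):
    """A simulation spec or configuration failed validation."""
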