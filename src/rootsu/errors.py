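"""Exception hierarchy shared across the package.

Validation-type errors map to CLI exit code 2, I/O errors to exit code 3.
"""


class RootsuError(Exception):
    """Base class for all package errors."""


class ValidationError(RootsuError):
    """Invalid parameters, malformed annotations, or broken preconditions."""


class InputOutputError(RootsuError):
    """Unreadable or unwritable files."""


class UnsupportedFormatError(InputOutputError):
    """A file format the reader cannot handle (e.g. multi-frame DICOM)."""


class DegenerateHistogramError(ValidationError):
    """Histogram with too few occupied levels for the requested split."""


class EmptyBodyError(ValidationError):
    """No foreground left where a body mask is required."""


class EmptyRoiError(ValidationError):
    """An ROI mask selects no pixels."""


class UndefinedRateError(ValidationError):
    """A missed-detection rate with no included slices."""


class UndefinedStatisticError(ValidationError):
    """A diagnostic ratio whose denominator is zero; names the statistic."""


class PhantomSpecError(ValidationError):
    """Infeasible phantom specification (e.g. a node that cannot be placed)."""
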