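"""Exception hierarchy.

Exit-code mapping used by the CLI: input/format/label/parameter problems
exit 2, classifier-gene coverage problems exit 3, degenerate models exit 4.
"""


class SubtypePredictError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 2


class FormatError(SubtypePredictError):
    """A file does not conform to its declared format."""


class DimensionError(FormatError):
    """Declared and actual matrix dimensions disagree."""


class UniquenessError(FormatError):
    """Duplicate gene or sample identifiers."""


class LabelError(SubtypePredictError):
    """A subtype label is not a leaf of the hierarchy."""


class ParameterError(SubtypePredictError):
    """A configuration value is outside its documented range."""


class BuildError(SubtypePredictError):
    """The labeled reference cannot support a reference model."""


class CoverageError(SubtypePredictError):
    """Too many classifier genes are missing from an input."""

    exit_code = 3


class DegenerateModelError(SubtypePredictError):
    """The data admit no usable model (zero variance, zero sigma, ...)."""

    exit_code = 4
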