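"""Exception hierarchy.

Analysis operations raise these rather than returning sentinel values, so
pipeline stages can exclude failed cells explicitly.
"""


class CdkSizeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CdkSizeError, ValueError):
    """Invalid or non-finite simulation / pipeline configuration."""


class SegmentationError(CdkSizeError):
    """Cell segmentation produced no usable mask; record is excluded."""


class SizingError(CdkSizeError, ValueError):
    """Cell does not fit in the requested image frame."""


class DegenerateCellError(CdkSizeError):
    """Mask too small/thin for the requested measurement."""


class QuantificationError(CdkSizeError):
    """Measurement failed (e.g. non-positive cytoplasmic baseline)."""


class InsufficientDataError(CdkSizeError, ValueError):
    """Too few points / bins / distinct doses for the requested fit."""


class NormalizationError(CdkSizeError, ValueError):
    """Reference for normalisation is empty or non-positive."""


class BinAlignmentError(CdkSizeError, ValueError):
    """Curves to be combined are not on identical bins."""


class SchemaError(CdkSizeError, ValueError):
    """Table does not match the CellRecord schema."""


class PipelineError(CdkSizeError):
    """A pipeline stage failed; the stage name is in the message."""
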