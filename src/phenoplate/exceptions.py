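"""Exception hierarchy for phenoplate.

All library errors derive from :class:`PhenoplateError` so callers can catch
everything from this package with a single except clause.
"""


class PhenoplateError(Exception):
    """Base class for all phenoplate errors."""


class ImageModeError(PhenoplateError):
    """Image has the wrong colour mode for the requested operation."""


class EmptyMaskError(PhenoplateError):
    """Segmentation found no objects (blank or contrast-free image)."""


class GeometryError(PhenoplateError):
    """Lattice fitting produced an unusable geometry (e.g. non-positive pitch)."""


class DimensionMismatchError(PhenoplateError):
    """Arrays or images that must share a shape do not."""


class NoBackgroundError(PhenoplateError):
    """No background pixels left to estimate a background level from."""


class CurveLengthError(PhenoplateError):
    """Growth curve or image series is too short for the requested fit."""


class SingularFitError(PhenoplateError):
    """A regression window is degenerate (no usable points or constant time)."""


class DegenerateGridError(PhenoplateError):
    """Fewer than three usable (or non-collinear) reference-grid colonies."""


class ZeroMedianError(PhenoplateError):
    """A row or column median is zero; division normalisation is undefined."""


class SampleSizeError(PhenoplateError):
    """Too few observations for the requested statistic."""


class UndefinedStatError(PhenoplateError):
    """Statistic undefined for this input (zero mean or zero variance)."""


class InsufficientDataError(PhenoplateError):
    """Not enough complete data points (e.g. no interior plate positions)."""


class SchemaError(PhenoplateError):
    """Input table is missing a required column or grouping key."""


class ConfigurationError(PhenoplateError):
    """Invalid simulation or analysis configuration."""
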