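"""Exception and warning hierarchy shared across biospat modules."""


class BiospatError(Exception):
    """Base class for all biospat errors."""


class SchemaError(BiospatError):
    """An input table is missing a required column or has a malformed header."""


class EmptyInputError(BiospatError):
    """An input contained no usable records."""


class GeometryError(BiospatError):
    """A vector input had the wrong geometry type or was unrepairable."""


class TreeParseError(BiospatError):
    """A newick string could not be parsed."""


class RasterFormatError(BiospatError):
    """A raster file could not be read or is inconsistent."""


class AlignmentError(BiospatError):
    """Rasters (or a raster and a reference grid) do not share geometry."""


class ConfigError(BiospatError):
    """Invalid configuration parameters."""


class DegenerateInputError(BiospatError):
    """Input is structurally valid but degenerate for the requested analysis
    (e.g. all dissimilarities equal, collinear spline samples, zero variance)."""


class UndefinedStatisticError(BiospatError):
    """A statistic is undefined for the given input (zero denominator etc.)."""


class BiospatWarning(UserWarning):
    """Base class for biospat warnings."""


class DroppedDataWarning(BiospatWarning):
    """Records, rows or cells were dropped during validation or assignment."""


class PremiseWarning(BiospatWarning):
    """A statistical premise of an analysis is violated; the analysis proceeds."""
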