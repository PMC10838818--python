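"""Exception hierarchy for hepavess.

Every error raised by the package derives from :class:`HepavessError` so
callers can catch toolkit failures without masking programming errors.
"""


class HepavessError(Exception):
    """Base class for all hepavess errors."""


class FormatError(HepavessError):
    """A file could not be read in a supported volume format."""


class DimensionalityError(HepavessError):
    """An image is not a 3D scalar volume."""


class GeometryError(HepavessError):
    """Two grids that must match (shape/spacing/extent) do not."""


class ParameterError(HepavessError):
    """An out-of-range or inconsistent parameter value."""


class SizeError(HepavessError):
    """A volume is too small for the requested operation."""


class SeedError(HepavessError):
    """A seed voxel is invalid (outside the mask / not found)."""


class SeedFailureError(SeedError):
    """The automatic seed heuristic found no bright structure.

    Callers should fall back to a manually supplied seed point.
    """


class EmptyInputError(HepavessError):
    """An operation that needs a nonempty mask/skeleton received an empty one."""


class DegenerateStatisticsError(HepavessError):
    """Statistics cannot be estimated (zero variance, constant input)."""


class UndefinedMetricError(HepavessError):
    """A metric is undefined for the given inputs (e.g. empty centerline)."""


class SampleSizeError(HepavessError):
    """Too few usable observations for a statistical test."""


class DataError(HepavessError):
    """Invalid or insufficient tabular/case data."""


class ValidationError(DataError):
    """A record failed validation (out-of-scale value, duplicate key)."""


class StateError(HepavessError):
    """An object is used before being put into the required state."""
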