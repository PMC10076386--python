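"""Exception hierarchy for torsometrics.

Every error raised by the library derives from :class:`TorsoMetricsError`
so callers (and the CLI) can distinguish tool errors from programming
errors.
"""


class TorsoMetricsError(Exception):
    """Base class for all torsometrics errors."""


class MeshError(TorsoMetricsError):
    """Problem with a surface mesh (I/O, validation, preprocessing)."""


class MeshParseError(MeshError):
    """A mesh file could not be parsed."""


class UnsupportedFormatError(MeshError):
    """Mesh file extension is not one of the supported formats."""


class EmptyMeshError(MeshError):
    """Mesh has no faces (possibly after cleaning)."""


class EmptyCropError(MeshError):
    """A Z-slab crop removed every face."""


class ROIError(TorsoMetricsError):
    """Problem with a region-of-interest query."""


class EmptyROIError(ROIError):
    """An ROI contains no mesh geometry."""


class InsufficientOverlapError(ROIError):
    """Too few usable slice levels in the paired-ROI Z overlap."""


class DegenerateContourError(TorsoMetricsError):
    """A cross-section contour encloses zero area."""


class NoNeckSectionError(TorsoMetricsError):
    """The neck section plane does not intersect the mesh."""


class UndefinedAngleError(TorsoMetricsError):
    """A landmark pair does not define the requested angle."""


class ConfigError(TorsoMetricsError):
    """Malformed or incomplete measurement configuration."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class RatingsError(TorsoMetricsError):
    """Invalid ratings matrix for reliability analysis."""


class UndefinedICCError(RatingsError):
    """ICC is undefined (zero total variance)."""


class SynthesisError(TorsoMetricsError):
    """Invalid synthetic-torso parameters."""


class ResolutionError(SynthesisError):
    """Mesh resolution too low to resolve a requested surface feature."""
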