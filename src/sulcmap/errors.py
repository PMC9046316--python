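"""Exception hierarchy for sulcmap.

All package errors derive from :class:`SulcmapError` so callers can catch
one base class; the subclasses mirror the failure modes of the pipeline
stages (file format, mesh integrity, array dimension, unit mixing,
delineation failures, bad generator/fit parameters).
"""


class SulcmapError(Exception):
    """Base class for all sulcmap errors."""


class FormatError(SulcmapError):
    """A file does not conform to its declared on-disk format."""


class IntegrityError(SulcmapError):
    """Data are structurally inconsistent (e.g. face index beyond vertex count)."""


class DimensionError(SulcmapError):
    """Array lengths/shapes do not match the mesh they are bound to."""


class UnitsError(SulcmapError):
    """Incompatible units were mixed at an operation boundary."""


class DelineationError(SulcmapError):
    """A retinotopic landmark (meridian border, confluence line) could not be found."""


class ParameterError(SulcmapError):
    """Invalid generator / fit / config parameters."""
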