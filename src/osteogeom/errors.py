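"""Exception hierarchy shared across the pipeline stages."""


class OsteogeomError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(OsteogeomError):
    """An STL file could not be parsed (truncated, malformed)."""


class ValidationError(OsteogeomError):
    """Invalid input data or configuration."""


class CleaningError(OsteogeomError):
    """Mesh repair failed (e.g. irreparable non-manifold topology)."""


class DecimationError(OsteogeomError):
    """Decimation could not reach the target or broke watertightness."""


class OrientationError(OsteogeomError):
    """Degenerate landmarks prevent frame construction."""


class SlicingError(OsteogeomError):
    """A cross-section could not be extracted or classified."""


class SamplingError(OsteogeomError):
    """Equiangular semilandmark sampling failed for a ray."""


class GeometryError(OsteogeomError):
    """Invalid polygon input to a geometric computation."""


class NoClosedFormError(OsteogeomError):
    """Analytic ground truth is not available for the requested quantity."""
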