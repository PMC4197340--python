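"""Exception hierarchy shared across the pipeline."""


class TarsokinError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(TarsokinError):
    """Input geometry does not determine the requested primitive
    (collinear points, coincident landmarks, zero-length axes ...)."""


class ContractViolationError(TarsokinError):
    """An input violates a documented invariant (e.g. a non-orthonormal
    rotation passed where a rigid transform is required)."""


class ProjectionError(TarsokinError):
    """A point or mesh cannot be projected (behind the source, outside
    the viewing frustum, ray parallel to the detector)."""


class NoEdgesError(TarsokinError):
    """Edge detection found no edges (constant or empty image)."""


class NoContactError(TarsokinError):
    """A contact event could not be detected in the supplied window."""


class SynchronizationError(TarsokinError):
    """Fluoroscopic and force-plate streams do not overlap in time."""


class MeshParseError(TarsokinError):
    """A mesh file could not be parsed."""


class ConfigError(TarsokinError):
    """Pipeline configuration failed validation."""
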