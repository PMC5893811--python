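"""Exception hierarchy for the laa_stasis package."""


class LAAStasisError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(LAAStasisError, ValueError):
    """An anatomy specification violates its invariants."""


class GeometryError(LAAStasisError):
    """A geometric model is malformed (open or self-intersecting boundary)."""


class ResolutionError(LAAStasisError, ValueError):
    """Requested mesh size is too coarse to resolve the geometry."""


class MeshQualityError(LAAStasisError):
    """Generated mesh falls below the configured quality threshold."""


class TaggingError(LAAStasisError):
    """Mesh facet or cell tags are missing, unknown or inconsistent."""


class RegionError(LAAStasisError):
    """A mesh region required by an operation is empty or missing."""


class InterpolationError(LAAStasisError):
    """A sample point lies outside the mesh."""


class SolverError(LAAStasisError):
    """Linear or nonlinear solve failed to converge."""


class StabilityError(LAAStasisError):
    """A stability constraint (CFL) was violated."""


class SchemeError(LAAStasisError):
    """A discrete scheme violated one of its guaranteed bounds."""


class FieldError(LAAStasisError, ValueError):
    """A field violates its admissible range."""


class PairingError(LAAStasisError):
    """A healthy/AF condition pair required for comparison is incomplete."""


class ConfigError(LAAStasisError, ValueError):
    """Experiment configuration is invalid."""


class PipelineError(LAAStasisError):
    """A pipeline stage is missing an input it requires."""
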