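"""Exception hierarchy for the pipshape pipeline.

Every error raised on a per-seed basis carries enough context (file, plane,
curve) to be reported against that seed without losing the rest of a run.
"""


class PipshapeError(Exception):
    """Base class for all pipeline errors."""


class MeshFormatError(PipshapeError):
    """A mesh file could not be parsed in the requested format."""


class MeshValidationError(PipshapeError):
    """A mesh violates a structural invariant (empty after cleaning, ...)."""


class GeometryError(PipshapeError):
    """A geometric computation is degenerate (zero volume, empty section)."""


class UnsupportedInputError(PipshapeError):
    """The input is valid but outside the operation's supported domain."""


class StarShapeError(GeometryError):
    """A planar curve is not star-shaped about the adjusted origin."""


class OriginNotAdjustedError(PipshapeError):
    """A descriptor was requested from a spectrum whose first harmonic has
    not been driven to zero by the origin-adjustment step."""


class ContractError(PipshapeError):
    """Mismatched shapes / lengths between paired inputs."""


class ParameterError(PipshapeError):
    """A parameter is outside its documented range."""
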