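"""Exception hierarchy for radcs."""


class RadcsError(Exception):
    """Base class for all radcs errors."""


class MeshFormatError(RadcsError):
    """A mesh file could not be parsed in the requested format."""


class ValidationError(RadcsError, ValueError):
    """An input violated a documented precondition or invariant."""


class DegenerateGeometryError(RadcsError):
    """Point set is coincident/collinear; moments of inertia are rank deficient."""


class AmbiguousAxisError(RadcsError):
    """The two smallest inertia eigenvalues are (nearly) equal; no unique long axis."""


class OrientationAmbiguousError(RadcsError):
    """The candidate axis is exactly perpendicular to the global up hint."""


class PlacementError(RadcsError):
    """Coordinate-system placement failed; carries the stage that failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class GenerationError(RadcsError):
    """Synthetic mesh generation produced invalid geometry."""


class DegenerateDesignError(RadcsError):
    """A statistical design lacks the variation required to fit the model."""
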