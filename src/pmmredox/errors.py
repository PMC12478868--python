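"""Exception hierarchy.

Every error raised on a user-facing contract derives from PmmRedoxError so
callers can catch the package's failures in one place.
"""


class PmmRedoxError(Exception):
    """Base class for all package errors."""


class SchemaError(PmmRedoxError):
    """A quantum-center (or config) file violates the documented schema."""


class ChargeSumError(SchemaError):
    """Per-state ESP charges do not sum to the species' total charge."""


class GeometryError(PmmRedoxError):
    """Invalid or degenerate geometry (mismatched atoms, collinearity...)."""


class FrameError(PmmRedoxError):
    """Invalid environment frame or frame-stream operation."""


class UnsupportedFormatError(FrameError):
    """Trajectory format not supported; message lists supported formats."""


class ClashError(PmmRedoxError):
    """A perturbing charge sits inside the clash radius of the quantum
    center — usually a sign of mis-masked QC atoms."""


class EstimatorError(PmmRedoxError):
    """Free-energy estimator precondition violated (empty ensemble,
    degenerate exponentials, non-positive electron count...)."""
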