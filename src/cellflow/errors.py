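"""Exception hierarchy for cellflow.

All package-specific failures derive from :class:`CellflowError` so callers can
catch simulation problems without masking programming errors.
"""


class CellflowError(Exception):
    """Base class for all cellflow errors."""


class MeshFormatError(CellflowError):
    """Malformed nodes/triangles file (reported with the offending line number)."""


class TopologyError(CellflowError):
    """Mesh is not a closed 2-manifold (non-manifold edge, duplicate triangle, ...)."""


class OrientationError(CellflowError):
    """Triangle winding is inconsistent and cannot be repaired by a global flip."""


class DegenerateGeometryError(CellflowError):
    """Collinear triangle, zero-length edge or vanishing normal."""


class StabilityError(CellflowError):
    """Parameter combination outside the stable regime (e.g. LBM tau <= 1/2)."""


class NumericalBlowupError(CellflowError):
    """NaN/Inf detected during time integration."""


class PenetrationError(CellflowError):
    """A repulsive interaction found an unresolved overlap (distance <= 0)."""


class PackingError(CellflowError):
    """Random seeding could not place the requested number of cells."""


class CheckpointError(CellflowError):
    """Unreadable, truncated or version-incompatible checkpoint file."""


class ConfigError(CellflowError):
    """Invalid or incomplete simulation configuration."""
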