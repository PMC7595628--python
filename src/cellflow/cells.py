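"""Cell templates and movable cell instances, with per-cell observables.

A :class:`CellType` holds the immutable relaxed-state template: the mesh as
read from file (or generated), optionally rescaled per axis, plus the elastic
coefficients and the node mass. Instantiating a :class:`Cell` copies the
template geometry into a movable mesh (rotated and translated into place)
while sharing the frozen relaxed quantities -- rigid motions do not change
the stress-free state, so many cells can share one template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .elastic import (
    ElasticCoefficients,
    accumulate_elastic_forces,
    bending_forces_mesh,
    global_area_forces,
    local_area_forces_mesh,
    stretching_forces,
    volume_forces,
)
from .errors import PackingError
from .mesh import Mesh, build_mesh, read_mesh_files

__all__ = [
    "CellType",
    "Cell",
    "create_cell_type",
    "instantiate_cell",
    "cell_metrics",
    "cell_kinematics",
    "elastic_forces_report",
    "suggest_coupling_gamma",
    "seed_cells_random",
]

_MODULI = {
    "stretching": lambda m, c: stretching_forces(m, c.ks),
    "bending": lambda m, c: bending_forces_mesh(m, c.kb),
    "local_area": lambda m, c: local_area_forces_mesh(m, c.kal),
    "global_area": lambda m, c: global_area_forces(m, c.kag),
    "volume": lambda m, c: volume_forces(m, c.kv),
}


@dataclass(frozen=True)
class CellType:
    """Immutable relaxed-state template shared by all cells of one kind."""

    template_mesh: Mesh
    coefficients: ElasticCoefficients
    resize: np.ndarray
    mass_per_node: float

    @classmethod
    def from_arrays(cls, positions, faces, coefficients, resize=(1.0, 1.0, 1.0),
                    mass_per_node: float = 1.0) -> "CellType":
        """Build a template from raw geometry.

        ``resize`` scales the template componentwise about its centroid
        *before* the relaxed quantities are frozen, so elasticity is measured
        relative to the resized shape.
        """
        resize = np.asarray(resize, dtype=float)
        if resize.shape != (3,) or np.any(resize <= 0):
            raise ValueError("resize must be 3 positive scale factors")
        positions = np.asarray(positions, dtype=float)
        centroid = positions.mean(axis=0)
        scaled = centroid + (positions - centroid) * resize
        mesh = build_mesh(scaled, faces, mass=mass_per_node, movable=False)
        mesh.positions.setflags(write=False)
        return cls(mesh, coefficients, resize, float(mass_per_node))


def create_cell_type(nodes_path, triangles_path, resize=(1.0, 1.0, 1.0),
                     coefficients: ElasticCoefficients | None = None,
                     mass_per_node: float = 1.0, index_base: int = 0) -> CellType:
    """Read ``nodes.dat``/``triangles.dat`` and build a :class:`CellType`."""
    positions, faces = read_mesh_files(nodes_path, triangles_path, index_base)
    return CellType.from_arrays(
        positions, faces, coefficients or ElasticCoefficients(),
        resize=resize, mass_per_node=mass_per_node,
    )


@dataclass
class Cell:
    """A movable instance of a :class:`CellType` with its own positions."""

    cell_type: CellType
    mesh: Mesh
    particle_id_offset: int = 0
    label: str = ""
    external_forces: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_points

    def elastic_forces(self) -> np.ndarray:
        return accumulate_elastic_forces(self.mesh, self.cell_type.coefficients)

    # -- named observables (mesh analysis methods) -------------------------
    def min_edge_length(self) -> float:
        return float(self.mesh.edge_lengths().min())

    def max_edge_length(self) -> float:
        return float(self.mesh.edge_lengths().max())

    def aver_edge_length(self) -> float:
        return float(self.mesh.edge_lengths().mean())

    def surface(self) -> float:
        return self.mesh.surface()

    def volume(self) -> float:
        return self.mesh.volume()

    def diameter(self) -> float:
        """Largest pairwise node distance (convex-hull diameter)."""
        p = self.mesh.positions
        # hull vertices suffice for the farthest pair; meshes here are small
        d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max()))

    def get_origin(self) -> np.ndarray:
        return self.mesh.positions.mean(axis=0)

    def get_approx_origin(self) -> np.ndarray:
        """Mean of the six axis-extremal nodes (cheap origin estimate)."""
        p = self.mesh.positions
        idx = np.concatenate([np.argmin(p, axis=0), np.argmax(p, axis=0)])
        return p[idx].mean(axis=0)

    def get_velocity(self) -> np.ndarray:
        return self.mesh.velocities.mean(axis=0)

    def pos_bounds(self):
        p = self.mesh.positions
        lo = p.min(axis=0)
        hi = p.max(axis=0)
        return (lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])

    # -- re-seeding support -------------------------------------------------
    def save_nodes(self) -> np.ndarray:
        """Snapshot of the current node positions."""
        return self.mesh.positions.copy()

    def restore_nodes(self, snapshot, new_origin=None, rotation=None) -> None:
        """Replace node positions from a snapshot, optionally re-placed.

        ``rotation`` (extrinsic X-Y-Z Euler angles, radians) is applied about
        the snapshot centroid, then the centroid is moved to ``new_origin``.
        Velocities are reset to zero; the relaxed state is untouched.
        """
        snapshot = np.asarray(snapshot, dtype=float)
        if snapshot.shape != self.mesh.positions.shape:
            raise ValueError(
                f"snapshot has shape {snapshot.shape}, expected "
                f"{self.mesh.positions.shape}"
            )
        pos = snapshot.copy()
        centroid = pos.mean(axis=0)
        if rotation is not None:
            R = Rotation.from_euler("xyz", rotation).as_matrix()
            pos = (pos - centroid) @ R.T + centroid
        if new_origin is not None:
            pos += np.asarray(new_origin, dtype=float) - centroid
        self.mesh.positions[:] = pos
        self.mesh.velocities[:] = 0.0


def instantiate_cell(cell_type: CellType, origin=(0.0, 0.0, 0.0),
                     rotation=(0.0, 0.0, 0.0), particle_id_offset: int = 0,
                     label: str = "") -> Cell:
    """Place a movable copy of the template: rotate (extrinsic X-Y-Z Euler
    angles, radians) about the template centroid, then move the centroid to
    ``origin``. Velocities start at zero."""
    mesh = cell_type.template_mesh.copy(movable=True)
    mesh.positions = mesh.positions.copy()
    mesh.positions.setflags(write=True)
    centroid = mesh.centroid()
    R = Rotation.from_euler("xyz", rotation).as_matrix()
    mesh.positions[:] = (mesh.positions - centroid) @ R.T + np.asarray(origin, float)
    return Cell(cell_type, mesh, particle_id_offset, label)


# ---------------------------------------------------------------------------
# observable records


def cell_metrics(cell: Cell) -> dict:
    """Geometry observables: edge-length statistics, surface, volume, diameter."""
    lengths = cell.mesh.edge_lengths()
    return {
        "min_edge_length": float(lengths.min()),
        "max_edge_length": float(lengths.max()),
        "aver_edge_length": float(lengths.mean()),
        "surface": cell.surface(),
        "volume": cell.volume(),
        "diameter": cell.diameter(),
    }


def cell_kinematics(cell: Cell) -> dict:
    """Location/dynamics observables: origin, approximate origin, mean
    velocity and axis-aligned position bounds."""
    return {
        "origin": cell.get_origin(),
        "approx_origin": cell.get_approx_origin(),
        "velocity": cell.get_velocity(),
        "pos_bounds": cell.pos_bounds(),
    }


def elastic_forces_report(cell: Cell, which=("stretching", "bending", "local_area",
                                             "global_area", "volume")) -> dict:
    """Per-node force vectors and magnitudes for the requested moduli.

    Returns ``{name: (N, 3) array, name + "_magnitude": (N,) array}`` fields
    ready to attach to VTK point data for local-stress inspection.
    """
    which = tuple(which)
    if not which:
        raise ValueError("at least one modulus must be requested")
    unknown = set(which) - set(_MODULI)
    if unknown:
        raise ValueError(f"unknown moduli {sorted(unknown)}; choose from "
                         f"{sorted(_MODULI)}")
    report = {}
    for name in which:
        f = _MODULI[name](cell.mesh, cell.cell_type.coefficients)
        report[name] = f
        report[name + "_magnitude"] = np.linalg.norm(f, axis=1)
    return report


def suggest_coupling_gamma(cell: Cell, fluid_viscosity: float,
                           grid_spacing: float = 1.0) -> float:
    """Heuristic fluid-friction coefficient for this cell's mesh density.

    Returns ``gamma = fluid_viscosity * mean_edge_length`` (dynamic viscosity
    in lattice units), a Stokes-like drag scale per node: it grows linearly
    with viscosity and shrinks for finer meshes so the total drag on the cell
    stays roughly discretization independent. ``grid_spacing`` enters only
    through the unit of viscosity (default 1 lattice spacing). A proper
    calibration of gamma against drag experiments is outside this package;
    always overridable by an explicit value in the configuration.
    """
    if fluid_viscosity <= 0 or grid_spacing <= 0:
        raise ValueError("viscosity and grid spacing must be positive")
    return float(fluid_viscosity * grid_spacing * cell.aver_edge_length() / grid_spacing)


# ---------------------------------------------------------------------------
# random seeding


def seed_cells_random(region, cell_type: CellType, n: int, min_gap: float,
                      rng_seed: int, max_attempts: int = 10000) -> list[Cell]:
    """Place ``n`` cells uniformly at random inside an axis-aligned box.

    ``region`` is ``(lo, hi)`` corner pair. Rejection sampling enforces
    pairwise centroid distances >= ``min_gap`` and keeps every cell's
    bounding box inside the region. Deterministic for a given ``rng_seed``.
    """
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    rng = np.random.default_rng(rng_seed)
    tmpl = cell_type.template_mesh.positions
    half = (tmpl.max(axis=0) - tmpl.min(axis=0)) / 2.0
    if np.any(hi - lo <= 2 * half):
        raise PackingError("region smaller than one cell's bounding box")
    cells: list[Cell] = []
    centers: list[np.ndarray] = []
    attempts = 0
    offset = 0
    while len(cells) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {len(cells)}/{n} cells in {max_attempts} attempts; "
                "lower n or min_gap, or enlarge the region"
            )
        attempts += 1
        c = lo + half + rng.random(3) * (hi - lo - 2 * half)
        if any(np.linalg.norm(c - prev) < min_gap for prev in centers):
            continue
        angles = rng.uniform(0, 2 * np.pi, size=3)
        cells.append(instantiate_cell(cell_type, origin=c, rotation=angles,
                                      particle_id_offset=offset,
                                      label=f"cell{len(cells)}"))
        offset += cell_type.template_mesh.n_points
        centers.append(c)
    return cells
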