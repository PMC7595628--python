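"""Time integration: velocity Verlet particles + lattice fluid substeps.

One integration step advances the coupled system as

1. conservative per-node forces (elastic + wall + cell-cell + self-cell),
2. friction coupling, evaluated once per step and deposited to the fluid,
3. ``lbm_substep_ratio`` fluid collide/stream/bounce-back substeps,
4. velocity-Verlet update of all movable mesh points.

The friction force is held constant through the Verlet update (explicit
treatment of the velocity-dependent force), so the particle impulse matches
the force deposited to the fluid exactly and total momentum is conserved to
rounding in a periodic boundary-free system. Conservative forces get the
standard two-evaluation Verlet treatment and are cached between steps.

Cells are kept inside the periodic box by rigid re-wrapping: when a cell's
centroid leaves the box it is shifted back by whole box lengths, which
preserves the mesh geometry exactly (individual nodes may protrude slightly
across the boundary; the fluid coupling wraps node positions itself).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from .cells import Cell
from .coupling import CouplingParams, couple_cell_to_fluid
from .errors import CheckpointError, ConfigError, NumericalBlowupError
from .fluid import BoundaryShape, FluidLattice
from .interactions import (
    MembraneCollisionParams,
    SoftSphereParams,
    cell_cell_forces,
    neighbor_exclusions,
    self_cell_forces,
    wall_forces,
)

__all__ = [
    "SimulationConfig",
    "Simulation",
    "compute_total_forces",
    "velocity_verlet_step",
    "run",
    "total_momentum",
    "checkpoint",
    "restore_checkpoint",
]

_CHECKPOINT_VERSION = 1


@dataclass
class SimulationConfig:
    """Run-level parameters.

    ``box`` is the periodic domain extent (length units); with the
    recommended scaling the units are micrometres, microseconds and 1e-15 kg
    and the fluid lattice spacing is 1. ``dt`` is the particle (MD) time
    step; the fluid advances ``lbm_substep_ratio`` substeps of ``dt /
    lbm_substep_ratio`` per MD step.
    """

    box: tuple = (16.0, 16.0, 16.0)
    dt: float = 1.0
    lbm_substep_ratio: int = 1
    rng_seed: int = 0
    output_every: int = 100
    time_scale: float = 1.0
    length_scale: float = 1.0
    mass_scale: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.lbm_substep_ratio < 1:
            raise ConfigError("lbm_substep_ratio must be >= 1")
        if np.any(np.asarray(self.box) <= 0):
            raise ConfigError("box extents must be positive")


@dataclass
class Simulation:
    """Complete simulation state: fluid lattice, cells, obstacles,
    interaction registry and the step counter."""

    config: SimulationConfig
    lattice: FluidLattice
    cells: list = field(default_factory=list)
    boundaries: list = field(default_factory=list)
    coupling: CouplingParams | None = None
    wall_params: SoftSphereParams | None = None
    cell_cell_params: MembraneCollisionParams | None = None
    self_params: SoftSphereParams | None = None
    self_exclusion_depth: int = 2
    step_counter: int = 0

    def __post_init__(self):
        box = np.asarray(self.config.box, dtype=float)
        lat = np.array(self.lattice.shape) * self.lattice.spacing
        if not np.allclose(box, lat):
            raise ConfigError(
                f"box {tuple(box)} does not match lattice extent {tuple(lat)}"
            )
        self.rng = np.random.default_rng(self.config.rng_seed)
        self._cons_forces = None
        self._exclusions = {}
        if self.coupling is not None and self.cells:
            m = min(c.mesh.masses.min() for c in self.cells)
            self.coupling.check_stability(self.config.dt, float(m))

    # -- forces -------------------------------------------------------------
    def _self_exclusions(self, cell: Cell):
        key = id(cell.cell_type)
        if key not in self._exclusions:
            self._exclusions[key] = neighbor_exclusions(
                cell.cell_type.template_mesh, self.self_exclusion_depth
            )
        return self._exclusions[key]

    def conservative_forces(self) -> list:
        """Elastic + wall + cell-cell + self-cell forces per cell."""
        forces = [cell.elastic_forces() for cell in self.cells]
        for k, cell in enumerate(self.cells):
            if self.wall_params is not None and self.boundaries:
                forces[k] += wall_forces(cell, self.boundaries, self.wall_params)
            if self.self_params is not None:
                forces[k] += self_cell_forces(
                    cell, self.self_params, self._self_exclusions(cell)
                )
        if self.cell_cell_params is not None:
            for a in range(len(self.cells)):
                for b in range(a + 1, len(self.cells)):
                    fa, fb = cell_cell_forces(
                        self.cells[a], self.cells[b], self.cell_cell_params
                    )
                    forces[a] += fa
                    forces[b] += fb
        return forces

    def coupling_forces(self, deposit: bool = True) -> list:
        """Friction forces per cell; optionally deposit the reaction."""
        if self.coupling is None or self.coupling.gamma == 0.0:
            return [np.zeros_like(c.mesh.positions) for c in self.cells]
        out = []
        for cell in self.cells:
            if deposit:
                out.append(couple_cell_to_fluid(cell, self.lattice, self.coupling))
            else:
                u = self.lattice.interpolate_velocity(
                    np.mod(cell.mesh.positions,
                           np.array(self.lattice.shape) * self.lattice.spacing)
                )
                out.append(self.coupling.gamma * (u - cell.mesh.velocities))
        return out

    def compute_total_forces(self) -> list:
        """Per-node total forces (Newtonian driving force) for every cell.

        The fluid reaction of the coupling term is queued in the lattice
        force accumulator for the next fluid step.
        """
        forces = self.conservative_forces()
        for k, fc in enumerate(self.coupling_forces(deposit=True)):
            forces[k] = forces[k] + fc
        for k, cell in enumerate(self.cells):
            if cell.external_forces is not None:
                forces[k] = forces[k] + cell.external_forces
        return forces

    # -- stepping -----------------------------------------------------------
    def step(self) -> None:
        """One coupled MD + fluid step (velocity Verlet for the particles)."""
        dt = self.config.dt
        if self._cons_forces is None:
            self._cons_forces = self.conservative_forces()
        fc = self.coupling_forces(deposit=True)
        held = []  # coupling + external, constant through the step
        for k, cell in enumerate(self.cells):
            h = fc[k]
            if cell.external_forces is not None:
                h = h + cell.external_forces
            held.append(h)
            m = cell.mesh.masses[:, None]
            F = self._cons_forces[k] + h
            cell.mesh.positions += cell.mesh.velocities * dt + F / (2.0 * m) * dt * dt
        self._rewrap_cells()

        sub = self.config.lbm_substep_ratio
        for _ in range(sub):
            self.lattice.step()

        new_cons = self.conservative_forces()
        for k, cell in enumerate(self.cells):
            m = cell.mesh.masses[:, None]
            cell.mesh.velocities += (
                (0.5 * (self._cons_forces[k] + new_cons[k]) + held[k]) / m * dt
            )
            if not np.all(np.isfinite(cell.mesh.positions)):
                raise NumericalBlowupError(
                    f"non-finite positions in cell '{cell.label}' at step "
                    f"{self.step_counter}"
                )
        self._cons_forces = new_cons
        self.step_counter += 1

    def _rewrap_cells(self) -> None:
        box = np.asarray(self.config.box, dtype=float)
        for cell in self.cells:
            shift = np.floor(cell.get_origin() / box) * box
            if shift.any():
                cell.mesh.positions -= shift

    def run(self, n_steps: int, callbacks=()) -> None:
        """Advance ``n_steps`` steps, firing callbacks at the output cadence.

        Each callback is called as ``callback(sim)`` whenever
        ``step_counter % output_every == 0`` after a step. Composable:
        ``run(a); run(b)`` is bit-identical to ``run(a + b)``.
        """
        for _ in range(int(n_steps)):
            self.step()
            if self.step_counter % self.config.output_every == 0:
                for cb in callbacks:
                    cb(self)

    # -- observables ----------------------------------------------------------
    def total_momentum(self) -> np.ndarray:
        """Fluid momentum plus particle momentum (mass * velocity summed)."""
        p = self.lattice.fluid_momentum()
        for cell in self.cells:
            p = p + (cell.mesh.masses[:, None] * cell.mesh.velocities).sum(axis=0)
        return p


# ---------------------------------------------------------------------------
# functional wrappers


def compute_total_forces(sim: Simulation) -> list:
    return sim.compute_total_forces()


def velocity_verlet_step(sim: Simulation) -> None:
    sim.step()


def run(sim: Simulation, n_steps: int, callbacks=()) -> None:
    sim.run(n_steps, callbacks)


def total_momentum(sim: Simulation) -> np.ndarray:
    return sim.total_momentum()


# ---------------------------------------------------------------------------
# checkpointing


def checkpoint(sim: Simulation, path) -> None:
    """Serialize the full simulation state (positions, velocities, fluid
    populations, step counter); restoring reproduces the subsequent
    trajectory bit-identically."""
    state = {"version": _CHECKPOINT_VERSION, "sim": sim}
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def restore_checkpoint(path) -> Simulation:
    try:
        with open(path, "rb") as fh:
            state = pickle.load(fh)
    except (OSError, pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if not isinstance(state, dict) or "version" not in state:
        raise CheckpointError(f"{path} is not a cellflow checkpoint")
    if state["version"] != _CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {state['version']} != supported "
            f"{_CHECKPOINT_VERSION}"
        )
    return state["sim"]
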