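"""Dissipative fluid-membrane coupling.

Each mesh point feels a friction force ``F = gamma * (u - v)`` penalizing the
mismatch between the local fluid velocity ``u`` (trilinearly interpolated at
the point) and the point velocity ``v``; the opposite force is deposited onto
the surrounding fluid nodes with the same weights, so momentum is exchanged
exactly. This purely dissipative two-way coupling approximates the no-slip
condition on the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cells import Cell
from .fluid import FluidLattice

__all__ = [
    "CouplingParams",
    "friction_force",
    "couple_cell_to_fluid",
    "fluid_force_on_cell",
]


@dataclass(frozen=True)
class CouplingParams:
    """Friction coefficient gamma (mass/time units), >= 0."""

    gamma: float

    def __post_init__(self):
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise ValueError(f"gamma must be finite and >= 0, got {self.gamma}")

    def check_stability(self, dt: float, mass: float) -> None:
        """Warn when the explicit friction update is close to unstable."""
        if self.gamma * dt / mass >= 1.0:
            warnings.warn(
                f"gamma*dt/m = {self.gamma * dt / mass:.3g} >= 1: explicit "
                "friction coupling may be unstable; reduce dt or gamma",
                stacklevel=2,
            )


def friction_force(u, v, gamma: float):
    """``gamma * (u - v)``; antisymmetric under swapping u and v."""
    return gamma * (np.asarray(u, dtype=float) - np.asarray(v, dtype=float))


def couple_cell_to_fluid(cell: Cell, lattice: FluidLattice,
                         params: CouplingParams) -> np.ndarray:
    """Two-way friction exchange for one cell.

    Returns the per-node forces applied to the mesh points and deposits the
    opposite forces into the lattice force accumulator (consumed by the next
    collision). The two sides balance exactly per node.
    """
    pos = np.mod(cell.mesh.positions, np.array(lattice.shape) * lattice.spacing)
    u = lattice.interpolate_velocity(pos)
    forces = friction_force(u, cell.mesh.velocities, params.gamma)
    lattice.deposit_force(pos, -forces)
    return forces


def fluid_force_on_cell(cell: Cell, lattice: FluidLattice,
                        params: CouplingParams) -> np.ndarray:
    """Net fluid force observable: sum of gamma*(u(x_i) - v_i) over nodes.

    Pure observable -- no force is deposited and no state changes.
    """
    pos = np.mod(cell.mesh.positions, np.array(lattice.shape) * lattice.spacing)
    u = lattice.interpolate_velocity(pos)
    return friction_force(u, cell.mesh.velocities, params.gamma).sum(axis=0)
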