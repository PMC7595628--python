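"""D3Q19 lattice-Boltzmann fluid on a periodic box with bounce-back walls.

Single-relaxation-time (BGK) collision with Guo forcing, streaming by
periodic shifts, and full-way bounce-back at solid nodes. Lattice nodes sit
at integer multiples of the spacing ``dx``; with full-way bounce-back the
effective no-slip wall lies half a spacing beyond the last fluid node.

The lattice exchanges momentum with immersed particles through trilinear
velocity interpolation and force deposition on the eight surrounding nodes,
using identical weights so the deposited force sums exactly to the applied
force.
"""

from __future__ import annotations

import numpy as np

from .errors import NumericalBlowupError, StabilityError

__all__ = [
    "STENCIL_VELOCITIES",
    "STENCIL_WEIGHTS",
    "FluidLattice",
    "BoundaryShape",
    "WallPlane",
    "Rhomboid",
    "Cylinder",
    "create_lattice",
    "step_fluid",
    "add_boundary",
    "macroscopic",
    "interpolate_velocity",
    "deposit_force",
]

# D3Q19 stencil: rest + 6 face neighbours + 12 edge diagonals
STENCIL_VELOCITIES = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.intp,
)

STENCIL_WEIGHTS = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)

_OPPOSITE = np.array(
    [
        int(np.flatnonzero((STENCIL_VELOCITIES == -c).all(axis=1))[0])
        for c in STENCIL_VELOCITIES
    ],
    dtype=np.intp,
)


# ---------------------------------------------------------------------------
# boundary shapes


class BoundaryShape:
    """Solid obstacle with a total inside/outside predicate.

    Subclasses provide ``contains`` (solid test), ``signed_distance``
    (positive in the fluid, negative inside the solid) and
    ``outward_normal`` (unit vector pointing away from the solid)."""

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.signed_distance(points) <= 0.0

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def outward_normal(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class WallPlane(BoundaryShape):
    """Half-space wall: solid where ``normal . x <= offset``."""

    def __init__(self, normal, offset: float):
        n = np.asarray(normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        self.offset = float(offset) / np.linalg.norm(n)

    def signed_distance(self, points):
        return np.atleast_2d(points) @ self.normal - self.offset

    def outward_normal(self, points):
        pts = np.atleast_2d(points)
        return np.broadcast_to(self.normal, pts.shape).copy()


class Rhomboid(BoundaryShape):
    """Solid parallelepiped given by a corner and three edge vectors.

    Containment works for any edge vectors; exact signed distances (needed
    for soft-sphere wall forces) require the edge vectors to be mutually
    orthogonal, which covers boxes in arbitrary orientation.
    """

    def __init__(self, corner, a, b, c):
        self.corner = np.asarray(corner, dtype=float)
        self.vectors = np.column_stack([a, b, c]).astype(float)
        if np.linalg.det(self.vectors) == 0:
            raise ValueError("rhomboid edge vectors must be independent")
        self.sizes = np.linalg.norm(self.vectors, axis=0)
        self._axes = self.vectors / self.sizes  # columns are unit edges
        gram = self._axes.T @ self._axes
        self._orthogonal = np.allclose(gram, np.eye(3), atol=1e-12)

    def _local(self, points):
        return (np.atleast_2d(points) - self.corner) @ self._axes

    def contains(self, points):
        lam = (np.atleast_2d(points) - self.corner) @ np.linalg.inv(self.vectors).T
        return np.all((lam >= 0.0) & (lam <= 1.0), axis=1)

    def _require_orthogonal(self):
        if not self._orthogonal:
            raise ValueError(
                "signed distance to a non-orthogonal rhomboid is not supported"
            )

    def signed_distance(self, points):
        self._require_orthogonal()
        q = self._local(points)
        lo = np.maximum(np.maximum(-q, q - self.sizes), 0.0)
        outside = np.linalg.norm(lo, axis=1)
        inside = np.minimum(q, self.sizes - q).min(axis=1)
        return np.where(outside > 0.0, outside, -inside)

    def outward_normal(self, points):
        self._require_orthogonal()
        q = self._local(points)
        closest = np.clip(q, 0.0, self.sizes)
        delta = q - closest
        dist = np.linalg.norm(delta, axis=1)
        normals = np.zeros_like(q)
        out = dist > 0.0
        normals[out] = delta[out] / dist[out, None]
        if np.any(~out):  # inside: nearest face normal
            inside = ~out
            face_d = np.stack([q[inside], self.sizes - q[inside]], axis=2)  # (M,3,2)
            flat = face_d.reshape(inside.sum(), 6)
            k = np.argmin(flat, axis=1)
            local_n = np.zeros((inside.sum(), 3))
            local_n[np.arange(inside.sum()), k // 2] = np.where(k % 2 == 0, -1.0, 1.0)
            normals[inside] = local_n
        return normals @ self._axes.T


class Cylinder(BoundaryShape):
    """Solid cylinder: ``center``, unit ``axis``, ``radius``; infinite when
    ``half_length`` is None, capped otherwise."""

    def __init__(self, center, axis, radius: float, half_length: float | None = None):
        self.center = np.asarray(center, dtype=float)
        a = np.asarray(axis, dtype=float)
        self.axis = a / np.linalg.norm(a)
        self.radius = float(radius)
        self.half_length = None if half_length is None else float(half_length)

    def _decompose(self, points):
        rel = np.atleast_2d(points) - self.center
        z = rel @ self.axis
        radial = rel - z[:, None] * self.axis
        r = np.linalg.norm(radial, axis=1)
        return z, radial, r

    def signed_distance(self, points):
        z, _, r = self._decompose(points)
        dr = r - self.radius
        if self.half_length is None:
            return dr
        dz = np.abs(z) - self.half_length
        outside = np.linalg.norm(
            np.stack([np.maximum(dr, 0.0), np.maximum(dz, 0.0)], axis=1), axis=1
        )
        return np.where((dr > 0) | (dz > 0), outside, np.maximum(dr, dz))

    def outward_normal(self, points):
        z, radial, r = self._decompose(points)
        rdir = np.where(r[:, None] > 0, radial / np.where(r[:, None] == 0, 1.0, r[:, None]),
                        np.array([1.0, 0.0, 0.0]))
        if self.half_length is None:
            return rdir
        dr = r - self.radius
        dz = np.abs(z) - self.half_length
        cap = dz > dr
        n = np.where(cap[:, None], np.sign(z)[:, None] * self.axis, rdir)
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norms == 0, 1.0, norms)


# ---------------------------------------------------------------------------
# the lattice


class FluidLattice:
    """D3Q19 populations plus boundary mask and per-node force accumulator.

    Parameters are physical in the chosen unit system (the recommended
    scaling is micrometres / microseconds / 1e-15 kg, where ``dx = dt = 1``).
    ``viscosity`` is kinematic; the BGK relaxation time follows as
    ``tau = viscosity / (cs^2 dt) + 1/2`` and must exceed 1/2.
    """

    def __init__(self, shape, spacing: float = 1.0, dt: float = 1.0,
                 viscosity: float = 1.0 / 6.0, density: float = 1.0):
        self.shape = tuple(int(s) for s in shape)
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be three positive integers")
        self.spacing = float(spacing)
        self.dt = float(dt)
        self.viscosity = float(viscosity)
        self.density = float(density)
        c = self.spacing / self.dt
        self.cs2 = c * c / 3.0
        self.tau = self.viscosity / (self.cs2 * self.dt) + 0.5
        if not self.tau > 0.5:
            raise StabilityError(
                f"tau = {self.tau} <= 1/2: viscosity={viscosity}, "
                f"spacing={spacing}, dt={dt} is not a stable combination"
            )
        self._c = STENCIL_VELOCITIES.astype(float) * c  # physical velocities
        self.populations = np.empty((19,) + self.shape)
        self.boundary_mask = np.zeros(self.shape, dtype=bool)
        self.force_field = np.zeros(self.shape + (3,))  # force per node
        self.body_force = np.zeros(3)  # force density, applied every step
        self.set_equilibrium()

    # -- setup -------------------------------------------------------------
    def set_equilibrium(self, velocity=(0.0, 0.0, 0.0), density=None):
        """Initialize all populations to equilibrium at a uniform state."""
        rho = self.density if density is None else float(density)
        u = np.zeros((3,) + self.shape) + np.asarray(velocity, float)[:, None, None, None]
        self.populations[:] = self._equilibrium(np.full(self.shape, rho), u)

    def add_boundary(self, shape: BoundaryShape) -> None:
        """Flag lattice nodes inside ``shape`` as solid (union semantics)."""
        self.boundary_mask |= shape.contains(self.node_positions()).reshape(self.shape)

    def node_positions(self) -> np.ndarray:
        grid = np.indices(self.shape).reshape(3, -1).T * self.spacing
        return grid

    # -- moments -----------------------------------------------------------
    def _equilibrium(self, rho, u):
        cu = np.tensordot(self._c, u, axes=(1, 0)) / self.cs2  # (19, ...)
        usq = np.einsum("a...,a...->...", u, u) / self.cs2
        feq = rho * (1.0 + cu + 0.5 * cu * cu - 0.5 * usq)
        return STENCIL_WEIGHTS[(slice(None),) + (None,) * 3] * feq

    def macroscopic(self):
        """Density and velocity fields (half-force corrected; zero in solid)."""
        f = self.populations
        rho = f.sum(axis=0)
        mom = np.tensordot(self._c, f, axes=(0, 0))
        phi = self._force_density()
        u = (mom + 0.5 * self.dt * phi) / rho
        u[:, self.boundary_mask] = 0.0
        return rho, np.moveaxis(u, 0, -1)

    def velocity_field(self) -> np.ndarray:
        return self.macroscopic()[1]

    def total_mass(self) -> float:
        return float(self.populations.sum()) * self.spacing**3

    def fluid_momentum(self) -> np.ndarray:
        """Total momentum of the populations (bare first moment)."""
        mom = np.tensordot(self._c, self.populations, axes=(0, 0))
        return mom.reshape(3, -1).sum(axis=1) * self.spacing**3

    def _force_density(self):
        phi = np.moveaxis(self.force_field, -1, 0) / self.spacing**3
        phi = phi + self.body_force[:, None, None, None]
        phi[:, self.boundary_mask] = 0.0
        return phi

    # -- dynamics ----------------------------------------------------------
    def step(self) -> None:
        """One collide (BGK + Guo forcing) / stream / bounce-back cycle.

        The deposited ``force_field`` is consumed by this collision and
        cleared; the constant ``body_force`` acts every step.
        """
        f = self.populations
        fluid = ~self.boundary_mask
        rho = f.sum(axis=0)
        mom = np.tensordot(self._c, f, axes=(0, 0))
        phi = self._force_density()
        u = (mom + 0.5 * self.dt * phi) / rho
        feq = self._equilibrium(rho, u)
        cphi = np.tensordot(self._c, phi, axes=(1, 0))
        cu = np.tensordot(self._c, u, axes=(1, 0))
        uphi = np.einsum("a...,a...->...", u, phi)
        guo = (1.0 - 0.5 / self.tau) * STENCIL_WEIGHTS[(slice(None),) + (None,) * 3] * (
            (cphi - uphi) / self.cs2 + cu * cphi / self.cs2**2
        )
        post = f - (f - feq) / self.tau + self.dt * guo
        f[:, fluid] = post[:, fluid]
        if not np.all(np.isfinite(f)):
            raise NumericalBlowupError(
                "NaN/Inf in populations: reduce dt, force or increase viscosity"
            )
        # stream
        for i in range(1, 19):
            ci = STENCIL_VELOCITIES[i]
            f[i] = np.roll(f[i], shift=tuple(ci), axis=(0, 1, 2))
        # full-way bounce-back on solid nodes
        if self.boundary_mask.any():
            solid = self.boundary_mask
            incoming = f[:, solid]
            f[:, solid] = incoming[_OPPOSITE]
        self.force_field[:] = 0.0

    # -- coupling support ----------------------------------------------------
    def _trilinear(self, x):
        """Periodic trilinear corner indices and weights for points ``x``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite interpolation point")
        xl = x / self.spacing
        base = np.floor(xl).astype(np.intp)
        frac = xl - base
        shape = np.array(self.shape)
        idx = np.empty((len(x), 8, 3), dtype=np.intp)
        w = np.empty((len(x), 8))
        corner = 0
        for dx_ in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    off = np.array([dx_, dy, dz])
                    idx[:, corner] = (base + off) % shape
                    fw = np.where(off == 1, frac, 1.0 - frac)
                    w[:, corner] = fw.prod(axis=1)
                    corner += 1
        return idx, w

    def interpolate_velocity(self, x) -> np.ndarray:
        """Fluid velocity at arbitrary points (trilinear, periodic wrap).

        Exact for fields that are affine in the node values; a point exactly
        on a node returns that node's velocity.
        """
        u = self.velocity_field()
        idx, w = self._trilinear(x)
        vals = u[idx[..., 0], idx[..., 1], idx[..., 2]]  # (M, 8, 3)
        out = np.einsum("mc,mcd->md", w, vals)
        return out[0] if np.asarray(x).ndim == 1 else out

    def deposit_force(self, x, F) -> None:
        """Spread point forces onto the 8 surrounding nodes.

        Uses the interpolation weights, so the deposited total equals the
        applied force exactly; consumed by the next collision.
        """
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        F2 = np.atleast_2d(np.asarray(F, dtype=float))
        idx, w = self._trilinear(x2)
        contrib = w[:, :, None] * F2[:, None, :]  # (M, 8, 3)
        np.add.at(
            self.force_field,
            (idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()),
            contrib.reshape(-1, 3),
        )


# ---------------------------------------------------------------------------
# functional wrappers


def create_lattice(shape, spacing=1.0, dt=1.0, viscosity=1.0 / 6.0,
                   density=1.0) -> FluidLattice:
    return FluidLattice(shape, spacing, dt, viscosity, density)


def step_fluid(lattice: FluidLattice) -> None:
    lattice.step()


def add_boundary(lattice: FluidLattice, shape: BoundaryShape) -> None:
    lattice.add_boundary(shape)


def macroscopic(lattice: FluidLattice):
    return lattice.macroscopic()


def interpolate_velocity(lattice: FluidLattice, x):
    return lattice.interpolate_velocity(x)


def deposit_force(lattice: FluidLattice, x, F):
    lattice.deposit_force(x, F)
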