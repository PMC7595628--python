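"""Short-range repulsive interactions: cell-wall, cell-cell and self-cell.

Walls repel membrane nodes through a power-law soft-sphere potential
``V(d) = a * d**-n`` acting below a cutoff ``d_cut``. Distinct cells repel
each other through a bounded sigmoid membrane-collision potential
``V(d) = a / (1 + exp(n*d))`` whose direction uses the outward membrane
normals at the two nodes, with a crossing test that reverses the push when
the membranes have interpenetrated. Self-cell contacts reuse the soft-sphere
law between non-neighbouring nodes of one mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cells import Cell
from .errors import DegenerateGeometryError, PenetrationError
from .fluid import BoundaryShape
from .mesh import Mesh, triangle_normals

__all__ = [
    "SoftSphereParams",
    "MembraneCollisionParams",
    "soft_sphere",
    "membrane_collision",
    "wall_forces",
    "node_outward_normal",
    "node_outward_normals",
    "cell_cell_forces",
    "neighbor_exclusions",
    "self_cell_forces",
]


@dataclass(frozen=True)
class SoftSphereParams:
    """Power-law repulsion ``a * d**-n`` below ``d_cut`` (zero beyond)."""

    a: float
    n: float
    d_cut: float

    def __post_init__(self):
        if self.a <= 0 or self.d_cut <= 0:
            raise ValueError("a and d_cut must be positive")


@dataclass(frozen=True)
class MembraneCollisionParams:
    """Sigmoid repulsion ``a / (1 + exp(n*d))`` below ``d_cut``; bounded by a."""

    a: float
    n: float
    d_cut: float

    def __post_init__(self):
        if self.a <= 0 or self.n <= 0 or self.d_cut <= 0:
            raise ValueError("a, n and d_cut must be positive")


def soft_sphere(d, params: SoftSphereParams):
    """Potential and (repulsive) force magnitude of the soft-sphere law.

    Returns ``(a * d**-n, n * a * d**-(n+1))`` for ``0 < d < d_cut`` and
    exact zeros at and beyond the cutoff. ``d <= 0`` signals an unresolved
    overlap and raises :class:`PenetrationError`.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise PenetrationError("soft-sphere distance <= 0: unresolved overlap")
    active = d < params.d_cut
    V = np.where(active, params.a * d ** -params.n, 0.0)
    F = np.where(active, params.n * params.a * d ** -(params.n + 1.0), 0.0)
    if V.ndim == 0:
        return float(V), float(F)
    return V, F


def membrane_collision(d, params: MembraneCollisionParams):
    """Potential and force magnitude of the membrane-collision law.

    ``V = a / (1 + exp(n*d))`` is bounded by ``a`` (``a/2`` at contact) and
    strictly decreasing; the force magnitude is ``a*n*exp(n*d)/(1+exp(n*d))^2``.
    Both vanish at and beyond ``d_cut``.
    """
    d = np.asarray(d, dtype=float)
    active = d < params.d_cut
    e = np.exp(np.minimum(params.n * d, 700.0))
    V = np.where(active, params.a / (1.0 + e), 0.0)
    F = np.where(active, params.a * params.n * e / (1.0 + e) ** 2, 0.0)
    if V.ndim == 0:
        return float(V), float(F)
    return V, F


# ---------------------------------------------------------------------------
# walls


def wall_forces(cell: Cell, boundaries, params: SoftSphereParams) -> np.ndarray:
    """Per-node soft-sphere wall forces from a list of boundary shapes.

    Each node closer than ``d_cut`` to a shape's surface is pushed along the
    shape's outward normal; contributions from several shapes add. A node at
    zero or negative distance (inside a solid) raises
    :class:`PenetrationError` naming the node.
    """
    pos = cell.mesh.positions
    forces = np.zeros_like(pos)
    for shape in boundaries:
        d = np.asarray(shape.signed_distance(pos))
        if np.any(d <= 0):
            node = int(np.argmin(d))
            raise PenetrationError(
                f"node {node} of cell '{cell.label}' is inside a "
                f"{type(shape).__name__} (distance {d[node]:.3g})"
            )
        close = d < params.d_cut
        if not close.any():
            continue
        _, mag = soft_sphere(d[close], params)
        forces[close] += mag[:, None] * shape.outward_normal(pos[close])
    return forces


# ---------------------------------------------------------------------------
# membrane normals


def node_outward_normals(mesh: Mesh) -> np.ndarray:
    """Area-weighted outward unit normal at every node.

    The unnormalized triangle normals (magnitude twice the area) of all
    incident triangles are summed and the result normalized.
    """
    tn = triangle_normals(mesh.positions, mesh.triangles)
    acc = np.zeros_like(mesh.positions)
    for v in range(3):
        np.add.at(acc, mesh.triangles[:, v], tn)
    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms == 0):
        raise DegenerateGeometryError("vanishing node normal (pathological fold)")
    return acc / norms[:, None]


def node_outward_normal(mesh: Mesh, node_id: int) -> np.ndarray:
    return node_outward_normals(mesh)[node_id]


# ---------------------------------------------------------------------------
# cell-cell membrane collision


def cell_cell_forces(cellA: Cell, cellB: Cell,
                     params: MembraneCollisionParams):
    """Membrane-collision forces between two distinct cells.

    For each node pair (i in A, j in B) with distance below ``d_cut`` the
    force magnitude follows the sigmoid law; node i is pushed along
    ``-(n_i - n_j)/|n_i - n_j|`` (against its own outward normal, away from
    the other membrane) and node j oppositely, so Newton's third law holds
    pairwise. When the crossing test finds the membranes interpenetrated --
    each node on the inner side of the other ((x_j - x_i) . n_i < 0 and
    (x_i - x_j) . n_j < 0) -- the push reverses to drive the membranes back
    through each other. Near-parallel normals fall back to the
    centre-to-centre line.

    Returns per-node force arrays ``(forces_on_A, forces_on_B)``.
    """
    if cellA is cellB:
        raise ValueError("cell_cell_forces needs two distinct cells")
    pA, pB = cellA.mesh.positions, cellB.mesh.positions
    fA = np.zeros_like(pA)
    fB = np.zeros_like(pB)
    pairs = cKDTree(pA).query_ball_tree(cKDTree(pB), params.d_cut)
    ii = [i for i, js in enumerate(pairs) for _ in js]
    jj = [j for js in pairs for j in js]
    if not ii:
        return fA, fB
    ii = np.asarray(ii, dtype=np.intp)
    jj = np.asarray(jj, dtype=np.intp)
    diff = pB[jj] - pA[ii]
    d = np.linalg.norm(diff, axis=1)
    _, mag = membrane_collision(d, params)
    nA = node_outward_normals(cellA.mesh)[ii]
    nB = node_outward_normals(cellB.mesh)[jj]
    direction = nA - nB
    dn = np.linalg.norm(direction, axis=1)
    parallel = dn < 1e-8
    if parallel.any():
        cc = cellB.get_origin() - cellA.get_origin()
        ccn = np.linalg.norm(cc)
        fallback = cc / ccn if ccn > 0 else np.array([1.0, 0.0, 0.0])
        direction[parallel] = fallback
        dn[parallel] = 1.0
    direction = direction / dn[:, None]
    crossed = (np.einsum("ij,ij->i", diff, nA) < 0) & (
        np.einsum("ij,ij->i", -diff, nB) < 0
    )
    sign = np.where(crossed, 1.0, -1.0)
    f = (sign * mag)[:, None] * direction
    np.add.at(fA, ii, f)
    np.add.at(fB, jj, -f)
    return fA, fB


# ---------------------------------------------------------------------------
# self-cell repulsion


def neighbor_exclusions(mesh: Mesh, depth: int = 2) -> set:
    """Node pairs within graph distance ``depth`` along mesh edges.

    Returned as a set of ordered tuples (i < j); these pairs are skipped by
    the self-cell repulsion so nearest mesh neighbours never repel.
    """
    if not 1 <= depth <= 5:
        raise ValueError("exclusion depth must be in 1..5")
    adjacency = [[] for _ in range(mesh.n_points)]
    for a, b in mesh.edges.tolist():
        adjacency[a].append(b)
        adjacency[b].append(a)
    excluded = set()
    for start in range(mesh.n_points):
        frontier = {start}
        seen = {start}
        for _ in range(depth):
            frontier = {nb for v in frontier for nb in adjacency[v]} - seen
            seen |= frontier
        for v in seen - {start}:
            if start < v:
                excluded.add((start, v))
    return excluded


def self_cell_forces(cell: Cell, params: SoftSphereParams,
                     exclusions: set) -> np.ndarray:
    """Soft-sphere repulsion between non-neighbouring nodes of one mesh.

    Acts along the connecting line, pairwise antisymmetric, so the total over
    the mesh is zero. Coincident non-excluded nodes raise
    :class:`PenetrationError`.
    """
    pos = cell.mesh.positions
    forces = np.zeros_like(pos)
    pairs = cKDTree(pos).query_pairs(params.d_cut, output_type="ndarray")
    if len(pairs) == 0:
        return forces
    keep = np.array(
        [(int(i), int(j)) not in exclusions for i, j in pairs], dtype=bool
    )
    pairs = pairs[keep]
    if len(pairs) == 0:
        return forces
    diff = pos[pairs[:, 1]] - pos[pairs[:, 0]]
    d = np.linalg.norm(diff, axis=1)
    if np.any(d == 0):
        raise PenetrationError("coincident non-excluded nodes in self-cell contact")
    _, mag = soft_sphere(d, params)
    f = (mag / d)[:, None] * diff  # push i away from j
    np.add.at(forces, pairs[:, 0], -f)
    np.add.at(forces, pairs[:, 1], f)
    return forces
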