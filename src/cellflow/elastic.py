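"""The five membrane elastic moduli of the spring-network cell model.

A membrane mesh resists deformation through five force laws, each controlled
by one non-negative coefficient (lattice units):

* stretching ``ks`` -- nonlinear (neo-Hookean) springs on edges,
* bending ``kb`` -- restores the dihedral angle between adjacent triangles,
* local area ``kal`` -- restores each triangle's area,
* global area ``kag`` -- restores the total surface area,
* volume ``kv`` -- restores the enclosed volume.

Every law is force-free (per-node contributions of one term sum to zero over
the mesh), and stretching/local-area are torque-free as well. The bending
force is the negative gradient of the quadratic angle energy
``kb/2 * (theta - theta0)**2`` under the dihedral convention of
:mod:`cellflow.mesh` (flat = pi, convex < pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .mesh import Mesh, angle_sizes, triangle_normals

__all__ = [
    "ElasticCoefficients",
    "neo_hookean_kappa",
    "stretching_force_pair",
    "bending_forces",
    "local_area_forces",
    "stretching_forces",
    "bending_forces_mesh",
    "local_area_forces_mesh",
    "global_area_forces",
    "volume_forces",
    "accumulate_elastic_forces",
]


@dataclass(frozen=True)
class ElasticCoefficients:
    """Membrane moduli; any coefficient may be zero to disable that term."""

    ks: float = 0.0
    kb: float = 0.0
    kal: float = 0.0
    kag: float = 0.0
    kv: float = 0.0

    def __post_init__(self):
        for name in ("ks", "kb", "kal", "kag", "kv"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def neo_hookean_kappa(lam):
    """Neo-Hookean nonlinearity kappa(lambda) = (l^0.5 + l^-2.5)/(l + l^-3).

    ``kappa(1) == 1`` and ``kappa(lam) == kappa(1/lam)``; it softens the
    linear spring response at large stretch ratios. Accepts arrays.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio lambda must be > 0")
    out = (lam**0.5 + lam**-2.5) / (lam + lam**-3)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# pairwise / per-element reference forms


def stretching_force_pair(posA, posB, l0: float, ks: float):
    """Stretching forces on the two endpoints of one edge.

    Force on A is ``ks * kappa(l/l0) * (l - l0) * p_AB`` with ``p_AB`` the
    unit vector from A to B; B gets the opposite force. Positive prolongation
    pulls the endpoints together.
    """
    posA = np.asarray(posA, dtype=float)
    posB = np.asarray(posB, dtype=float)
    d = posB - posA
    l = np.linalg.norm(d)
    if l == 0.0:
        raise DegenerateGeometryError("coincident edge endpoints")
    fA = ks * neo_hookean_kappa(l / l0) * (l - l0) * (d / l)
    return fA, -fA


def bending_forces(posA, posB, posC, posD, theta0: float, kb: float):
    """Bending forces on the quad (A, B, C, D) of two triangles sharing AB.

    The four forces sum to zero identically and equal the negative gradient
    of ``kb/2 * (theta - theta0)**2`` with respect to the four positions.
    """
    A, B, C, D = (np.asarray(p, dtype=float) for p in (posA, posB, posC, posD))
    theta = angle_sizes(np.array([A, B, C, D]), np.array([[0, 1, 2, 3]]))[0]
    dth = theta - theta0
    nc = np.cross(A - C, B - C)
    nd = np.cross(B - D, A - D)
    nc2 = float(nc @ nc)
    nd2 = float(nd @ nd)
    lab = float(np.linalg.norm(B - A))
    fC = -kb * dth * lab * nc / nc2
    fD = -kb * dth * lab * nd / nd2
    fA = kb * dth * (
        nc / nc2 * float((A - B) @ (C - B)) / lab
        + nd / nd2 * float((A - B) @ (D - B)) / lab
    )
    fB = kb * dth * (
        nc / nc2 * float((A - B) @ (A - C)) / lab
        + nd / nd2 * float((A - B) @ (A - D)) / lab
    )
    return fA, fB, fC, fD


def local_area_forces(posA, posB, posC, S0: float, kal: float):
    """Local-area forces on one triangle.

    Each vertex X receives ``kal * (S - S0) / (ta^2 + tb^2 + tc^2) * (T - X)``
    with T the centroid and ``t*`` the vertex-centroid distances; the three
    forces sum to zero and carry no torque.
    """
    A, B, C = (np.asarray(p, dtype=float) for p in (posA, posB, posC))
    n = np.cross(A - C, B - C)
    S = 0.5 * np.linalg.norm(n)
    if S == 0.0:
        raise DegenerateGeometryError("degenerate triangle")
    T = (A + B + C) / 3.0
    t2 = float((T - A) @ (T - A) + (T - B) @ (T - B) + (T - C) @ (T - C))
    fac = kal * (S - S0) / t2
    return fac * (T - A), fac * (T - B), fac * (T - C)


# ---------------------------------------------------------------------------
# whole-mesh vectorized passes


def stretching_forces(mesh: Mesh, ks: float) -> np.ndarray:
    """Per-node stretching forces summed over all edges."""
    forces = np.zeros_like(mesh.positions)
    if ks == 0.0:
        return forces
    a = mesh.edges[:, 0]
    b = mesh.edges[:, 1]
    d = mesh.positions[b] - mesh.positions[a]
    l = np.linalg.norm(d, axis=1)
    if np.any(l == 0.0):
        raise DegenerateGeometryError("coincident edge endpoints")
    lam = l / mesh.relaxed_edge_lengths
    mag = ks * neo_hookean_kappa(lam) * (l - mesh.relaxed_edge_lengths) / l
    f = mag[:, None] * d
    np.add.at(forces, a, f)
    np.add.at(forces, b, -f)
    return forces


def bending_forces_mesh(mesh: Mesh, kb: float) -> np.ndarray:
    """Per-node bending forces summed over all angles."""
    forces = np.zeros_like(mesh.positions)
    if kb == 0.0:
        return forces
    q = mesh.angles
    A = mesh.positions[q[:, 0]]
    B = mesh.positions[q[:, 1]]
    C = mesh.positions[q[:, 2]]
    D = mesh.positions[q[:, 3]]
    dth = angle_sizes(mesh.positions, q) - mesh.relaxed_angles
    nc = np.cross(A - C, B - C)
    nd = np.cross(B - D, A - D)
    nc2 = np.einsum("ij,ij->i", nc, nc)
    nd2 = np.einsum("ij,ij->i", nd, nd)
    ab = B - A
    lab = np.linalg.norm(ab, axis=1)
    gc = nc / nc2[:, None] * (kb * dth * lab)[:, None]
    gd = nd / nd2[:, None] * (kb * dth * lab)[:, None]
    wAc = np.einsum("ij,ij->i", A - B, C - B) / (lab * lab)
    wAd = np.einsum("ij,ij->i", A - B, D - B) / (lab * lab)
    wBc = np.einsum("ij,ij->i", A - B, A - C) / (lab * lab)
    wBd = np.einsum("ij,ij->i", A - B, A - D) / (lab * lab)
    np.add.at(forces, q[:, 0], gc * wAc[:, None] + gd * wAd[:, None])
    np.add.at(forces, q[:, 1], gc * wBc[:, None] + gd * wBd[:, None])
    np.add.at(forces, q[:, 2], -gc)
    np.add.at(forces, q[:, 3], -gd)
    return forces


def _local_area_terms(mesh: Mesh, dS, weight):
    """Centroid-directed per-vertex forces shared by the two area moduli."""
    forces = np.zeros_like(mesh.positions)
    tri = mesh.triangles
    p = mesh.positions[tri]
    T = p.mean(axis=1)
    r = T[:, None, :] - p  # (F, 3 vertices, 3)
    t2 = np.einsum("fvj,fvj->f", r, r)
    fac = (dS * weight / t2)[:, None, None]
    contrib = fac * r
    for v in range(3):
        np.add.at(forces, tri[:, v], contrib[:, v])
    return forces


def local_area_forces_mesh(mesh: Mesh, kal: float) -> np.ndarray:
    """Per-node local-area forces summed over all triangles."""
    if kal == 0.0:
        return np.zeros_like(mesh.positions)
    S = 0.5 * np.linalg.norm(triangle_normals(mesh.positions, mesh.triangles), axis=1)
    return _local_area_terms(mesh, S - mesh.relaxed_areas, kal)


def global_area_forces(mesh: Mesh, kag: float) -> np.ndarray:
    """Per-node global-area forces.

    Same centroid-directed distribution as the local term, but driven by the
    total surface deviation and weighted by each triangle's share of the
    relaxed surface.
    """
    if kag == 0.0:
        return np.zeros_like(mesh.positions)
    S = 0.5 * np.linalg.norm(triangle_normals(mesh.positions, mesh.triangles), axis=1)
    dS_cell = float(np.sum(S)) - mesh.relaxed_surface
    return _local_area_terms(mesh, np.full_like(S, dS_cell), kag * S / mesh.relaxed_surface)


def volume_forces(mesh: Mesh, kv: float) -> np.ndarray:
    """Per-node volume-restoring forces.

    Each triangle contributes ``-kv * (dV/V0) * S * n_hat`` along its outward
    unit normal, split equally among its vertices: inflation pushes every
    face inward, deflation outward. Scaling by the triangle area prevents
    triangle annihilation.
    """
    forces = np.zeros_like(mesh.positions)
    if kv == 0.0:
        return forces
    n = triangle_normals(mesh.positions, mesh.triangles)  # |n| = 2S, outward
    dV = mesh.volume() - mesh.relaxed_volume
    contrib = (-kv * dV / mesh.relaxed_volume / 6.0) * n  # (S * n_hat) / 3 = n / 6
    for v in range(3):
        np.add.at(forces, mesh.triangles[:, v], contrib)
    return forces


def accumulate_elastic_forces(mesh: Mesh, coeffs: ElasticCoefficients) -> np.ndarray:
    """Total per-node elastic force from all five moduli.

    Organized as the single angle-centric pass: every angle owns exactly one
    edge (its shared edge -- angle ``q`` is built on edge ``q``), and
    ``mesh.triangle_owner`` assigns every triangle to exactly one angle, so
    evaluating stretching per owned edge, bending per angle and local area
    per owned triangle touches each element exactly once and is identical to
    the standalone per-modulus passes below. The two global terms (surface,
    volume) follow as whole-mesh passes.
    """
    total = stretching_forces(mesh, coeffs.ks)
    total += bending_forces_mesh(mesh, coeffs.kb)
    total += local_area_forces_mesh(mesh, coeffs.kal)
    total += global_area_forces(mesh, coeffs.kag)
    total += volume_forces(mesh, coeffs.kv)
    return total
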