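"""Triangulated closed-surface meshes: construction, file I/O and geometry.

A cell membrane is represented by a closed, consistently oriented triangular
mesh. Four kinds of entities carry the elastic state: points, edges (with a
relaxed length), triangles (with a relaxed area) and angles -- pairs of
triangles sharing an edge, with a relaxed dihedral angle. The relaxed (stress
free) quantities are frozen when the mesh is built and all deformation
measures are taken relative to them.

Dihedral convention: the angle ``theta`` of a quad (A, B, C, D) -- triangles
ABC and ABD sharing edge AB, both wound outward -- is ``pi`` for a flat
configuration, below ``pi`` where the surface is locally convex and above
``pi`` (up to ``2*pi``) where it is locally concave. A regular tetrahedron
gives ``arccos(1/3)`` on every edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    MeshFormatError,
    OrientationError,
    TopologyError,
)

__all__ = [
    "Mesh",
    "read_mesh_files",
    "write_mesh_files",
    "build_mesh",
    "triangle_normal",
    "triangle_normals",
    "triangle_areas",
    "angle_size",
    "angle_sizes",
    "mesh_surface",
    "mesh_volume",
    "generate_icosphere",
    "min_angle",
]

_DEGENERACY_TOL = 1e-24  # on squared normal magnitude, relative to edge scale


# ---------------------------------------------------------------------------
# plain-text mesh files


def _parse_triplet_file(path, conv, what):
    rows = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise MeshFormatError(
                    f"{path}:{lineno}: expected 3 {what} values, got {len(parts)}"
                )
            try:
                rows.append([conv(p) for p in parts])
            except ValueError as exc:
                raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


def read_mesh_files(nodes_path, triangles_path, index_base: int = 0):
    """Read ``nodes.dat`` / ``triangles.dat`` style mesh files.

    ``nodes_path`` holds one whitespace-separated x y z float triplet per
    line; the line order defines the point ids. ``triangles_path`` holds one
    integer id triplet per line. Lines starting with ``#`` and blank lines
    are skipped. ``index_base`` selects 0- or 1-based node ids in the
    triangle file.

    Returns ``(positions, faces)`` as float and int arrays.
    """
    positions = np.asarray(
        _parse_triplet_file(nodes_path, float, "float"), dtype=float
    )
    faces_rows = _parse_triplet_file(triangles_path, int, "integer")
    faces = np.asarray(faces_rows, dtype=np.intp)
    if faces.size:
        faces = faces - index_base
        if faces.min() < 0 or faces.max() >= len(positions):
            bad = int(np.argmax((faces < 0).any(axis=1) | (faces >= len(positions)).any(axis=1)))
            raise IndexError(
                f"{triangles_path}: triangle {bad} references a node id outside "
                f"0..{len(positions) - 1} (index_base={index_base})"
            )
    return positions, faces


def write_mesh_files(positions, faces, nodes_path, triangles_path, index_base: int = 0):
    """Write mesh files readable by :func:`read_mesh_files` (17 digits)."""
    positions = np.asarray(positions, dtype=float)
    faces = np.asarray(faces, dtype=np.intp)
    if positions.size == 0:
        raise ValueError("refusing to write an empty mesh")
    if faces.size and (faces.min() < 0 or faces.max() >= len(positions)):
        raise IndexError("face indices out of range for the given positions")
    with open(nodes_path, "w") as fh:
        for p in positions:
            fh.write("%.17g %.17g %.17g\n" % (p[0], p[1], p[2]))
    with open(triangles_path, "w") as fh:
        for t in faces + index_base:
            fh.write("%d %d %d\n" % (t[0], t[1], t[2]))


# ---------------------------------------------------------------------------
# geometric primitives


def triangle_normal(A, B, C):
    """Unnormalized triangle normal ``(A - C) x (B - C)``.

    Its magnitude is twice the triangle area; for a triangle wound (A, B, C)
    it points along the outward orientation.
    """
    A, B, C = (np.asarray(p, dtype=float) for p in (A, B, C))
    n = np.cross(A - C, B - C)
    scale = max(np.dot(B - A, B - A), np.dot(C - A, C - A))
    if np.dot(n, n) <= _DEGENERACY_TOL * scale * scale:
        raise DegenerateGeometryError("collinear points: triangle has no normal")
    return n


def triangle_normals(positions, faces):
    """Vectorized unnormalized normals, one row per face."""
    p = positions[faces]
    return np.cross(p[:, 0] - p[:, 2], p[:, 1] - p[:, 2])


def triangle_areas(positions, faces):
    return 0.5 * np.linalg.norm(triangle_normals(positions, faces), axis=1)


def angle_sizes(positions, quads):
    """Dihedral angles in (0, 2pi) for an array of (A, B, C, D) quads."""
    A = positions[quads[:, 0]]
    B = positions[quads[:, 1]]
    C = positions[quads[:, 2]]
    D = positions[quads[:, 3]]
    nc = np.cross(A - C, B - C)
    nd = np.cross(B - D, A - D)
    nc2 = np.einsum("ij,ij->i", nc, nc)
    nd2 = np.einsum("ij,ij->i", nd, nd)
    scale = np.einsum("ij,ij->i", B - A, B - A)
    if np.any(nc2 <= _DEGENERACY_TOL * scale * scale) or np.any(
        nd2 <= _DEGENERACY_TOL * scale * scale
    ):
        raise DegenerateGeometryError("degenerate triangle in dihedral angle")
    cosphi = np.clip(
        np.einsum("ij,ij->i", nc, nd) / np.sqrt(nc2 * nd2), -1.0, 1.0
    )
    phi = np.arccos(cosphi)
    # convex (theta < pi) when C lies below the outward plane of ABD
    s = np.einsum("ij,ij->i", C - D, nd)
    return np.pi + np.sign(s) * phi


def angle_size(A, B, C, D):
    """Dihedral angle at the shared edge AB of triangles ABC and ABD.

    Flat quads give ``pi``; locally convex configurations give values below
    ``pi``, locally concave ones above. Mirror-reflecting D through the ABC
    plane maps ``theta`` to ``2*pi - theta``.
    """
    pos = np.array([A, B, C, D], dtype=float)
    return float(angle_sizes(pos, np.array([[0, 1, 2, 3]]))[0])


# ---------------------------------------------------------------------------
# the mesh container


@dataclass
class Mesh:
    """Closed oriented triangle mesh with frozen relaxed-state geometry.

    ``positions``/``velocities`` are (N, 3) arrays; ``edges`` (E, 2),
    ``triangles`` (F, 3) and ``angles`` (Q, 4) are index arrays. By
    construction angle ``q`` has ``edges[q]`` as its shared edge (one angle
    per interior edge, E == Q for a closed mesh), and ``triangle_owner``
    assigns every triangle to exactly one angle so a single pass over the
    angles touches each edge and each triangle exactly once.
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    movable: bool
    edges: np.ndarray
    triangles: np.ndarray
    angles: np.ndarray
    relaxed_edge_lengths: np.ndarray
    relaxed_areas: np.ndarray
    relaxed_angles: np.ndarray
    relaxed_surface: float
    relaxed_volume: float
    triangle_owner: np.ndarray = field(repr=False, default=None)

    # -- counts ------------------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    # -- geometry ----------------------------------------------------------
    def edge_lengths(self) -> np.ndarray:
        d = self.positions[self.edges[:, 1]] - self.positions[self.edges[:, 0]]
        return np.linalg.norm(d, axis=1)

    def angle_values(self) -> np.ndarray:
        return angle_sizes(self.positions, self.angles)

    def surface(self) -> float:
        return float(np.sum(triangle_areas(self.positions, self.triangles)))

    def volume(self) -> float:
        p = self.positions[self.triangles]
        return float(
            np.sum(np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2]))) / 6.0
        )

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def min_angle(self):
        """Smallest dihedral angle and the (A, B, C, D) ids of its quad."""
        if self.n_angles == 0:
            raise ValueError("mesh has no angles")
        vals = self.angle_values()
        i = int(np.argmin(vals))
        return float(vals[i]), tuple(int(k) for k in self.angles[i])

    # -- manipulation ------------------------------------------------------
    def copy(self, movable: bool | None = None) -> "Mesh":
        return Mesh(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
            movable=self.movable if movable is None else movable,
            edges=self.edges,
            triangles=self.triangles,
            angles=self.angles,
            relaxed_edge_lengths=self.relaxed_edge_lengths,
            relaxed_areas=self.relaxed_areas,
            relaxed_angles=self.relaxed_angles,
            relaxed_surface=self.relaxed_surface,
            relaxed_volume=self.relaxed_volume,
            triangle_owner=self.triangle_owner,
        )

    def translate(self, shift) -> None:
        self.positions += np.asarray(shift, dtype=float)

    def transform(self, rotation=None, translation=None, about=None) -> None:
        """Apply a rigid motion: rotate about ``about`` (default centroid),
        then translate."""
        if rotation is not None:
            pivot = self.centroid() if about is None else np.asarray(about, float)
            R = np.asarray(rotation, dtype=float)
            self.positions[:] = (self.positions - pivot) @ R.T + pivot
            if self.velocities.any():
                self.velocities[:] = self.velocities @ R.T
        if translation is not None:
            self.translate(translation)


def mesh_surface(mesh: Mesh) -> float:
    """Total surface area, the sum of all triangle areas."""
    return mesh.surface()


def mesh_volume(mesh: Mesh) -> float:
    """Enclosed volume via the divergence theorem (positive when outward)."""
    return mesh.volume()


def min_angle(mesh: Mesh):
    return mesh.min_angle()


# ---------------------------------------------------------------------------
# construction


def build_mesh(positions, faces, mass: float = 1.0, movable: bool = True) -> Mesh:
    """Build a :class:`Mesh` from raw positions and faces.

    Validates that the faces form a closed, orientable, consistently wound
    2-manifold; flips the whole mesh if the signed volume is negative so the
    stored orientation is always outward; freezes all relaxed quantities from
    the input geometry.
    """
    positions = np.array(positions, dtype=float)
    faces = np.array(faces, dtype=np.intp)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be an (N, 3) array")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValueError("faces must be an (F, 3) array")
    if faces.size and (faces.min() < 0 or faces.max() >= len(positions)):
        raise IndexError("face indices out of range")
    if len({tuple(sorted(f)) for f in faces.tolist()}) != len(faces):
        raise TopologyError("duplicate triangle in face list")
    for k, f in enumerate(faces):
        if len(set(f.tolist())) != 3:
            raise TopologyError(f"triangle {k} has repeated vertex ids")

    edges, angles = _edges_and_angles(faces)

    mesh = Mesh(
        positions=positions,
        velocities=np.zeros_like(positions),
        masses=np.full(len(positions), float(mass)),
        movable=movable,
        edges=edges,
        triangles=faces,
        angles=angles,
        relaxed_edge_lengths=None,
        relaxed_areas=None,
        relaxed_angles=None,
        relaxed_surface=0.0,
        relaxed_volume=0.0,
    )
    if mesh.volume() < 0:
        faces = faces[:, ::-1].copy()
        edges, angles = _edges_and_angles(faces)
        mesh.triangles = faces
        mesh.edges = edges
        mesh.angles = angles

    mesh.triangle_owner = _assign_triangle_owners(faces, angles)
    mesh.relaxed_edge_lengths = mesh.edge_lengths()
    mesh.relaxed_areas = triangle_areas(positions, faces)
    mesh.relaxed_angles = mesh.angle_values()
    mesh.relaxed_surface = mesh.surface()
    mesh.relaxed_volume = mesh.volume()
    if np.any(mesh.relaxed_edge_lengths <= 0.0):
        raise DegenerateGeometryError("zero-length edge in input mesh")
    return mesh


def _edges_and_angles(faces):
    """Edge list, manifold/orientation checks and one angle quad per edge.

    For each undirected edge the quad is (A, B, C, D) where (A, B) follows
    the winding of the first incident triangle (file order), C is that
    triangle's opposite vertex and D the other triangle's.
    """
    directed = {}  # (a, b) -> (face index, opposite vertex)
    for fi, (a, b, c) in enumerate(faces.tolist()):
        for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
            if (u, v) in directed:
                raise OrientationError(
                    f"directed edge ({u},{v}) traversed twice: inconsistent "
                    "winding not repairable by a global flip"
                )
            directed[(u, v)] = (fi, w)

    edges = []
    quads = []
    seen = set()
    for fi, (a, b, c) in enumerate(faces.tolist()):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            if key in seen:
                continue
            seen.add(key)
            if (v, u) not in directed:
                raise TopologyError(
                    f"edge ({u},{v}) borders {'1' if (u, v) in directed else '0'} "
                    "triangle(s); mesh is not closed"
                )
            fwd_face, C = directed[(u, v)]
            rev_face, D = directed[(v, u)]
            # (A,B) in the winding order of the first incident triangle
            if fwd_face <= rev_face:
                quads.append((u, v, C, D))
                edges.append((u, v))
            else:
                quads.append((v, u, D, C))
                edges.append((v, u))
    return np.asarray(edges, dtype=np.intp), np.asarray(quads, dtype=np.intp)


def _assign_triangle_owners(faces, angles):
    """Assign each triangle to exactly one angle (double-counting guard).

    Every triangle borders three angles; the owner is the first angle (in
    angle order) whose pair of incident triangles includes it. Used by the
    combined angle loop so local-area terms are evaluated once per triangle.
    """
    tri_index = {tuple(sorted(f)): i for i, f in enumerate(faces.tolist())}
    owner = np.full(len(faces), -1, dtype=np.intp)
    for qi, (a, b, c, d) in enumerate(angles.tolist()):
        for tri in ((a, b, c), (b, a, d)):
            ti = tri_index[tuple(sorted(tri))]
            if owner[ti] < 0:
                owner[ti] = qi
    assert (owner >= 0).all()
    return owner


# ---------------------------------------------------------------------------
# built-in generator


_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.intp,
)


def generate_icosphere(subdivisions: int = 2, radius: float = 1.0):
    """Subdivided icosahedron projected onto a sphere of ``radius``.

    Returns ``(positions, faces)`` with ``10 * 4**s + 2`` vertices and
    ``20 * 4**s`` outward-wound faces. ``subdivisions`` is capped at 6.
    """
    if not 0 <= subdivisions <= 6:
        raise ValueError("subdivisions must be in 0..6")
    verts = [v / np.linalg.norm(v) for v in _ICO_VERTS]
    faces = _ICO_FACES.tolist()
    for _ in range(subdivisions):
        midpoint = {}

        def mid(i, j):
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                midpoint[key] = len(verts) - 1
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = new_faces
    positions = np.asarray(verts) * float(radius)
    faces = np.asarray(faces, dtype=np.intp)
    # enforce outward orientation
    p = positions[faces]
    vol = np.sum(np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2]))) / 6.0
    if vol < 0:
        faces = faces[:, ::-1].copy()
    return positions, faces
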