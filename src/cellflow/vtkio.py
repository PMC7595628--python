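"""Legacy ASCII VTK writers and tab-separated observable tables.

Cells are written as POLYDATA (points + triangle polygons, optional per-node
vector/scalar fields); the fluid and rasterized boundaries as
STRUCTURED_POINTS. Legacy ASCII keeps the outputs diffable and readable by
any VTK-compatible viewer. Floats use the ``%.9g`` format.
"""

from __future__ import annotations

import numpy as np

from .cells import Cell
from .fluid import FluidLattice

__all__ = [
    "write_vtk_cell",
    "write_vtk_fluid",
    "write_vtk_boundaries",
    "ObservableWriter",
    "write_observables",
]

_F = "%.9g"


def _write_vector_rows(fh, arr):
    for row in arr:
        fh.write((_F + " " + _F + " " + _F + "\n") % (row[0], row[1], row[2]))


def write_vtk_cell(cell: Cell, path, point_data: dict | None = None) -> None:
    """Write one cell as legacy VTK POLYDATA.

    ``point_data`` maps field names to per-node arrays: (N, 3) fields become
    VECTORS, (N,) fields SCALARS. Field lengths must match the node count.
    """
    mesh = cell.mesh
    n = mesh.n_points
    point_data = point_data or {}
    for name, arr in point_data.items():
        if len(arr) != n:
            raise ValueError(f"point_data field '{name}' has length "
                             f"{len(arr)}, expected {n}")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"cellflow cell {cell.label}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        _write_vector_rows(fh, mesh.positions)
        f = mesh.n_triangles
        fh.write(f"POLYGONS {f} {4 * f}\n")
        for t in mesh.triangles:
            fh.write("3 %d %d %d\n" % (t[0], t[1], t[2]))
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2:
                    fh.write(f"VECTORS {name} float\n")
                    _write_vector_rows(fh, arr)
                else:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write((_F + "\n") % v)


def _write_structured_points(path, title, lattice: FluidLattice, fields):
    nx, ny, nz = lattice.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        s = lattice.spacing
        fh.write(("SPACING " + _F + " " + _F + " " + _F + "\n") % (s, s, s))
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields:
            if arr.ndim == 4:  # (nx, ny, nz, 3) vector field
                fh.write(f"VECTORS {name} float\n")
                # VTK structured points iterate x fastest
                _write_vector_rows(fh, arr.transpose(2, 1, 0, 3).reshape(-1, 3))
            else:
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in arr.transpose(2, 1, 0).ravel():
                    fh.write((_F + "\n") % v)


def write_vtk_fluid(lattice: FluidLattice, path) -> None:
    """Velocity field + solid mask as legacy VTK STRUCTURED_POINTS."""
    u = lattice.velocity_field()
    _write_structured_points(
        path, "cellflow fluid", lattice,
        [("velocity", u), ("boundary", lattice.boundary_mask.astype(float))],
    )


def write_vtk_boundaries(boundaries, lattice: FluidLattice, path) -> None:
    """Boundary shapes rasterized on the fluid grid (1 = solid)."""
    mask = np.zeros(lattice.shape)
    pts = lattice.node_positions()
    for shape in boundaries:
        mask += shape.contains(pts).reshape(lattice.shape)
    _write_structured_points(
        path, "cellflow boundaries", lattice, [("solid", (mask > 0).astype(float))]
    )


class ObservableWriter:
    """Tab-separated observable table with a single header line.

    The first row fixes the column set; later rows must match it exactly.
    Values are written with 15 significant digits so they round-trip.
    """

    def __init__(self, path):
        self.path = path
        self.columns = None

    def write_row(self, row: dict) -> None:
        if self.columns is None:
            self.columns = list(row.keys())
            with open(self.path, "w") as fh:
                fh.write("\t".join(self.columns) + "\n")
        if list(row.keys()) != self.columns:
            raise ValueError(
                f"row columns {list(row)} do not match header {self.columns}"
            )
        with open(self.path, "a") as fh:
            fh.write("\t".join("%.15g" % float(row[c]) for c in self.columns) + "\n")


def write_observables(path, rows) -> None:
    """Write a list of uniform dict rows as one tab-separated table."""
    writer = ObservableWriter(path)
    rows = list(rows)
    if rows:
        cols = list(rows[0].keys())
        for row in rows:
            if list(row.keys()) != cols:
                raise ValueError("inconsistent observable columns")
    for row in rows:
        writer.write_row(row)
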