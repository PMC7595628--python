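"""Shared fixtures: small closed meshes, cell templates and a VTK parser."""

import numpy as np
import pytest

from cellflow.cells import CellType, instantiate_cell
from cellflow.elastic import ElasticCoefficients
from cellflow.mesh import build_mesh, generate_icosphere

# red-blood-cell-scale elastic coefficients (lattice units)
RBC = dict(ks=0.005, kb=0.02, kal=0.007, kag=0.7, kv=0.9)


@pytest.fixture(scope="session")
def tetra_arrays():
    positions = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return positions, faces


@pytest.fixture()
def tetra_mesh(tetra_arrays):
    return build_mesh(*tetra_arrays)


@pytest.fixture(scope="session")
def cube_arrays():
    """Unit cube as 8 vertices / 12 outward-wound triangles."""
    positions = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom, -z
            [4, 5, 6], [4, 6, 7],  # top, +z
            [0, 1, 5], [0, 5, 4],  # -y
            [2, 3, 7], [2, 7, 6],  # +y
            [0, 4, 7], [0, 7, 3],  # -x
            [1, 2, 6], [1, 6, 5],  # +x
        ]
    )
    return positions, faces


@pytest.fixture()
def cube_mesh(cube_arrays):
    return build_mesh(*cube_arrays)


@pytest.fixture()
def ico1_mesh():
    return build_mesh(*generate_icosphere(1, 1.0))


@pytest.fixture()
def ico2_mesh():
    return build_mesh(*generate_icosphere(2, 1.0))


@pytest.fixture(scope="session")
def rbc_type():
    pos, faces = generate_icosphere(2, 3.91)
    return CellType.from_arrays(pos, faces, ElasticCoefficients(**RBC))


@pytest.fixture()
def rbc_cell(rbc_type):
    return instantiate_cell(rbc_type, origin=(8.0, 8.0, 8.0))


def _tokens(path):
    with open(path) as fh:
        for line in fh:
            yield from line.split()


def parse_legacy_vtk(path):
    """Minimal independent legacy-VTK ASCII reader used as a roundtrip oracle.

    Understands POLYDATA (POINTS/POLYGONS) and STRUCTURED_POINTS
    (DIMENSIONS) plus POINT_DATA VECTORS/SCALARS blocks. Returns a dict.
    """
    out = {"point_data": {}}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    def take_floats(k, start):
        vals = []
        j = start
        while len(vals) < k:
            vals.extend(float(v) for v in lines[j].split())
            j += 1
        return np.array(vals), j

    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0]
        if key == "DATASET":
            out["dataset"] = parts[1]
        elif key == "DIMENSIONS":
            out["dimensions"] = tuple(int(v) for v in parts[1:4])
        elif key == "POINTS":
            n = int(parts[1])
            vals, i = take_floats(3 * n, i + 1)
            out["points"] = vals.reshape(n, 3)
            continue
        elif key == "POLYGONS":
            n = int(parts[1])
            polys = []
            j = i + 1
            while len(polys) < n:
                row = [int(v) for v in lines[j].split()]
                assert row[0] == len(row) - 1
                polys.append(row[1:])
                j += 1
            out["polygons"] = polys
            i = j
            continue
        elif key == "POINT_DATA":
            out["n_point_data"] = int(parts[1])
        elif key == "VECTORS":
            n = out.get("n_point_data")
            vals, i = take_floats(3 * n, i + 1)
            out["point_data"][parts[1]] = vals.reshape(n, 3)
            continue
        elif key == "SCALARS":
            n = out.get("n_point_data")
            vals, i = take_floats(n, i + 2)  # skip LOOKUP_TABLE
            out["point_data"][parts[1]] = vals
            continue
        i += 1
    return out


@pytest.fixture(scope="session")
def vtk_parser():
    return parse_legacy_vtk
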