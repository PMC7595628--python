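"""Mesh construction, file round-trips and geometric queries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cellflow.errors import (
    DegenerateGeometryError,
    MeshFormatError,
    OrientationError,
    TopologyError,
)
from cellflow.mesh import (
    angle_size,
    build_mesh,
    generate_icosphere,
    mesh_surface,
    mesh_volume,
    read_mesh_files,
    triangle_normal,
    write_mesh_files,
)


class TestMeshFiles:
    def test_roundtrip_bit_identical(self, tetra_arrays, tmp_path):
        pos, faces = tetra_arrays
        write_mesh_files(pos, faces, tmp_path / "n.dat", tmp_path / "t.dat")
        pos2, faces2 = read_mesh_files(tmp_path / "n.dat", tmp_path / "t.dat")
        assert np.array_equal(pos, pos2)
        assert np.array_equal(faces, faces2)

    def test_icosphere_roundtrip_preserves_volume(self, tmp_path):
        pos, faces = generate_icosphere(2, 1.3)
        write_mesh_files(pos, faces, tmp_path / "n.dat", tmp_path / "t.dat")
        pos2, faces2 = read_mesh_files(tmp_path / "n.dat", tmp_path / "t.dat")
        assert build_mesh(pos2, faces2).volume() == build_mesh(pos, faces).volume()

    def test_comments_and_blank_lines_tolerated(self, tmp_path):
        (tmp_path / "n.dat").write_text("# header\n0 0 0\n\n1 0 0\n0 1 0\n0 0 1\n")
        (tmp_path / "t.dat").write_text("0 1 2\n0 3 1\n0 2 3\n1 3 2\n")
        pos, faces = read_mesh_files(tmp_path / "n.dat", tmp_path / "t.dat")
        assert pos.shape == (4, 3) and faces.shape == (4, 3)

    def test_malformed_line_names_line_number(self, tmp_path):
        (tmp_path / "n.dat").write_text("0 0 0\n1 oops 0\n")
        (tmp_path / "t.dat").write_text("0 1 2\n")
        with pytest.raises(MeshFormatError, match=":2"):
            read_mesh_files(tmp_path / "n.dat", tmp_path / "t.dat")

    def test_out_of_range_face_index(self, tmp_path):
        (tmp_path / "n.dat").write_text("0 0 0\n1 0 0\n0 1 0\n0 0 1\n")
        (tmp_path / "t.dat").write_text("0 1 9\n")
        with pytest.raises(IndexError):
            read_mesh_files(tmp_path / "n.dat", tmp_path / "t.dat")

    def test_one_based_indexing_switch(self, tetra_arrays, tmp_path):
        pos, faces = tetra_arrays
        write_mesh_files(pos, faces, tmp_path / "n.dat", tmp_path / "t.dat",
                         index_base=1)
        text = (tmp_path / "t.dat").read_text()
        assert "0" not in text.split()  # all ids shifted up
        _, faces2 = read_mesh_files(tmp_path / "n.dat", tmp_path / "t.dat",
                                    index_base=1)
        assert np.array_equal(faces, faces2)

    def test_refuses_empty_mesh(self, tmp_path):
        with pytest.raises(ValueError):
            write_mesh_files(np.empty((0, 3)), np.empty((0, 3), dtype=int),
                             tmp_path / "n.dat", tmp_path / "t.dat")


class TestBuildMesh:
    def test_tetrahedron_counts_and_euler(self, tetra_mesh):
        m = tetra_mesh
        assert (m.n_points, m.n_edges, m.n_triangles, m.n_angles) == (4, 6, 4, 6)
        assert m.n_points - m.n_edges + m.n_triangles == 2

    @pytest.mark.parametrize("s,V,F", [(0, 12, 20), (1, 42, 80), (2, 162, 320)])
    def test_icosphere_counts(self, s, V, F):
        pos, faces = generate_icosphere(s, 1.0)
        m = build_mesh(pos, faces)
        assert (m.n_points, m.n_triangles) == (V, F)
        assert m.n_edges == 3 * F // 2
        assert m.n_angles == m.n_edges
        assert m.n_points - m.n_edges + m.n_triangles == 2

    def test_icosphere_vertices_on_sphere(self):
        pos, _ = generate_icosphere(3, 2.5)
        assert np.allclose(np.linalg.norm(pos, axis=1), 2.5, atol=1e-12)

    def test_duplicate_triangle_is_topology_error(self, tetra_arrays):
        pos, faces = tetra_arrays
        bad = np.vstack([faces, faces[0]])
        with pytest.raises(TopologyError):
            build_mesh(pos, bad)

    def test_open_surface_is_topology_error(self, tetra_arrays):
        pos, faces = tetra_arrays
        with pytest.raises(TopologyError):
            build_mesh(pos, faces[:3])

    def test_mixed_winding_is_orientation_error(self, cube_arrays):
        pos, faces = cube_arrays
        bad = faces.copy()
        bad[0] = bad[0, ::-1]
        with pytest.raises(OrientationError):
            build_mesh(pos, bad)

    def test_inward_winding_flipped_globally(self, tetra_arrays):
        pos, faces = tetra_arrays
        m = build_mesh(pos, faces[:, ::-1])
        assert m.volume() > 0
        assert m.volume() == pytest.approx(8.0 / 3.0, rel=1e-12)

    def test_relaxed_state_frozen_from_input(self, ico1_mesh):
        assert np.allclose(ico1_mesh.relaxed_edge_lengths, ico1_mesh.edge_lengths())
        assert np.allclose(ico1_mesh.relaxed_angles, ico1_mesh.angle_values())
        assert ico1_mesh.relaxed_volume == ico1_mesh.volume()

    def test_triangle_owner_is_a_bijection_onto_triangles(self, ico1_mesh):
        owner = ico1_mesh.triangle_owner
        assert owner.shape == (ico1_mesh.n_triangles,)
        assert (owner >= 0).all() and (owner < ico1_mesh.n_angles).all()


class TestGeometry:
    def test_triangle_normal_hand_value(self):
        n = triangle_normal([0, 0, 0], [1, 0, 0], [0, 1, 0])
        assert np.allclose(n, [0, 0, 1])

    def test_triangle_normal_antisymmetry(self):
        A, B, C = np.random.default_rng(0).standard_normal((3, 3))
        assert np.allclose(triangle_normal(A, B, C), -triangle_normal(B, A, C))

    def test_triangle_normal_345_magnitude(self):
        n = triangle_normal([0, 0, 0], [3, 0, 0], [0, 4, 0])
        assert np.linalg.norm(n) == pytest.approx(12.0)  # twice area 6

    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            triangle_normal([0, 0, 0], [1, 0, 0], [2, 0, 0])

    def test_flat_quad_angle_is_pi(self):
        th = angle_size([0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, -1, 0])
        assert th == pytest.approx(np.pi)

    def test_tetrahedron_dihedral(self, tetra_mesh):
        # every angle of the regular tetrahedron equals arccos(1/3)
        assert np.allclose(tetra_mesh.angle_values(), np.arccos(1.0 / 3.0))

    def test_convex_mesh_angles_below_pi(self, ico2_mesh):
        assert (ico2_mesh.angle_values() < np.pi).all()

    def test_mirror_reflection_maps_theta_to_2pi_minus(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            A = np.array([0.0, 0.0, 0.0])
            B = np.array([1.0, 0.0, 0.0])
            C = np.array([0.5, 1.0, 0.0]) + 0.2 * rng.standard_normal(3)
            D = np.array([0.5, -1.0, 0.5]) + 0.2 * rng.standard_normal(3)
            D_mirror = D * np.array([1, 1, -1])
            C_flat = C * np.array([1, 1, 0])  # keep ABC in the mirror plane
            th = angle_size(A, B, C_flat, D)
            th_m = angle_size(A, B, C_flat, D_mirror)
            assert th + th_m == pytest.approx(2 * np.pi, abs=1e-10)

    def test_cube_surface_volume(self, cube_mesh):
        assert mesh_surface(cube_mesh) == pytest.approx(6.0)
        assert mesh_volume(cube_mesh) == pytest.approx(1.0)

    def test_icosphere_volume_brackets_ball(self):
        pos, faces = generate_icosphere(3, 1.0)
        v = build_mesh(pos, faces).volume()
        ball = 4.0 * np.pi / 3.0
        assert 0.95 * ball < v < ball  # inscribed polyhedron underestimates

    def test_icosphere_volume_matches_trimesh(self):
        trimesh = pytest.importorskip("trimesh")
        pos, faces = generate_icosphere(2, 1.7)
        m = build_mesh(pos, faces)
        tm = trimesh.Trimesh(vertices=pos, faces=faces, process=False)
        assert m.volume() == pytest.approx(tm.volume, rel=1e-12)
        assert m.surface() == pytest.approx(tm.area, rel=1e-12)
        assert tm.is_watertight and tm.is_winding_consistent

    def test_translation_invariance(self, ico1_mesh):
        s, v = ico1_mesh.surface(), ico1_mesh.volume()
        ico1_mesh.translate((5, 5, 5))
        assert ico1_mesh.surface() == pytest.approx(s, rel=1e-12)
        assert ico1_mesh.volume() == pytest.approx(v, rel=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = build_mesh(*generate_icosphere(1, 1.0))
        s, v = m.surface(), m.volume()
        lengths, angles = m.edge_lengths(), m.angle_values()
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        m.positions[:] = m.positions @ R.T + rng.standard_normal(3) * 10
        assert m.surface() == pytest.approx(s, rel=1e-10)
        assert m.volume() == pytest.approx(v, rel=1e-10)
        assert np.allclose(m.edge_lengths(), lengths, rtol=1e-10)
        assert np.allclose(m.angle_values(), angles, rtol=1e-10, atol=1e-10)


class TestMinAngle:
    def test_matches_bruteforce_loop(self, ico1_mesh):
        val, ids = ico1_mesh.min_angle()
        assert val < np.pi
        # exhaustive loop oracle, one quad at a time
        best = 2 * np.pi
        best_ids = None
        for quad in ico1_mesh.angles:
            a = angle_size(*ico1_mesh.positions[quad])
            if a < best:
                best, best_ids = a, tuple(int(i) for i in quad)
        assert val == pytest.approx(best, rel=1e-12)
        assert ids == best_ids

    def test_identifies_sharpened_crease(self):
        pos, faces = generate_icosphere(1, 1.0)
        m = build_mesh(pos, faces)
        spike = 7
        m.positions[spike] *= 1.6  # pull one vertex outward
        val, ids = m.min_angle()
        neighborhood = {spike} | {
            int(b) for a, b in m.edges if a == spike
        } | {int(a) for a, b in m.edges if b == spike}
        assert val < m.relaxed_angles.min()
        assert neighborhood.intersection(ids)

    def test_regular_tetrahedron_ties_first_in_order(self, tetra_mesh):
        val, ids = tetra_mesh.min_angle()
        assert val == pytest.approx(np.arccos(1.0 / 3.0), rel=1e-12)
        assert ids == tuple(int(i) for i in tetra_mesh.angles[0])
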