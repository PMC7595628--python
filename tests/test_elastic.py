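"""Elastic force laws: printed-formula values, conservation properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellflow.cells import CellType, instantiate_cell
from cellflow.elastic import (
    ElasticCoefficients,
    accumulate_elastic_forces,
    bending_forces,
    bending_forces_mesh,
    global_area_forces,
    local_area_forces,
    local_area_forces_mesh,
    neo_hookean_kappa,
    stretching_force_pair,
    stretching_forces,
    volume_forces,
)
from cellflow.errors import DegenerateGeometryError
from cellflow.mesh import angle_size, build_mesh, generate_icosphere

from conftest import RBC


def perturbed_ico(scale=0.05, seed=0, subdivisions=2, radius=1.0):
    m = build_mesh(*generate_icosphere(subdivisions, radius))
    rng = np.random.default_rng(seed)
    m.positions += scale * rng.standard_normal(m.positions.shape)
    return m


class TestKappa:
    def test_relaxed_identity(self):
        assert neo_hookean_kappa(1.0) == pytest.approx(1.0, rel=1e-15)

    def test_printed_formula_value(self):
        # (2**0.5 + 2**-2.5) / (2 + 2**-3) = 1.5909902576... / 2.125
        assert neo_hookean_kappa(2.0) == pytest.approx(0.7487012977, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_inversion_symmetry(self, lam):
        assert neo_hookean_kappa(lam) == pytest.approx(
            neo_hookean_kappa(1.0 / lam), rel=1e-12
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            neo_hookean_kappa(0.0)


class TestStretching:
    def test_zero_at_relaxed_length(self):
        fA, fB = stretching_force_pair([0, 0, 0], [1, 0, 0], 1.0, 1.0)
        assert np.all(fA == 0) and np.all(fB == 0)

    def test_doubled_edge_value(self):
        fA, fB = stretching_force_pair([0, 0, 0], [2, 0, 0], 1.0, 1.0)
        assert np.allclose(fA, [neo_hookean_kappa(2.0), 0, 0])
        assert np.allclose(fB, -fA)

    def test_compression_pushes_apart(self):
        fA, _ = stretching_force_pair([0, 0, 0], [0.5, 0, 0], 1.0, 1.0)
        assert fA[0] < 0  # A pushed away from B

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            stretching_force_pair([1, 1, 1], [1, 1, 1], 1.0, 1.0)

    def test_mesh_pass_matches_pairwise(self):
        m = perturbed_ico(seed=1)
        F = stretching_forces(m, 0.7)
        ref = np.zeros_like(F)
        for (a, b), l0 in zip(m.edges, m.relaxed_edge_lengths):
            fa, fb = stretching_force_pair(m.positions[a], m.positions[b], l0, 0.7)
            ref[a] += fa
            ref[b] += fb
        assert np.allclose(F, ref, atol=1e-14)


def bending_reference(A, B, C, D, theta0, kb):
    """Independent transcription of the four bending forces (loop form)."""
    A, B, C, D = map(np.asarray, (A, B, C, D))
    nc = np.cross(A - C, B - C)
    nd = np.cross(B - D, A - D)
    dth = angle_size(A, B, C, D) - theta0
    lab = np.linalg.norm(B - A)
    # restoring sign: forces push theta back toward theta0
    fC = -kb * dth * lab * nc / (nc @ nc)
    fD = -kb * dth * lab * nd / (nd @ nd)
    fA = -(-kb * dth) * (
        nc / (nc @ nc) * ((A - B) @ (C - B)) / lab
        + nd / (nd @ nd) * ((A - B) @ (D - B)) / lab
    )
    fB = -(-kb * dth) * (
        nc / (nc @ nc) * ((A - B) @ (A - C)) / lab
        + nd / (nd @ nd) * ((A - B) @ (A - D)) / lab
    )
    return fA, fB, fC, fD


class TestBending:
    quad = (np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
            np.array([0.5, 1.0, 0]), np.array([0.5, -1.0, 1.0]))

    def test_zero_at_relaxed_angle(self):
        A, B, C, D = self.quad
        th = angle_size(A, B, C, D)
        for f in bending_forces(A, B, C, D, th, 1.0):
            assert np.all(f == 0)

    def test_forces_sum_to_zero_identically(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            pts = rng.standard_normal((4, 3))
            fs = bending_forces(*pts, theta0=np.pi * 0.9, kb=1.0)
            total = sum(fs)
            assert np.linalg.norm(total) < 1e-12 * max(
                np.linalg.norm(f) for f in fs
            )

    def test_matches_independent_transcription(self):
        A, B, C, D = self.quad
        got = bending_forces(A, B, C, D, np.pi, 1.0)
        ref = bending_reference(A, B, C, D, np.pi, 1.0)
        for g, r in zip(got, ref):
            assert np.allclose(g, r, atol=1e-14)

    def test_negative_gradient_of_angle_energy(self):
        """The bending force is restoring: -d/dx of kb/2 (theta-theta0)^2."""
        rng = np.random.default_rng(5)
        pts = np.array(self.quad) + 0.1 * rng.standard_normal((4, 3))
        th0 = 0.95 * np.pi
        kb = 0.7
        F = np.array(bending_forces(*pts, theta0=th0, kb=kb))
        h = 1e-6
        for i in range(4):
            for k in range(3):
                q = pts.copy()
                q[i, k] += h
                e1 = 0.5 * kb * (angle_size(*q) - th0) ** 2
                q[i, k] -= 2 * h
                e0 = 0.5 * kb * (angle_size(*q) - th0) ** 2
                assert F[i, k] == pytest.approx(-(e1 - e0) / (2 * h), abs=1e-5)

    def test_mesh_pass_matches_per_quad(self):
        m = perturbed_ico(seed=3, subdivisions=1)
        F = bending_forces_mesh(m, 0.4)
        ref = np.zeros_like(F)
        for quad, th0 in zip(m.angles, m.relaxed_angles):
            fs = bending_forces(*m.positions[quad], theta0=th0, kb=0.4)
            for idx, f in zip(quad, fs):
                ref[idx] += f
        assert np.allclose(F, ref, atol=1e-13)


class TestLocalArea:
    def test_zero_at_relaxed_area(self):
        fs = local_area_forces([0, 0, 0], [1, 0, 0], [0, 1, 0], 0.5, 1.0)
        for f in fs:
            assert np.all(f == 0)

    def test_centroid_identity_sum_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.standard_normal((3, 3))
            fs = local_area_forces(*pts, S0=0.3, kal=1.0)
            assert np.linalg.norm(sum(fs)) < 1e-14

    def test_scaled_equilateral_points_to_centroid(self):
        a = np.array([1.0, 0, 0])
        b = np.array([-0.5, np.sqrt(3) / 2, 0])
        c = np.array([-0.5, -np.sqrt(3) / 2, 0])
        S0 = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
        fs = local_area_forces(1.1 * a, 1.1 * b, 1.1 * c, S0, 1.0)
        mags = [np.linalg.norm(f) for f in fs]
        assert mags[0] == pytest.approx(mags[1]) == pytest.approx(mags[2])
        for f, p in zip(fs, (a, b, c)):
            assert f @ p < 0  # toward the centroid (origin)
        # brute-force evaluation of the printed expression
        S = S0 * 1.1**2
        t2 = 3 * (1.1 * np.linalg.norm(a)) ** 2
        assert mags[0] == pytest.approx((S - S0) / t2 * 1.1 * np.linalg.norm(a))


class TestGlobalTerms:
    def test_zero_at_relaxed(self):
        m = build_mesh(*generate_icosphere(1, 1.0))
        assert np.all(global_area_forces(m, 1.0) == 0)
        assert np.all(volume_forces(m, 1.0) == 0)

    @pytest.mark.parametrize("func", [global_area_forces, volume_forces])
    def test_net_force_zero_under_deformation(self, func):
        m = perturbed_ico(seed=11)
        F = func(m, 1.0)
        assert np.linalg.norm(F.sum(axis=0)) < 1e-10 * np.abs(F).sum()

    @pytest.mark.parametrize("scale,sign", [(1.05, -1.0), (0.95, 1.0)])
    def test_restoring_radial_sign(self, scale, sign):
        m = build_mesh(*generate_icosphere(2, 1.0))
        m.positions *= scale
        radial = m.positions / np.linalg.norm(m.positions, axis=1, keepdims=True)
        for F in (global_area_forces(m, 1.0), volume_forces(m, 1.0)):
            rdot = np.einsum("ij,ij->i", F, radial)
            assert np.all(sign * rdot > 0)


class TestAccumulation:
    def test_relaxed_mesh_exact_zero(self):
        # on the untouched relaxed mesh every deformation measure is exactly
        # zero, so all five moduli return bitwise-zero forces
        m = build_mesh(*generate_icosphere(2, 3.91))
        F = accumulate_elastic_forces(m, ElasticCoefficients(**RBC))
        assert np.all(F == 0.0)

    def test_freshly_placed_cell_has_negligible_forces(self, rbc_cell):
        # translation/rotation into place only adds float rounding
        F = accumulate_elastic_forces(rbc_cell.mesh, rbc_cell.cell_type.coefficients)
        assert np.abs(F).max() < 1e-12

    def test_equals_sum_of_standalone_moduli(self):
        m = perturbed_ico(seed=13, radius=3.91)
        c = ElasticCoefficients(**RBC)
        total = accumulate_elastic_forces(m, c)
        ref = (
            stretching_forces(m, c.ks)
            + bending_forces_mesh(m, c.kb)
            + local_area_forces_mesh(m, c.kal)
            + global_area_forces(m, c.kag)
            + volume_forces(m, c.kv)
        )
        scale = np.abs(ref).max()
        assert np.allclose(total, ref, atol=1e-12 * scale)

    def test_total_force_free(self):
        m = perturbed_ico(seed=17, radius=3.91)
        F = accumulate_elastic_forces(m, ElasticCoefficients(**RBC))
        assert np.linalg.norm(F.sum(axis=0)) <= 1e-10 * np.abs(F).sum()

    def test_torque_free_stretching_and_local_area(self):
        m = perturbed_ico(seed=19, radius=3.91)
        r = m.positions - m.positions.mean(axis=0)
        for F in (stretching_forces(m, 1.0), local_area_forces_mesh(m, 1.0)):
            tq = np.cross(r, F).sum(axis=0)
            assert np.linalg.norm(tq) <= 1e-10 * np.abs(np.cross(r, F)).sum()


class TestRigidInvariance:
    def test_forces_co_rotate(self):
        from scipy.spatial.transform import Rotation

        m = perturbed_ico(seed=23)
        c = ElasticCoefficients(**RBC)
        F = accumulate_elastic_forces(m, c)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        m.positions[:] = m.positions @ R.T + np.array([3.0, -2.0, 7.0])
        F2 = accumulate_elastic_forces(m, c)
        assert np.allclose(F2, F @ R.T, atol=1e-11)
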