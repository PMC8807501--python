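"""Coupled hexahedral element: operators, element blocks, assembly structure."""

import numpy as np
import pytest

from bonefe2.fem import (
    NDOF,
    Constraints,
    CoupledSystem,
    DofLayout,
    GAUSS_POINTS,
    element_matrices,
    element_volume,
    operator_matrices,
)
from bonefe2.materials import (
    MaterialTensors,
    PhaseMaterial,
    build_tensors,
)
from bonefe2.rve import HexMesh, RVEParams, build_rve_mesh

UNIT_CUBE = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [1.0, 1.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [1.0, 0.0, 1.0],
        [1.0, 1.0, 1.0],
        [0.0, 1.0, 1.0],
    ]
)

# a skewed but valid hexahedron for non-trivial Jacobians
SKEWED = UNIT_CUBE + 0.15 * np.array(
    [
        [0.0, 0.0, 0.0],
        [0.1, 0.3, 0.0],
        [0.0, 0.2, 0.1],
        [0.2, 0.0, 0.0],
        [0.1, 0.0, 0.3],
        [0.0, 0.1, 0.0],
        [0.3, 0.0, 0.2],
        [0.0, 0.0, 0.1],
    ]
)


def nodal_vector(coords, func):
    """Stack func(y) over the 8 nodes into the 24-vector layout."""
    return np.concatenate([np.asarray(func(y)) for y in coords])


class TestOperatorMatrices:
    @pytest.mark.parametrize("coords", [UNIT_CUBE, SKEWED], ids=["cube", "skewed"])
    def test_constant_vector_field_has_zero_curl_and_div(self, coords):
        A_hat = nodal_vector(coords, lambda y: [1.3, -0.7, 2.1])
        for xi in GAUSS_POINTS:
            _, _, B_curl, B_div, *_ = operator_matrices(coords, xi)
            np.testing.assert_allclose(B_curl @ A_hat, 0.0, atol=1e-12)
            np.testing.assert_allclose(B_div @ A_hat, 0.0, atol=1e-12)

    @pytest.mark.parametrize("coords", [UNIT_CUBE, SKEWED], ids=["cube", "skewed"])
    def test_affine_displacement_patch_consistency(self, coords):
        """An affine u with symmetric gradient eps* gives B_u u = eps* (Voigt,
        engineering shears) at every quadrature point."""
        grad = np.array([[1.0, 0.5, -0.2], [0.5, -0.3, 0.4], [-0.2, 0.4, 0.8]]) * 1e-3
        u_hat = nodal_vector(coords, lambda y: grad @ y)
        expected = np.array(
            [grad[0, 0], grad[1, 1], grad[2, 2],
             2 * grad[0, 1], 2 * grad[1, 2], 2 * grad[0, 2]]
        )
        for xi in GAUSS_POINTS:
            B_u, *_ = operator_matrices(coords, xi)
            np.testing.assert_allclose(B_u @ u_hat, expected, atol=1e-15)

    @pytest.mark.parametrize("coords", [UNIT_CUBE, SKEWED], ids=["cube", "skewed"])
    def test_rotational_potential_gives_unit_flux_density(self, coords):
        """A = (-y/2, x/2, 0) has curl (0, 0, 1)."""
        A_hat = nodal_vector(coords, lambda y: [-y[1] / 2, y[0] / 2, 0.0])
        for xi in GAUSS_POINTS:
            _, _, B_curl, B_div, *_ = operator_matrices(coords, xi)
            np.testing.assert_allclose(B_curl @ A_hat, [0, 0, 1], atol=1e-12)
            np.testing.assert_allclose(B_div @ A_hat, 0.0, atol=1e-12)

    def test_degenerate_jacobian_rejected(self):
        flat = UNIT_CUBE.copy()
        flat[:, 2] = 0.0
        with pytest.raises(ValueError):
            operator_matrices(flat, np.zeros(3))

    def test_element_volume_skewed(self):
        # oracle: volume by dense high-order quadrature of the same mapping
        from numpy.polynomial.legendre import leggauss

        x, w = leggauss(4)
        from bonefe2.fem import shape_functions

        vol = 0.0
        for a, wa in zip(x, w):
            for b, wb in zip(x, w):
                for c, wc in zip(x, w):
                    _, dN = shape_functions(np.array([a, b, c]))
                    vol += wa * wb * wc * np.linalg.det(SKEWED.T @ dN)
        assert element_volume(SKEWED) == pytest.approx(vol, rel=1e-12)


class TestElementMatrices:
    def test_insulating_phase_has_no_conduction_blocks(self, bone_tensors):
        K_e, C_e, M_e = element_matrices(UNIT_CUBE, bone_tensors, 1.0, 1e-3)
        iphi = [NDOF * a + 3 for a in range(8)]
        iA = [NDOF * a + 4 + c for a in range(8) for c in range(3)]
        np.testing.assert_array_equal(K_e[np.ix_(iA, iphi)], 0.0)

    def test_no_piezo_decouples_mechanics_from_electrics(self, marrow_tensors):
        K_e, C_e, _ = element_matrices(UNIT_CUBE, marrow_tensors, 1.0, 0.0)
        iu = [NDOF * a + c for a in range(8) for c in range(3)]
        iphi = [NDOF * a + 3 for a in range(8)]
        iA = [NDOF * a + 4 + c for a in range(8) for c in range(3)]
        np.testing.assert_array_equal(K_e[np.ix_(iu, iphi)], 0.0)
        np.testing.assert_array_equal(K_e[np.ix_(iphi, iu)], 0.0)
        np.testing.assert_array_equal(C_e[np.ix_(iu, iA)], 0.0)
        np.testing.assert_array_equal(C_e[np.ix_(iA, iu)], 0.0)

    def test_quadrature_exact_for_parallelepiped(self, bone_tensors):
        """2x2x2 Gauss equals a 4x4x4 reference on an affine element."""
        K2, C2, M2 = element_matrices(UNIT_CUBE, bone_tensors, 1.0, 1e-3)
        K4, C4, M4 = element_matrices(UNIT_CUBE, bone_tensors, 1.0, 1e-3, n_gauss=4)
        for A2, A4 in ((K2, K4), (C2, C4), (M2, M4)):
            scale = np.abs(A4).max()
            np.testing.assert_allclose(A2, A4, atol=1e-12 * scale)

    def test_free_element_equilibrium_under_rigid_translation(self, bone_tensors):
        """K times a rigid u-translation is zero: a free body carries no force."""
        K_e, _, _ = element_matrices(SKEWED, bone_tensors, 0.0, 0.0)
        d = np.zeros(56)
        for a in range(8):
            d[NDOF * a : NDOF * a + 3] = [1.0, -2.0, 0.5]
        np.testing.assert_allclose(K_e @ d, 0.0, atol=1e-6 * np.abs(K_e).max())


class TestAssembly:
    def test_operator_block_structure(self, healthy_mesh, bone_tensors, marrow_tensors):
        """M carries only the A-A block; K has no u-A coupling; C has no u-u
        or phi-phi blocks."""
        from bonefe2.rve import BONE, MARROW

        sysm = CoupledSystem(
            healthy_mesh, {BONE: bone_tensors, MARROW: marrow_tensors}, 1.0, 1e-3
        )
        n = healthy_mesh.n_nodes
        nodes = np.arange(n)
        iu = DofLayout.u(nodes)
        iphi = DofLayout.phi(nodes)
        iA = DofLayout.A(nodes)
        M, C, K = sysm.M.toarray(), sysm.C.toarray(), sysm.K.toarray()
        for rows in (iu, iphi):
            assert np.all(M[rows] == 0.0) and np.all(M[:, rows] == 0.0)
        assert np.any(M[np.ix_(iA, iA)] != 0.0)
        assert np.all(K[np.ix_(iu, iA)] == 0.0)
        assert np.all(K[np.ix_(iA, iu)] == 0.0)
        assert np.all(C[np.ix_(iu, iu)] == 0.0)
        assert np.all(C[np.ix_(iphi, iphi)] == 0.0)

    def test_affine_patch_is_equilibrated(self, bone_tensors):
        """Affine (u, phi, A) fields produce zero residual at interior nodes of
        a structured patch: the discrete operators reproduce constant fields
        exactly."""
        mesh = build_rve_mesh(RVEParams(0.4, 0.2, 1))  # 27-element patch
        sysm = CoupledSystem(mesh, bone_tensors, gamma=0.0, dt=0.0)
        from bonefe2.homogenization import MacroState, affine_fields

        macro = MacroState(
            eps_bar=[1e-5, -2e-5, 3e-5, 4e-6, -5e-6, 6e-6],
            E_bar=[1.0, -2.0, 0.5],
            B_bar=[0.3, 0.1, -0.2],
        )
        g = affine_fields(mesh, macro)
        R = sysm.K @ g
        boundary = np.unique(np.concatenate(list(mesh.face_sets.values())))
        interior = np.setdiff1d(np.arange(mesh.n_nodes), boundary)
        scale = np.abs(R).max()
        np.testing.assert_allclose(R[DofLayout.all(interior)], 0.0, atol=1e-12 * scale)

    def test_constraint_prolongation_shapes(self, healthy_mesh):
        cons = Constraints.build(
            healthy_mesh.n_nodes,
            fixed_nodes_all=healthy_mesh.corner_nodes,
            periodic_pairs=healthy_mesh.periodic_pairs,
        )
        n_full = NDOF * healthy_mesh.n_nodes
        n_fixed = NDOF * 8
        n_slaves = NDOF * len(healthy_mesh.periodic_pairs)
        assert cons.T.shape == (n_full, n_full - n_fixed - n_slaves)
        # each retained column sums over its identity + slave copies
        col_sums = np.asarray(cons.T.sum(axis=0)).ravel()
        assert col_sums.min() >= 1.0
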