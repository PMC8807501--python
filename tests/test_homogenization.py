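"""Periodic homogenization: macro-state imposition, averaging, tangents,
Hill-Mandel and the effective Young's modulus."""

import numpy as np
import pytest

from bonefe2 import (
    MacroState,
    RVEParams,
    RVEProblem,
    TimeIntegrationConfig,
    build_rve_mesh,
    effective_young_modulus,
)
from bonefe2.homogenization import affine_fields, voigt_to_tensor
from bonefe2.materials import (
    PhaseMaterial,
    build_tensors,
    isotropic_stiffness,
)

RVE_FAMILY = [(0.43, 0.14), (0.40, 0.20), (0.38, 0.24),
              (0.36, 0.28), (0.34, 0.32), (0.32, 0.36)]


class TestMacroStateImposition:
    def test_zero_state_zero_fields(self, healthy_mesh):
        g = affine_fields(healthy_mesh, MacroState())
        np.testing.assert_array_equal(g, 0.0)

    def test_affine_fields_reproduce_macro_state_at_quadrature(
        self, healthy_rve
    ):
        macro = MacroState(
            eps_bar=[1e-5, -2e-5, 3e-5, 4e-6, -5e-6, 6e-6],
            E_bar=[2.0, -1.0, 0.5],
            B_bar=[0.0, 0.0, 1.0],
        )
        g = affine_fields(healthy_rve.mesh, macro)
        n = healthy_rve.system.n_dofs
        eps, _, E, _, B, _ = healthy_rve.system.qp_state(g, np.zeros(n), np.zeros(n))
        np.testing.assert_allclose(eps, np.broadcast_to(macro.eps_bar, eps.shape),
                                   atol=1e-18)
        np.testing.assert_allclose(E, np.broadcast_to(macro.E_bar, E.shape),
                                   atol=1e-12)
        np.testing.assert_allclose(B, np.broadcast_to(macro.B_bar, B.shape),
                                   atol=1e-12)

    def test_voigt_tensor_halves_engineering_shears(self):
        t = voigt_to_tensor([1, 2, 3, 4, 5, 6])
        assert t[0, 1] == 2.0 and t[1, 2] == 2.5 and t[0, 2] == 3.0
        np.testing.assert_array_equal(t, t.T)

    def test_homogeneous_cell_has_no_fluctuations(self, homogeneous_rve):
        """Uniform fields solve the homogeneous cell exactly; each fluctuation
        block vanishes relative to its own physical scale (u in meters, phi in
        volts with the piezo-potential scale e*eps*L/xi, A in T*m)."""
        macro = MacroState(eps_bar=[1e-5, 0, 0, 2e-5, 0, 0])
        d = homogeneous_rve.solve_static(macro)
        g = affine_fields(homogeneous_rve.mesh, macro)
        diff = (d - g).reshape(-1, 7)
        u_scale = np.abs(g.reshape(-1, 7)[:, :3]).max()
        phi_scale = 3e-3 * 1e-5 / 8.85e-12 * 1e-3  # e15*eps*L/xi ~ 3.4 V
        assert np.abs(diff[:, :3]).max() < 1e-10 * u_scale
        assert np.abs(diff[:, 3]).max() < 1e-10 * phi_scale
        assert np.abs(diff[:, 4:]).max() < 1e-15

    def test_periodicity_of_micro_fluctuations(self, healthy_rve):
        """Fluctuation fields agree on paired nodes to machine precision."""
        macro = MacroState(eps_bar=[0, 0, 0, 0, 1e-5, 0])
        d = healthy_rve.solve_static(macro)
        fluct = d - affine_fields(healthy_rve.mesh, macro)
        f = fluct.reshape(-1, 7)
        pairs = healthy_rve.mesh.periodic_pairs
        scale = np.abs(f).max()
        np.testing.assert_allclose(
            f[pairs[:, 0]], f[pairs[:, 1]], atol=1e-10 * scale
        )


class TestAverageFluxes:
    def test_uniform_strain_on_homogeneous_cell(self, homogeneous_rve, bone_tensors):
        eps_bar = np.array([1e-5, -2e-5, 0.5e-5, 1e-6, 0, 0])
        d = homogeneous_rve.solve_static(MacroState(eps_bar=eps_bar))
        fl = homogeneous_rve.average_fluxes(d)
        expected = bone_tensors.C @ eps_bar
        np.testing.assert_allclose(
            fl.sigma_bar, expected, rtol=1e-9, atol=1e-9 * np.abs(expected).max()
        )
        np.testing.assert_allclose(fl.Ddot_bar, 0.0, atol=1e-30)

    def test_phase_weighted_average_of_piecewise_constant_field(
        self, healthy_rve
    ):
        """A field constant per phase averages to the rho_b-weighted mean; here
        probed through the J flux, which is kappa E with kappa nonzero only in
        the marrow."""
        macro = MacroState(E_bar=[1.0, 0.0, 0.0])
        g = affine_fields(healthy_rve.mesh, macro)
        # no solve: force the exact affine state, E = (1,0,0) everywhere
        fl = healthy_rve.average_fluxes(g)
        rho_b = healthy_rve.mesh.bone_volume_fraction()
        kappa1 = 1e4
        np.testing.assert_allclose(
            fl.J_bar, [(1 - rho_b) * kappa1, 0.0, 0.0], rtol=1e-12, atol=1e-9
        )


class TestPerturbationTangents:
    def test_homogeneous_limit_recovers_phase_tensors(self, homogeneous_rve,
                                                      bone_tensors):
        tg = homogeneous_rve.perturbation_tangents()

        def close(actual, expected):
            scale = np.abs(expected).max()
            np.testing.assert_allclose(actual, expected, atol=1e-6 * scale)

        close(tg.C_bar, bone_tensors.C)
        close(tg.xi_bar, bone_tensors.xi)
        close(tg.mu_inv_bar, bone_tensors.mu_inv)
        close(tg.e_bar, bone_tensors.e)
        np.testing.assert_allclose(tg.kappa_bar, bone_tensors.kappa, atol=1e-9)

    def test_no_piezo_coupling_gives_zero_e_bar(self, micro_cfg):
        mat = build_tensors(PhaseMaterial(name="b", E_GPa=22.0, nu=0.32))
        mesh = build_rve_mesh(RVEParams(0.32, 0.36, 1))
        rve = RVEProblem(mesh, mat, mat, micro_cfg)
        tg = rve.perturbation_tangents()
        np.testing.assert_allclose(tg.e_bar, 0.0, atol=1e-12)

    def test_effective_stiffness_symmetry_and_definiteness(self, healthy_rve):
        tg = healthy_rve.perturbation_tangents()
        C = tg.C_bar
        np.testing.assert_allclose(C, C.T, atol=1e-6 * np.abs(C).max())
        assert np.all(np.linalg.eigvalsh(0.5 * (C + C.T)) > 0)
        for M in (tg.xi_bar, tg.mu_inv_bar):
            np.testing.assert_allclose(M, M.T, atol=1e-6 * np.abs(M).max())
            assert np.all(np.linalg.eigvalsh(0.5 * (M + M.T)) > 0)

    def test_tangents_are_cached(self, healthy_rve):
        assert healthy_rve.perturbation_tangents() is healthy_rve.perturbation_tangents()


class TestHillMandel:
    def test_two_phase_gaps_below_threshold(self, healthy_rve):
        """Periodic boundary conditions satisfy the macrohomogeneity condition
        by construction; each work line is probed under its canonical load."""
        cases = [
            (MacroState(eps_bar=[0, 0, 0, 0, 1e-5, 0]), 0),
            (MacroState(E_bar=[1.0, 0, 0]), 1),
            (MacroState(B_bar=[0, 0, 1.0]), 2),
        ]
        for macro, line in cases:
            d = healthy_rve.solve_static(macro)
            gaps = healthy_rve.hill_mandel_residual(macro, d)
            assert gaps[line] < 1e-8

    def test_homogeneous_cell_gaps_tiny(self, homogeneous_rve):
        macro = MacroState(eps_bar=[1e-5, 0, 0, 0, 0, 0])
        d = homogeneous_rve.solve_static(macro)
        gaps = homogeneous_rve.hill_mandel_residual(macro, d)
        assert gaps[0] < 1e-10

    def test_zero_macro_state_gives_zero_gaps(self, healthy_rve):
        d = healthy_rve.solve_static(MacroState())
        gaps = healthy_rve.hill_mandel_residual(MacroState(), d)
        assert gaps == (0.0, 0.0, 0.0)


class TestEffectiveYoungModulus:
    def test_isotropic_identity(self):
        """For an exact isotropic tensor the recovery formula returns E."""
        C = isotropic_stiffness(5e9, 0.3)
        assert effective_young_modulus(C) == pytest.approx(5e9, rel=1e-12)

    def test_singular_denominator_rejected(self):
        C = np.zeros((6, 6))
        with pytest.raises(ZeroDivisionError):
            effective_young_modulus(C)

    def test_healthy_value_and_voigt_reuss_bracketing(
        self, healthy_rve
    ):
        E_eff = effective_young_modulus(healthy_rve.perturbation_tangents().C_bar)
        rho = healthy_rve.mesh.bone_volume_fraction()
        E_b, E_m = 22e9, 2e9
        reuss = 1.0 / (rho / E_b + (1 - rho) / E_m)
        voigt = rho * E_b + (1 - rho) * E_m
        assert reuss < E_eff < voigt
        assert E_eff == pytest.approx(3.89e9, rel=0.02)

    def test_monotone_in_bone_fraction_across_family(
        self, bone_tensors, marrow_tensors, micro_cfg
    ):
        """E_eff strictly increases with the cortical volume fraction."""
        values = []
        for a, b in RVE_FAMILY:
            rve = RVEProblem(
                build_rve_mesh(RVEParams(a, b, 2)), bone_tensors, marrow_tensors,
                micro_cfg,
            )
            values.append(effective_young_modulus(rve.perturbation_tangents().C_bar))
        assert all(x < y for x, y in zip(values, values[1:]))


class TestTransientMicro:
    def test_insulating_everywhere_no_current(self, micro_cfg):
        bone = build_tensors(PhaseMaterial(name="b", E_GPa=22.0, nu=0.32, e15=3e-3))
        mesh = build_rve_mesh(RVEParams(0.32, 0.36, 1))
        rve = RVEProblem(mesh, bone, bone, micro_cfg)
        fluxes, _ = rve.solve_transient(
            [MacroState(eps_bar=[0, 0, 0, 0, 1e-5, 0])] * 3
        )
        for fl in fluxes:
            np.testing.assert_allclose(fl.J_bar, 0.0, atol=1e-20)

    def test_identical_decoupled_phases_give_exact_mixture_stress(self, micro_cfg):
        mat = build_tensors(PhaseMaterial(name="m", E_GPa=5.0, nu=0.25))
        mesh = build_rve_mesh(RVEParams(0.32, 0.36, 1))
        rve = RVEProblem(mesh, mat, mat, micro_cfg)
        eps_bar = np.array([1e-5, 2e-5, -1e-5, 0, 5e-6, 0])
        fluxes, _ = rve.solve_transient([MacroState(eps_bar=eps_bar)] * 2)
        expected = mat.C @ eps_bar
        np.testing.assert_allclose(
            fluxes[-1].sigma_bar, expected,
            rtol=1e-9, atol=1e-9 * np.abs(expected).max(),
        )
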