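"""Microscale driver: periodic RVE solves, volume averaging, effective tangents.

A macroscopic state (strain, electric field, magnetic flux density) is imposed
on the periodic RVE through the additive split of the micro state into an
affine macro part and a periodic fluctuation:

    u = eps_bar . y + u~ ,   phi = -E_bar . y + phi~ ,   A = (B_bar x y)/2 + A~

with the fluctuations linked on opposite faces and pinned to zero at the eight
corner nodes (preventing rigid body motions).  The curl of the affine vector
potential equals B_bar exactly and is divergence-free, so it does not load the
gauge penalty.  Volume averages of the fluxes (sigma, D, D_dot, H, J) are
returned to the macroscale; the five effective tangents follow from forward
differences under unit-entry perturbations of the macro state (increment
1e-8), computed once about the zero state and cached — the only nonlinearity,
the marrow inelastic strain, is negligibly small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .fem import Constraints, CoupledSystem, DofLayout
from .materials import (
    MaterialTensors,
    evaluate_fluxes,
    evolve_inelastic_strain,
    tangent_stiffness,
)
from .rve import BONE, HexMesh, MARROW
from .timestepping import JWHAlphaIntegrator, TimeIntegrationConfig

__all__ = [
    "MacroState",
    "MacroFluxes",
    "EffectiveTangents",
    "voigt_to_tensor",
    "affine_fields",
    "RVEProblem",
    "effective_young_modulus",
]

PERTURBATION = 1e-8  # forward-difference increment of the tangent evaluation


@dataclass(frozen=True)
class MacroState:
    """Macroscale state passed down to the RVE.

    eps_bar: Voigt 6-vector strain (engineering shears, order xx,yy,zz,xy,yz,xz);
    E_bar: electric field [V/m]; B_bar: magnetic flux density [T].
    """

    eps_bar: np.ndarray = field(default_factory=lambda: np.zeros(6))
    E_bar: np.ndarray = field(default_factory=lambda: np.zeros(3))
    B_bar: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "eps_bar", np.asarray(self.eps_bar, dtype=float))
        object.__setattr__(self, "E_bar", np.asarray(self.E_bar, dtype=float))
        object.__setattr__(self, "B_bar", np.asarray(self.B_bar, dtype=float))
        if not (
            np.all(np.isfinite(self.eps_bar))
            and np.all(np.isfinite(self.E_bar))
            and np.all(np.isfinite(self.B_bar))
        ):
            raise ValueError("macro state entries must be finite")


@dataclass(frozen=True)
class MacroFluxes:
    """Volume-averaged flux quantities returned to the macroscale."""

    sigma_bar: np.ndarray
    D_bar: np.ndarray
    Ddot_bar: np.ndarray
    H_bar: np.ndarray
    J_bar: np.ndarray


@dataclass(frozen=True)
class EffectiveTangents:
    """Homogenized moduli from numerical perturbation of the macro state."""

    C_bar: np.ndarray  # 6x6 [Pa]
    xi_bar: np.ndarray  # 3x3 [F/m]
    e_bar: np.ndarray  # 3x6 [As/m^2]
    mu_inv_bar: np.ndarray  # 3x3 [m/H]
    kappa_bar: np.ndarray  # 3x3 [S/m]
    perturbation: float = PERTURBATION


def voigt_to_tensor(eps: np.ndarray) -> np.ndarray:
    """Symmetric strain tensor from the Voigt vector (engineering shears)."""
    e = np.asarray(eps, dtype=float)
    return np.array(
        [
            [e[0], e[3] / 2.0, e[5] / 2.0],
            [e[3] / 2.0, e[1], e[4] / 2.0],
            [e[5] / 2.0, e[4] / 2.0, e[2]],
        ]
    )


def affine_fields(mesh: HexMesh, macro: MacroState) -> np.ndarray:
    """Nodal vector of the affine macro contribution on every node.

    u = eps.y, phi = -E.y, A = (B x y)/2 evaluated at the node coordinates;
    the symmetric-gauge vector potential reproduces B_bar exactly under
    trilinear interpolation and is divergence-free.
    """
    y = mesh.nodes
    g = np.zeros(7 * mesh.n_nodes)
    eps_t = voigt_to_tensor(macro.eps_bar)
    u = y @ eps_t.T
    phi = -(y @ macro.E_bar)
    A = 0.5 * np.cross(np.broadcast_to(macro.B_bar, y.shape), y)
    nodes = np.arange(mesh.n_nodes)
    g[DofLayout.u(nodes)] = u.ravel()
    g[DofLayout.phi(nodes)] = phi
    g[DofLayout.A(nodes)] = A.ravel()
    return g


class RVEProblem:
    """Periodic micro problem on a two-phase bone RVE.

    Parameters
    ----------
    mesh : periodic :class:`~bonefe2.rve.HexMesh` with phase tags.
    bone, marrow : :class:`~bonefe2.materials.MaterialTensors`.
    cfg : time integration settings (dt also scales the viscous tangent).
    gamma : divergence gauge penalty (default 1.0).
    """

    def __init__(
        self,
        mesh: HexMesh,
        bone: MaterialTensors,
        marrow: MaterialTensors,
        cfg: TimeIntegrationConfig,
        gamma: float = 1.0,
    ):
        self.mesh = mesh
        self.cfg = cfg
        self.system = CoupledSystem(
            mesh, {BONE: bone, MARROW: marrow}, gamma=gamma, dt=cfg.dt
        )
        # stationary solves (tangents, Hill-Mandel) are instantaneous elastic
        # responses: dt=0 drops the viscous consistent-tangent correction so
        # the stiffness is consistent with the elastic flux evaluation
        self.static_system = CoupledSystem(
            mesh, {BONE: bone, MARROW: marrow}, gamma=gamma, dt=0.0
        )
        self.constraints = Constraints.build(
            mesh.n_nodes,
            fixed_nodes_all=mesh.corner_nodes,
            periodic_pairs=mesh.periodic_pairs,
        )
        self.volume = self.system.total_volume()
        self._static_solve = None
        self._tangents: EffectiveTangents | None = None

    # -- static solves -----------------------------------------------------
    def solve_static(self, macro: MacroState) -> np.ndarray:
        """Stationary periodic solve under a constant macro state.

        Returns the full nodal vector (affine + fluctuation).  Rates are zero,
        so only the stiffness operator acts.
        """
        T = self.constraints.T
        if self._static_solve is None:
            self._Kr = (T.T @ self.static_system.K @ T).tocsc()
            self._static_solve = spla.factorized(self._Kr)
        g = affine_fields(self.mesh, macro)
        rhs = -(T.T @ (self.static_system.K @ g))
        d_f = self._static_solve(rhs)
        # two rounds of iterative refinement: the mixed-unit blocks span ~20
        # orders of magnitude and a single factorized solve leaves the small
        # (electric) rows several digits short
        for _ in range(2):
            d_f = d_f + self._static_solve(rhs - self._Kr @ d_f)
        return T @ d_f + g

    def average_fluxes(
        self,
        d: np.ndarray,
        v: np.ndarray | None = None,
        vd: np.ndarray | None = None,
        eps_i: np.ndarray | None = None,
    ) -> MacroFluxes:
        """Volume-weighted quadrature averages of (sigma, D, D_dot, H, J)."""
        n = self.system.n_dofs
        v = np.zeros(n) if v is None else v
        vd = np.zeros(n) if vd is None else vd
        eps, epsdot, E, Edot, B, _Adot = self.system.qp_state(d, v, vd)
        w = self.system.qp_weights()
        sig = np.zeros(6)
        D = np.zeros(3)
        Dd = np.zeros(3)
        H = np.zeros(3)
        J = np.zeros(3)
        for iel in range(self.mesh.n_elements):
            tens = self.system.tensors_of(iel)
            for iqp in range(self.system.n_qp):
                ei = None if eps_i is None else eps_i[iel, iqp]
                s, d_, h, j = evaluate_fluxes(
                    eps[iel, iqp], E[iel, iqp], B[iel, iqp], tens, eps_i=ei
                )
                wq = w[iel, iqp]
                sig += wq * s
                D += wq * d_
                Dd += wq * (tens.e @ epsdot[iel, iqp] + tens.xi @ Edot[iel, iqp])
                H += wq * h
                J += wq * j
        V = self.volume
        return MacroFluxes(sig / V, D / V, Dd / V, H / V, J / V)

    # -- effective tangents -------------------------------------------------
    def perturbation_tangents(self, delta: float = PERTURBATION) -> EffectiveTangents:
        """Five effective tangents by forward differences about the zero state.

        One stationary solve per unit-entry perturbation of the macro state
        (6 strain + 3 electric + 3 magnetic columns), all sharing a single
        factorization.  Cached: the same tangents serve every macro point and
        time step.
        """
        if self._tangents is not None and self._tangents.perturbation == delta:
            return self._tangents
        C_bar = np.zeros((6, 6))
        e_bar = np.zeros((3, 6))
        xi_bar = np.zeros((3, 3))
        kappa_bar = np.zeros((3, 3))
        mu_inv_bar = np.zeros((3, 3))
        for i in range(6):
            eps = np.zeros(6)
            eps[i] = delta
            fl = self.average_fluxes(self.solve_static(MacroState(eps_bar=eps)))
            C_bar[:, i] = fl.sigma_bar / delta
            e_bar[:, i] = fl.D_bar / delta
        for i in range(3):
            E = np.zeros(3)
            E[i] = delta
            fl = self.average_fluxes(self.solve_static(MacroState(E_bar=E)))
            xi_bar[:, i] = fl.D_bar / delta
            kappa_bar[:, i] = fl.J_bar / delta
        for i in range(3):
            B = np.zeros(3)
            B[i] = delta
            fl = self.average_fluxes(self.solve_static(MacroState(B_bar=B)))
            mu_inv_bar[:, i] = fl.H_bar / delta
        self._tangents = EffectiveTangents(
            C_bar=C_bar,
            xi_bar=xi_bar,
            e_bar=e_bar,
            mu_inv_bar=mu_inv_bar,
            kappa_bar=kappa_bar,
            perturbation=delta,
        )
        return self._tangents

    # -- Hill-Mandel check ---------------------------------------------------
    def hill_mandel_residual(
        self, macro: MacroState, d: np.ndarray
    ) -> tuple[float, float, float]:
        """Normalized virtual-work gaps of a converged stationary solve.

        Uses the actual micro fields as the admissible variation: the
        mechanical, electric and magnetic lines compare the macro products
        sigma_bar.eps_bar, D_bar.E_bar, B_bar.H_bar with the volume averages
        of the corresponding micro products.  Gaps are normalized by the
        average of the absolute micro products (with a tiny floor), so a zero
        macro state gives 0.
        """
        n = self.system.n_dofs
        eps, _, E, _, B, _ = self.system.qp_state(d, np.zeros(n), np.zeros(n))
        w = self.system.qp_weights()
        fl = self.average_fluxes(d)
        micro = np.zeros(3)
        scale = np.zeros(3)
        for iel in range(self.mesh.n_elements):
            tens = self.system.tensors_of(iel)
            for iqp in range(self.system.n_qp):
                s, d_, h, _ = evaluate_fluxes(
                    eps[iel, iqp], E[iel, iqp], B[iel, iqp], tens
                )
                wq = w[iel, iqp]
                micro += wq * np.array(
                    [s @ eps[iel, iqp], d_ @ E[iel, iqp], B[iel, iqp] @ h]
                )
                scale += wq * np.array(
                    [
                        np.linalg.norm(s) * np.linalg.norm(eps[iel, iqp]),
                        np.linalg.norm(d_) * np.linalg.norm(E[iel, iqp]),
                        np.linalg.norm(B[iel, iqp]) * np.linalg.norm(h),
                    ]
                )
        micro /= self.volume
        scale /= self.volume
        mac = np.array(
            [
                fl.sigma_bar @ macro.eps_bar,
                fl.D_bar @ macro.E_bar,
                macro.B_bar @ fl.H_bar,
            ]
        )
        denom = np.maximum(np.maximum(np.abs(mac), scale), 1e-300)
        gaps = np.abs(micro - mac) / denom
        gaps[scale == 0.0] = 0.0
        return float(gaps[0]), float(gaps[1]), float(gaps[2])

    # -- transient micro solve -----------------------------------------------
    def solve_transient(self, macro_history) -> tuple[list[MacroFluxes], np.ndarray]:
        """Advance the periodic micro problem through a macro-state history.

        ``macro_history`` is a sequence of :class:`MacroState`, one per step.
        The inelastic strain is advanced once per accepted step with the
        explicit Euler rule, using the end-of-step trial stress.  Returns the
        per-step averaged fluxes and the final inelastic strain field.
        """
        integ = JWHAlphaIntegrator(self.system, self.constraints, self.cfg)
        ne, nq = self.mesh.n_elements, self.system.n_qp
        eps_i = np.zeros((ne, nq, 6))
        fluxes: list[MacroFluxes] = []
        marrow_elems = [
            iel
            for iel in range(ne)
            if self.system.tensors_of(iel).mu_v != 0.0
        ]
        for step, macro in enumerate(macro_history):
            g = affine_fields(self.mesh, macro)
            G = self.system.internal_force(eps_i) if marrow_elems else None
            integ.step(g_new=g, G=G)
            full = integ.full_state()
            # commit the explicit inelastic-strain update (trial stress)
            if marrow_elems:
                eps_all, _, _, _, _, _ = self.system.qp_state(full.d, full.v, full.vd)
                for iel in marrow_elems:
                    tens = self.system.tensors_of(iel)
                    for iqp in range(nq):
                        sig_tr = tens.C @ (eps_all[iel, iqp] - eps_i[iel, iqp])
                        eps_i[iel, iqp] = evolve_inelastic_strain(
                            eps_i[iel, iqp], sig_tr, tens.mu_v, self.cfg.dt
                        )
            fluxes.append(
                self.average_fluxes(full.d, full.v, full.vd, eps_i=eps_i)
            )
        self.newton_iterations = integ.newton_iterations
        return fluxes, eps_i


def effective_young_modulus(C_bar: np.ndarray) -> float:
    """Isotropic Young's modulus recovered from the homogenized stiffness.

    ``E_eff = C44 (3 C12 + 2 C44) / (C12 + C44)`` with C12 the first
    off-diagonal and C44 the xy-shear diagonal entry — the Lamé identity
    ``E = mu (3 lambda + 2 mu) / (lambda + mu)`` applied to the homogenized
    tensor.
    """
    C12 = float(C_bar[0, 1])
    C44 = float(C_bar[3, 3])
    if abs(C12 + C44) < 1e-300:
        raise ZeroDivisionError("C12 + C44 = 0: singular modulus recovery")
    return C44 * (3.0 * C12 + 2.0 * C44) / (C12 + C44)
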