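"""Per-phase material tensors and quadrature-point constitutive response.

Cortical bone is a linear piezoelectric, electrically insulating solid; bone
marrow is a viscoelastic (Maxwell-type, volume-preserving inelastic strain),
electrically conducting solid.  Both phases share vacuum-like magnetic
permeability.  Voigt convention: stress carries no engineering factors, strain
carries factor 2 on the shears, component order (xx, yy, zz, xy, yz, xz).

Constitutive laws
-----------------
bone:    sigma = C_b eps - e^T E,   D = e eps + xi_b E,   H = mu^-1 B,  J = 0
marrow:  sigma = C_m (eps - eps_i), D = xi_m E,           H = mu^-1 B,  J = kappa E

The inelastic strain evolves as ``eps_i_dot = mu_v * dev(sigma)`` (traceless by
construction), discretized with one explicit Euler step per time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseMaterial",
    "MaterialTensors",
    "CORTICAL_BONE",
    "BONE_MARROW",
    "build_tensors",
    "isotropic_stiffness",
    "deviatoric",
    "DEV_PROJECTOR",
    "evaluate_fluxes",
    "evolve_inelastic_strain",
    "tangent_stiffness",
]

GPA = 1e9

#: Voigt projector onto the deviatoric stress subspace (shear rows unchanged).
DEV_PROJECTOR = np.eye(6) - np.block(
    [[np.full((3, 3), 1.0 / 3.0), np.zeros((3, 3))], [np.zeros((3, 6))]]
)


@dataclass(frozen=True)
class PhaseMaterial:
    """Material parameters of one phase in the units they are tabulated in.

    E [GPa], nu [-], xi1 [F/m], mu_c [H/m], e15 [As/m^2], kappa1 [S/m],
    mu_v [1/(Pa s)] (rate coefficient of the inelastic strain; zero for bone).
    """

    name: str
    E_GPa: float
    nu: float
    xi1: float = 8.85e-12
    mu_c: float = 1.257e-6
    e15: float = 0.0
    kappa1: float = 0.0
    mu_v: float = 0.0

    def __post_init__(self) -> None:
        if self.E_GPa <= 0.0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")
        if self.xi1 <= 0.0 or self.mu_c <= 0.0:
            raise ValueError("permittivity and permeability must be positive")
        if self.kappa1 < 0.0 or self.mu_v < 0.0:
            raise ValueError("conductivity and viscosity must be non-negative")


def default_marrow_mu_v(dt: float) -> float:
    """Default marrow viscosity rate coefficient, tied to the time step.

    The tabulated value is 0.5*dt in s/GPa; as a rate coefficient in SI this is
    ``0.5 * dt * 1e-9`` per (Pa s).
    """
    return 0.5 * dt * 1e-9


def cortical_bone() -> PhaseMaterial:
    """Default cortical bone phase."""
    return PhaseMaterial(name="bone", E_GPa=22.0, nu=0.32, e15=3.0e-3)


def bone_marrow(dt: float = 1e-3) -> PhaseMaterial:
    """Default bone marrow phase; the viscosity default is tied to ``dt``."""
    return PhaseMaterial(
        name="marrow", E_GPa=2.0, nu=0.3, kappa1=1.0e4, mu_v=default_marrow_mu_v(dt)
    )


CORTICAL_BONE = cortical_bone()
BONE_MARROW = bone_marrow()


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """Isotropic 6x6 stiffness in Voigt notation (engineering shear strains)."""
    if nu >= 0.5:
        raise ValueError("nu = 0.5 gives a singular (incompressible) stiffness")
    f = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    C = np.zeros((6, 6))
    C[:3, :3] = nu
    np.fill_diagonal(C[:3, :3], 1.0 - nu)
    for i in range(3, 6):
        C[i, i] = (1.0 - 2.0 * nu) / 2.0
    return f * C


@dataclass(frozen=True)
class MaterialTensors:
    """SI material tensors of one phase (or a homogenized medium).

    C: 6x6 stiffness [Pa]; xi: 3x3 permittivity [F/m]; mu_inv: 3x3 inverse
    permeability [m/H]; e: 3x6 piezoelectric coupling [As/m^2]; kappa: 3x3
    conductivity [S/m]; mu_v: viscous rate coefficient [1/(Pa s)].
    """

    C: np.ndarray
    xi: np.ndarray
    mu_inv: np.ndarray
    e: np.ndarray
    kappa: np.ndarray
    mu_v: float = 0.0

    @property
    def conducting(self) -> bool:
        return bool(np.any(self.kappa != 0.0))


def build_tensors(mat: PhaseMaterial) -> MaterialTensors:
    """Assemble the SI material tensors of a phase.

    The piezoelectric tensor carries the shear-mode e15 pattern only: +e15 at
    (row 1, col 5) and -e15 at (row 2, col 6) in 1-based indexing, reflecting
    collagen fibers oriented along the z-axis.
    """
    C = isotropic_stiffness(mat.E_GPa * GPA, mat.nu)
    e = np.zeros((3, 6))
    e[0, 4] = mat.e15
    e[1, 5] = -mat.e15
    return MaterialTensors(
        C=C,
        xi=mat.xi1 * np.eye(3),
        mu_inv=(1.0 / mat.mu_c) * np.eye(3),
        e=e,
        kappa=mat.kappa1 * np.eye(3),
        mu_v=mat.mu_v,
    )


def deviatoric(sigma: np.ndarray) -> np.ndarray:
    """Deviatoric part of a Voigt stress (no engineering factors)."""
    return DEV_PROJECTOR @ sigma


def evaluate_fluxes(
    eps: np.ndarray,
    E_field: np.ndarray,
    B_field: np.ndarray,
    tensors: MaterialTensors,
    eps_i: np.ndarray | None = None,
):
    """Constitutive fluxes (sigma, D, H, J) at a quadrature point.

    ``eps_i`` is the inelastic strain (marrow); omitted or zero for bone.
    The piezoelectric blocks obey reciprocity: -e^T enters the stress, +e the
    electric displacement.
    """
    eps_el = eps if eps_i is None else eps - eps_i
    sigma = tensors.C @ eps_el - tensors.e.T @ E_field
    D = tensors.e @ eps + tensors.xi @ E_field
    H = tensors.mu_inv @ B_field
    J = tensors.kappa @ E_field
    return sigma, D, H, J


def evolve_inelastic_strain(
    eps_i_n: np.ndarray, sigma: np.ndarray, mu_v: float, dt: float
) -> np.ndarray:
    """One explicit Euler step of ``eps_i_dot = mu_v * dev(sigma)``.

    The deviatoric projector keeps the trace exactly zero, enforcing volume
    conservation of the inelastic deformation.
    """
    if dt < 0.0:
        raise ValueError("negative time increment")
    return eps_i_n + (dt * mu_v) * deviatoric(sigma)


def tangent_stiffness(
    tensors: MaterialTensors, mu_v: float | None = None, dt: float = 0.0
) -> np.ndarray:
    """Consistent mechanical stiffness tangent of the one-step stress update.

    Bone (mu_v = 0): the elastic stiffness.  Marrow: the explicit-Euler update
    of the inelastic strain makes the end-of-step stress
    ``sigma = C (eps - eps_i_n) - C dt mu_v D_dev C (eps - eps_i_n)``, whose
    strain derivative is ``C - C (dt mu_v D_dev C)``.
    """
    mu_v = tensors.mu_v if mu_v is None else mu_v
    C = tensors.C
    if mu_v == 0.0 or dt == 0.0:
        return C.copy()
    return C - C @ ((dt * mu_v) * DEV_PROJECTOR @ C)
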