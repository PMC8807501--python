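"""JWH generalized-alpha time integration for the coupled first/second-order
system with Newton-Raphson iteration.

The semi-discrete problem ``M v' + C v + K d = F`` (with ``v ~ d'`` enforced
through the scheme's compatibility relation) is advanced with the
single-parameter generalized-alpha family for first-order systems applied
twice.  The scheme parameters derive from the spectral radius at infinity:

    alpha_m = (3 - rho_inf) / (2 (1 + rho_inf))
    alpha_f = 1 / (1 + rho_inf)
    gamma_a = 1/2 + alpha_m - alpha_f

Update relations (auxiliary rate ``dd ~ d'`` kept separately from the system
velocity ``v``), with ``Dt`` the time increment:

    dd_{n+1} = (d_{n+1} - d_n) / (gamma_a Dt) + (1 - 1/gamma_a) dd_n
    v_{n+1}  = v_n + (alpha_m/alpha_f) (dd_{n+1} - dd_n) + (dd_n - v_n)/alpha_f
    vd_{n+1} = (v_{n+1} - v_n) / (gamma_a Dt) + (1 - 1/gamma_a) vd_n

and the residual is evaluated at the generalized midpoints
``d_{n+alpha_f}, v_{n+alpha_f}, vd_{n+alpha_m}``, giving the iteration matrix

    S = alpha_m^2 / (alpha_f gamma_a^2 Dt^2) M
      + alpha_m / (gamma_a Dt) C + alpha_f K .

Because the problem is linear in ``d`` for a frozen inelastic strain, Newton
converges in a single iteration per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TimeIntegrationConfig",
    "alpha_parameters",
    "effective_tangent",
    "SchemeState",
    "JWHAlphaIntegrator",
    "NewtonError",
]


def alpha_parameters(rho_inf: float) -> tuple[float, float, float]:
    """Scheme parameters (alpha_m, alpha_f, gamma_a) from the spectral radius.

    ``rho_inf = 1`` gives the undamped midpoint-like limit (1/2, 1/2, 1/2);
    ``rho_inf = 0`` annihilates the highest frequency in one step.
    """
    if not 0.0 <= rho_inf <= 1.0:
        raise ValueError(f"rho_inf must lie in [0, 1], got {rho_inf}")
    alpha_m = (3.0 - rho_inf) / (2.0 * (1.0 + rho_inf))
    alpha_f = 1.0 / (1.0 + rho_inf)
    gamma_a = 0.5 + alpha_m - alpha_f
    return alpha_m, alpha_f, gamma_a


@dataclass(frozen=True)
class TimeIntegrationConfig:
    """Time integration and Newton settings.

    rho_inf: spectral radius parameter in [0, 1] (default 0.5).
    dt: time increment [s].
    newton_tol: relative residual tolerance of the Newton loop.
    newton_tol_abs: absolute residual tolerance (converged if either holds).
    max_iter: iteration cap per step.
    """

    dt: float
    rho_inf: float = 0.5
    newton_tol: float = 1e-8
    newton_tol_abs: float = 0.0
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        alpha_parameters(self.rho_inf)  # validates rho_inf

    @property
    def alphas(self) -> tuple[float, float, float]:
        return alpha_parameters(self.rho_inf)


def effective_tangent(M, C, K, cfg: TimeIntegrationConfig):
    """Generalized iteration matrix S of the scheme."""
    alpha_m, alpha_f, gamma_a = cfg.alphas
    dt = cfg.dt
    cM = alpha_m**2 / (alpha_f * gamma_a**2 * dt**2)
    cC = alpha_m / (gamma_a * dt)
    return cM * M + cC * C + alpha_f * K


@dataclass
class SchemeState:
    """Discrete state carried between steps: (d, dd, v, vd).

    ``dd`` is the scheme's auxiliary displacement rate, ``v`` the system
    velocity and ``vd`` its rate (the acceleration proxy).
    """

    d: np.ndarray
    dd: np.ndarray
    v: np.ndarray
    vd: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "SchemeState":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))

    def copy(self) -> "SchemeState":
        return SchemeState(
            self.d.copy(), self.dd.copy(), self.v.copy(), self.vd.copy()
        )


def advance_rates(
    state_n: SchemeState, d_new: np.ndarray, cfg: TimeIntegrationConfig
) -> SchemeState:
    """Rates at t_{n+1} from the new displacement via the update relations."""
    alpha_m, alpha_f, gamma_a = cfg.alphas
    dt = cfg.dt
    dd = (d_new - state_n.d) / (gamma_a * dt) + (1.0 - 1.0 / gamma_a) * state_n.dd
    v = (
        state_n.v
        + (alpha_m / alpha_f) * (dd - state_n.dd)
        + (state_n.dd - state_n.v) / alpha_f
    )
    vd = (v - state_n.v) / (gamma_a * dt) + (1.0 - 1.0 / gamma_a) * state_n.vd
    return SchemeState(d=d_new, dd=dd, v=v, vd=vd)


def midpoint_state(
    state_n: SchemeState, state_new: SchemeState, cfg: TimeIntegrationConfig
):
    """Evaluation points (d_{n+af}, v_{n+af}, vd_{n+am}) of the residual."""
    alpha_m, alpha_f, _ = cfg.alphas
    d_af = state_n.d + alpha_f * (state_new.d - state_n.d)
    v_af = state_n.v + alpha_f * (state_new.v - state_n.v)
    vd_am = state_n.vd + alpha_m * (state_new.vd - state_n.vd)
    return d_af, v_af, vd_am


class NewtonError(RuntimeError):
    """Raised when the Newton loop does not converge; carries the history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


class NewtonCriterion:
    """Block-wise relative convergence check for the coupled residual.

    The three fields (u, phi, A) carry residuals of entirely different
    physical units, so a single-norm tolerance is meaningless: the mechanical
    rows would mask the electric ones.  Each block is measured against its own
    reference — the largest first-iteration residual of that block seen during
    the run — and the loop converges when every block has dropped below
    ``newton_tol`` relative to its reference (or below the optional absolute
    floor).  A stagnation guard accepts the iterate when the residual has hit
    the attainable floating-point floor after a substantial drop.
    """

    STAGNATION_ACCEPT = 1e-4  # minimal drop factor to accept a stalled iterate
    FLOOR_FACTOR = 1e3 * np.finfo(float).eps  # roundoff floor multiplier

    def __init__(self, cfg: TimeIntegrationConfig, free_dofs: np.ndarray):
        self.cfg = cfg
        comp = np.asarray(free_dofs) % 7
        self.masks = [comp < 3, comp == 3, comp > 3]
        self.refs = np.zeros(3)

    def block_norms(self, R: np.ndarray) -> np.ndarray:
        return np.array([np.linalg.norm(R[m]) if m.any() else 0.0 for m in self.masks])

    def start_step(self, R: np.ndarray) -> np.ndarray:
        nrm = self.block_norms(R)
        self.refs = np.maximum(self.refs, nrm)
        return nrm

    def converged(self, nrm: np.ndarray, scale: np.ndarray | None = None) -> bool:
        """Block-wise test: relative drop, roundoff floor, or absolute floor.

        ``scale`` is the cancellation-free magnitude of the terms composing
        each block's residual (computed with absolute-value operators); a
        residual below ``FLOOR_FACTOR`` times it is numerically
        indistinguishable from zero.
        """
        tol, tol_abs = self.cfg.newton_tol, self.cfg.newton_tol_abs
        ok = (nrm <= tol * self.refs) | (nrm <= tol_abs)
        if scale is not None:
            ok |= nrm <= self.FLOOR_FACTOR * scale
        return bool(ok.all())

    def stagnated(self, nrm: np.ndarray, prev: np.ndarray) -> bool:
        """No further progress: the attainable floor has been reached."""
        total, prev_total = nrm.sum(), prev.sum()
        if total < 0.5 * prev_total:
            return False
        return bool(
            np.all((nrm <= self.STAGNATION_ACCEPT * self.refs) | (nrm == 0.0))
        )


class JWHAlphaIntegrator:
    """Time stepper for the reduced (constraint-eliminated) coupled system.

    Parameters
    ----------
    system : CoupledSystem with assembled M, C, K.
    constraints : Constraints with prolongation T.
    cfg : TimeIntegrationConfig.

    The full solution is ``d_full = T d_free + g(t)`` with a caller-supplied
    inhomogeneity ``g`` per step (affine macro field or prescribed boundary
    motion).  ``g`` is advanced with the same update relations, so prescribed
    values and their rates are scheme-consistent.  The iteration matrix is
    factorized once (the problem is linear and the tangent state-independent).
    """

    def __init__(self, system, constraints, cfg: TimeIntegrationConfig):
        self.system = system
        self.constraints = constraints
        self.cfg = cfg
        T = constraints.T
        self.Mr = (T.T @ system.M @ T).tocsc()
        self.Cr = (T.T @ system.C @ T).tocsc()
        self.Kr = (T.T @ system.K @ T).tocsc()
        S = effective_tangent(self.Mr, self.Cr, self.Kr, cfg).tocsc()
        # symmetric diagonal equilibration + one refinement pass: the blocks
        # span ~20 decades (stiffness vs permittivity), which otherwise limits
        # the attainable accuracy of the factorized solve
        scal = 1.0 / np.sqrt(np.maximum(np.abs(S.diagonal()), 1e-300))
        D = sp.diags(scal)
        lu = spla.splu((D @ S @ D).tocsc())

        def solve(r, _S=S, _s=scal, _lu=lu):
            x = _s * _lu.solve(_s * r)
            return x + _s * _lu.solve(_s * (r - _S @ x))

        self._solve = solve
        # cancellation-free operators for the roundoff-floor estimate
        self._absM = abs(system.M.tocsr())
        self._absC = abs(system.C.tocsr())
        self._absK = abs(system.K.tocsr())
        n = constraints.n_free
        self.free = SchemeState.zeros(n)
        self.pres = SchemeState.zeros(system.n_dofs)
        self.criterion = NewtonCriterion(cfg, constraints.free_dofs)
        self.newton_iterations: list[int] = []

    # -- state handling ----------------------------------------------------
    def full_state(self, free: SchemeState | None = None, pres=None) -> SchemeState:
        free = self.free if free is None else free
        pres = self.pres if pres is None else pres
        T = self.constraints.T
        return SchemeState(
            d=T @ free.d + pres.d,
            dd=T @ free.dd + pres.dd,
            v=T @ free.v + pres.v,
            vd=T @ free.vd + pres.vd,
        )

    def residual_full(self, d, v, vd, F=None, G=None) -> np.ndarray:
        sysm = self.system
        R = -(sysm.M @ vd) - (sysm.C @ v) - (sysm.K @ d)
        if F is not None:
            R += F
        if G is not None:
            R += G
        return R

    def residual_scale(self, d, v, vd, F=None, G=None) -> np.ndarray:
        """Cancellation-free magnitude of the residual terms (full space)."""
        s = (
            self._absM @ np.abs(vd)
            + self._absC @ np.abs(v)
            + self._absK @ np.abs(d)
        )
        if F is not None:
            s += np.abs(F)
        if G is not None:
            s += np.abs(G)
        return s

    def step(self, g_new: np.ndarray | None = None, F=None, G=None) -> None:
        """Advance one time step with prescribed values ``g_new``.

        ``F`` is the external load vector (full size), ``G`` the internal
        inelastic force; both evaluated at the end of the step and treated as
        constant within it.  Raises :class:`NewtonError` on non-convergence.
        """
        cfg = self.cfg
        pres_n = self.pres
        if g_new is None:
            g_new = pres_n.d
        pres_new = advance_rates(pres_n, np.asarray(g_new, dtype=float), cfg)

        free_n = self.free
        d_free = free_n.d.copy()  # same-displacement predictor
        T = self.constraints.T
        history: list[float] = []
        prev = None
        for it in range(cfg.max_iter + 1):
            free_new = advance_rates(free_n, d_free, cfg)
            fd, fv, fvd = midpoint_state(free_n, free_new, cfg)
            pd, pv, pvd = midpoint_state(pres_n, pres_new, cfg)
            d, v, vd = T @ fd + pd, T @ fv + pv, T @ fvd + pvd
            R = self.residual_full(d, v, vd, F=F, G=G)
            Rr = T.T @ R
            if it == 0:
                nrm = self.criterion.start_step(Rr)
            else:
                nrm = self.criterion.block_norms(Rr)
            scale = self.criterion.block_norms(
                T.T @ self.residual_scale(d, v, vd, F=F, G=G)
            )
            history.append(float(nrm.sum()))
            if self.criterion.converged(nrm, scale):
                break
            if prev is not None and self.criterion.stagnated(nrm, prev):
                break
            if it == cfg.max_iter:
                raise NewtonError(
                    f"Newton did not converge in {cfg.max_iter} iterations "
                    f"(last residual {nrm.sum():.3e})",
                    history,
                )
            d_free = d_free + self._solve(Rr)
            prev = nrm
        self.newton_iterations.append(max(len(history) - 1, 0))
        self.free = advance_rates(free_n, d_free, cfg)
        self.pres = pres_new
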