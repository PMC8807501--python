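"""Trilinear hexahedral coupled element and global assembly.

Seven degrees of freedom per node, node-major global numbering:
``(u_x, u_y, u_z, phi, A_x, A_y, A_z)``.  Equal-order trilinear interpolation
is used for all fields; the magnetic vector potential is stabilized by the
divergence gauge penalty ``gamma``.  All element blocks are integrated with
2x2x2 Gauss quadrature, which is exact for the trilinear bilinear forms on
parallelepiped elements.

The semi-discrete system is ``M d'' + C d' + K d = F`` where M carries only
the A-A permittivity mass, C the conduction and rate couplings, and K the
stiffness/permittivity/curl-curl blocks; see :func:`element_matrices` for the
individual integrands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .materials import MaterialTensors, tangent_stiffness

__all__ = [
    "NDOF",
    "DofLayout",
    "shape_functions",
    "operator_matrices",
    "element_volume",
    "element_matrices",
    "Constraints",
    "CoupledSystem",
]

NDOF = 7  # per-node DOFs: u (3), phi (1), A (3)

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
#: 2x2x2 Gauss points in the reference cube, weight 1 each
GAUSS_POINTS = np.array([[x, y, z] for x in _GP for y in _GP for z in _GP])

# local DOF indices (node-major within the element) of each field block
_IU = np.array([NDOF * a + c for a in range(8) for c in range(3)])
_IPHI = np.array([NDOF * a + 3 for a in range(8)])
_IA = np.array([NDOF * a + 4 + c for a in range(8) for c in range(3)])


class DofLayout:
    """Node-major global numbering with 7 DOFs per node."""

    @staticmethod
    def u(node: np.ndarray) -> np.ndarray:
        return (NDOF * np.asarray(node)[..., None] + np.arange(3)).reshape(-1)

    @staticmethod
    def phi(node: np.ndarray) -> np.ndarray:
        return NDOF * np.asarray(node) + 3

    @staticmethod
    def A(node: np.ndarray) -> np.ndarray:
        return (NDOF * np.asarray(node)[..., None] + 4 + np.arange(3)).reshape(-1)

    @staticmethod
    def all(node: np.ndarray) -> np.ndarray:
        return (NDOF * np.asarray(node)[..., None] + np.arange(NDOF)).reshape(-1)


def shape_functions(xi: np.ndarray):
    """Trilinear shape functions and reference gradients at ``xi``."""
    from .rve import HEX_LOCAL_NODES as L

    g = 0.125 * (1.0 + L * xi)  # (8, 3) one-dimensional factors / 2 each
    N = 8.0 * g[:, 0] * g[:, 1] * g[:, 2]
    dN = np.empty((8, 3))
    dN[:, 0] = L[:, 0] * (1.0 + L[:, 1] * xi[1]) * (1.0 + L[:, 2] * xi[2]) / 8.0
    dN[:, 1] = L[:, 1] * (1.0 + L[:, 0] * xi[0]) * (1.0 + L[:, 2] * xi[2]) / 8.0
    dN[:, 2] = L[:, 2] * (1.0 + L[:, 0] * xi[0]) * (1.0 + L[:, 1] * xi[1]) / 8.0
    return N, dN


def operator_matrices(coords: np.ndarray, xi: np.ndarray):
    """Discrete operators at one reference point of one element.

    Returns ``(B_u, B_grad, B_curl, B_div, N_u, N_phi, N_A, detJ)`` with the
    physical shape-function gradients mapped through the element Jacobian.
    ``B_curl`` is the standard curl operator (so that for the nodal field
    ``A = (-y/2, x/2, 0)`` it returns ``(0, 0, 1)``).
    """
    N, dN_ref = shape_functions(xi)
    J = coords.T @ dN_ref  # (3, 3), dx/dxi
    detJ = np.linalg.det(J)
    if detJ <= 0.0:
        raise ValueError(f"degenerate element Jacobian (detJ = {detJ:g})")
    dN = dN_ref @ np.linalg.inv(J)  # (8, 3) physical gradients

    B_u = np.zeros((6, 24))
    B_grad = dN.T  # (3, 8)
    B_curl = np.zeros((3, 24))
    B_div = np.zeros((1, 24))
    N_u = np.zeros((3, 24))
    N_A = np.zeros((3, 24))
    for a in range(8):
        dx, dy, dz = dN[a]
        c = 3 * a
        B_u[0, c] = dx
        B_u[1, c + 1] = dy
        B_u[2, c + 2] = dz
        B_u[3, c] = dy
        B_u[3, c + 1] = dx
        B_u[4, c + 1] = dz
        B_u[4, c + 2] = dy
        B_u[5, c] = dz
        B_u[5, c + 2] = dx
        # standard curl: (d_y A_z - d_z A_y, d_z A_x - d_x A_z, d_x A_y - d_y A_x)
        B_curl[0, c + 2] = dy
        B_curl[0, c + 1] = -dz
        B_curl[1, c] = dz
        B_curl[1, c + 2] = -dx
        B_curl[2, c + 1] = dx
        B_curl[2, c] = -dy
        B_div[0, c] = dx
        B_div[0, c + 1] = dy
        B_div[0, c + 2] = dz
        for k in range(3):
            N_u[k, c + k] = N[a]
            N_A[k, c + k] = N[a]
    return B_u, B_grad, B_curl, B_div, N_u, N.reshape(1, 8), N_A, detJ


def element_volume(coords: np.ndarray) -> float:
    """Element volume by 2x2x2 Gauss quadrature of the Jacobian determinant."""
    vol = 0.0
    for xi in GAUSS_POINTS:
        _, dN_ref = shape_functions(xi)
        vol += np.linalg.det(coords.T @ dN_ref)
    return float(vol)


def element_matrices(
    coords: np.ndarray,
    tensors: MaterialTensors,
    gamma: float,
    dt: float,
    n_gauss: int | None = None,
    conduction: str = "full",
):
    """All nonzero K, C, M blocks of one element, scattered node-major.

    Returns ``(K_e, C_e, M_e)`` as dense (56, 56) arrays.  The eleven blocks:

    =========  =====================================================
    K_uu       int B_u^T C_tang B_u           (consistent stiffness)
    K_uphi     int B_u^T e^T B_grad           (piezo)
    K_phiu     int B_grad^T e B_u             (piezo)
    K_phiphi   -int B_grad^T xi B_grad        (permittivity, negative)
    K_AA       int B_curl^T mu^-1 B_curl + gamma B_div^T B_div
    K_Aphi     int N_A^T kappa B_grad         (conduction)
    C_uA       int B_u^T e^T N_A              (piezo rate)
    C_Au       -int N_A^T e B_u               (piezo rate)
    C_phiA     -int B_grad^T xi N_A           (permittivity rate)
    C_Aphi     int N_A^T xi B_grad            (permittivity rate)
    C_AA       int N_A^T kappa N_A            (conduction damping)
    M_AA       int N_A^T xi N_A               (permittivity mass)
    =========  =====================================================
    """
    C_tang = tangent_stiffness(tensors, dt=dt)
    K_e = np.zeros((56, 56))
    C_e = np.zeros((56, 56))
    M_e = np.zeros((56, 56))
    points = GAUSS_POINTS
    if n_gauss is not None:  # higher-order rule, used as an independent check
        from numpy.polynomial.legendre import leggauss

        x, w = leggauss(n_gauss)
        points = np.array([[a, b, c] for a in x for b in x for c in x])
        weights = np.array([wa * wb * wc for wa in w for wb in w for wc in w])
    else:
        weights = np.ones(len(points))

    for xi, w in zip(points, weights):
        B_u, B_grad, B_curl, B_div, _, _, N_A, detJ = operator_matrices(coords, xi)
        s = w * detJ
        K_e[np.ix_(_IU, _IU)] += s * (B_u.T @ C_tang @ B_u)
        K_e[np.ix_(_IU, _IPHI)] += s * (B_u.T @ tensors.e.T @ B_grad)
        K_e[np.ix_(_IPHI, _IU)] += s * (B_grad.T @ tensors.e @ B_u)
        K_e[np.ix_(_IPHI, _IPHI)] += -s * (B_grad.T @ tensors.xi @ B_grad)
        K_e[np.ix_(_IA, _IA)] += s * (
            B_curl.T @ tensors.mu_inv @ B_curl + gamma * (B_div.T @ B_div)
        )
        C_e[np.ix_(_IU, _IA)] += s * (B_u.T @ tensors.e.T @ N_A)
        C_e[np.ix_(_IA, _IU)] += -s * (N_A.T @ tensors.e @ B_u)
        C_e[np.ix_(_IPHI, _IA)] += -s * (B_grad.T @ tensors.xi @ N_A)
        C_e[np.ix_(_IA, _IPHI)] += s * (N_A.T @ tensors.xi @ B_grad)
        M_e[np.ix_(_IA, _IA)] += s * (N_A.T @ tensors.xi @ N_A)
        if tensors.conducting:
            # "induced" drops the scalar-potential part of the conduction
            # current (quasi-electrostatic screening closure, macroscale)
            if conduction == "full":
                K_e[np.ix_(_IA, _IPHI)] += s * (N_A.T @ tensors.kappa @ B_grad)
            C_e[np.ix_(_IA, _IA)] += s * (N_A.T @ tensors.kappa @ N_A)
    return K_e, C_e, M_e


@dataclass
class Constraints:
    """Affine constraint map ``d_full = T d_free + g(t)``.

    ``T`` is the sparse prolongation from free DOFs to the full vector: free
    DOFs carry an identity row, periodic slaves a unit entry in their master's
    column, fixed (Dirichlet) DOFs a zero row.  The inhomogeneity ``g`` (the
    affine macro field or prescribed boundary values) is supplied per step by
    the caller.
    """

    T: sp.csr_matrix
    free_dofs: np.ndarray
    fixed_dofs: np.ndarray

    @property
    def n_free(self) -> int:
        return self.T.shape[1]

    @staticmethod
    def build(
        n_nodes: int,
        fixed_nodes_all: np.ndarray | None = None,
        periodic_pairs: np.ndarray | None = None,
        fixed_dofs: np.ndarray | None = None,
    ) -> "Constraints":
        """Build the prolongation for a mix of constraint types.

        ``fixed_nodes_all`` fixes all 7 DOFs of the given nodes (RVE corners);
        ``periodic_pairs`` ties all 7 DOFs of each (slave, master) node pair;
        ``fixed_dofs`` fixes individual global DOFs (macro Dirichlet sets).
        """
        n = NDOF * n_nodes
        master_of = np.arange(n)
        if periodic_pairs is not None and len(periodic_pairs):
            for c in range(NDOF):
                slaves = NDOF * periodic_pairs[:, 0] + c
                masters = NDOF * periodic_pairs[:, 1] + c
                master_of[slaves] = masters
        fixed = np.zeros(n, dtype=bool)
        if fixed_nodes_all is not None and len(fixed_nodes_all):
            fixed[DofLayout.all(np.asarray(fixed_nodes_all))] = True
        if fixed_dofs is not None and len(fixed_dofs):
            fixed[np.asarray(fixed_dofs)] = True
        # a slave of a fixed master is fixed as well
        fixed |= fixed[master_of]

        is_master = (master_of == np.arange(n)) & ~fixed
        free = np.flatnonzero(is_master)
        col_of = -np.ones(n, dtype=int)
        col_of[free] = np.arange(free.size)
        rows, cols = [], []
        for i in range(n):
            m = master_of[i]
            if fixed[i] or col_of[m] < 0:
                continue
            rows.append(i)
            cols.append(col_of[m])
        T = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, free.size)
        )
        return Constraints(T=T, free_dofs=free, fixed_dofs=np.flatnonzero(fixed))


class CoupledSystem:
    """Assembled global operators of the 7-field coupled problem.

    Parameters
    ----------
    mesh : HexMesh
    materials : mapping phase tag -> MaterialTensors (or a single
        MaterialTensors used for every element).
    gamma : divergence gauge penalty.
    dt : time increment; enters only the viscous consistent stiffness.

    The structure of the assembled operators mirrors the continuous problem:
    M is nonzero only in the A-A block, K has no u-A coupling, C has no u-u or
    phi-phi blocks.
    """

    def __init__(self, mesh, materials, gamma: float, dt: float, conduction: str = "full"):
        self.mesh = mesh
        self.gamma = float(gamma)
        self.dt = float(dt)
        if conduction not in ("full", "induced"):
            raise ValueError(f"unknown conduction treatment {conduction!r}")
        self.conduction = conduction
        if isinstance(materials, MaterialTensors):
            materials = {int(p): materials for p in np.unique(mesh.phase)} or {0: materials}
        self.materials = materials
        self.n_dofs = NDOF * mesh.n_nodes
        self._qp_cache = None
        self._assemble()

    def tensors_of(self, elem: int) -> MaterialTensors:
        phase = int(self.mesh.phase[elem]) if len(self.mesh.phase) else 0
        return self.materials[phase]

    def _assemble(self) -> None:
        mesh = self.mesh
        ndloc = NDOF * 8
        ne = mesh.n_elements
        rows = np.empty(ne * ndloc * ndloc, dtype=np.int64)
        cols = np.empty_like(rows)
        kv = np.empty(ne * ndloc * ndloc)
        cv = np.empty_like(kv)
        mv = np.empty_like(kv)
        cache: dict[tuple, tuple] = {}
        for iel, conn in enumerate(mesh.elements):
            coords = mesh.nodes[conn]
            tens = self.tensors_of(iel)
            key = (id(tens), coords.tobytes())
            if key in cache:
                K_e, C_e, M_e = cache[key]
            else:
                K_e, C_e, M_e = element_matrices(
                    coords, tens, self.gamma, self.dt, conduction=self.conduction
                )
                cache[key] = (K_e, C_e, M_e)
            gdof = DofLayout.all(conn)
            sl = slice(iel * ndloc * ndloc, (iel + 1) * ndloc * ndloc)
            rows[sl] = np.repeat(gdof, ndloc)
            cols[sl] = np.tile(gdof, ndloc)
            kv[sl] = K_e.ravel()
            cv[sl] = C_e.ravel()
            mv[sl] = M_e.ravel()
        shape = (self.n_dofs, self.n_dofs)
        self.K = sp.csr_matrix((kv, (rows, cols)), shape=shape)
        self.C = sp.csr_matrix((cv, (rows, cols)), shape=shape)
        self.M = sp.csr_matrix((mv, (rows, cols)), shape=shape)
        for A in (self.K, self.C, self.M):
            A.eliminate_zeros()

    # -- quadrature bookkeeping -------------------------------------------
    def quadrature(self):
        """Cached per-qp operators: (w*detJ, B_u, B_grad, B_curl, B_div, N_A)."""
        if self._qp_cache is None:
            mesh = self.mesh
            ops = []
            for conn in mesh.elements:
                coords = mesh.nodes[conn]
                el = []
                for xi in GAUSS_POINTS:
                    B_u, B_grad, B_curl, B_div, _, _, N_A, detJ = operator_matrices(
                        coords, xi
                    )
                    el.append((detJ, B_u, B_grad, B_curl, B_div, N_A))
                ops.append(el)
            self._qp_cache = ops
        return self._qp_cache

    @property
    def n_qp(self) -> int:
        return len(GAUSS_POINTS)

    def total_volume(self) -> float:
        return sum(qp[0] for el in self.quadrature() for qp in el)

    def internal_force(self, eps_i: np.ndarray) -> np.ndarray:
        """u-block internal force ``int B_u^T C_tang eps_i dV``.

        With the end-of-step stress written as ``C_tang (eps - eps_i_n)``, the
        frozen inelastic strain contributes this vector to the residual.
        """
        G = np.zeros(self.n_dofs)
        qps = self.quadrature()
        for iel, conn in enumerate(self.mesh.elements):
            tens = self.tensors_of(iel)
            if tens.mu_v == 0.0:
                continue
            C_tang = tangent_stiffness(tens, dt=self.dt)
            udof = DofLayout.u(conn)
            for iqp, (detJ, B_u, *_) in enumerate(qps[iel]):
                G[udof] += detJ * (B_u.T @ (C_tang @ eps_i[iel, iqp]))
        return G

    def qp_state(self, d, v, vdot, macro=None):
        """Per-qp state (eps, E, B), rates, and the A-rate from nodal vectors.

        ``macro`` optionally adds constant macroscale contributions
        (MacroState) to every quadrature point; used when the affine part is
        not carried in the nodal vectors.  Returns arrays of shape
        (n_elems, n_qp, .): (eps, epsdot, E, Edot, B, Adot), where ``-Adot``
        is the induced part of the electric field.
        """
        mesh = self.mesh
        ne, nq = mesh.n_elements, self.n_qp
        eps = np.zeros((ne, nq, 6))
        epsdot = np.zeros((ne, nq, 6))
        E = np.zeros((ne, nq, 3))
        Edot = np.zeros((ne, nq, 3))
        B = np.zeros((ne, nq, 3))
        Adot = np.zeros((ne, nq, 3))
        qps = self.quadrature()
        for iel, conn in enumerate(mesh.elements):
            ud, pd, ad = DofLayout.u(conn), DofLayout.phi(conn), DofLayout.A(conn)
            for iqp, (detJ, B_u, B_grad, B_curl, _B_div, N_A) in enumerate(qps[iel]):
                eps[iel, iqp] = B_u @ d[ud]
                epsdot[iel, iqp] = B_u @ v[ud]
                Adot[iel, iqp] = N_A @ v[ad]
                E[iel, iqp] = -B_grad @ d[pd] - Adot[iel, iqp]
                Edot[iel, iqp] = -B_grad @ v[pd] - N_A @ vdot[ad]
                B[iel, iqp] = B_curl @ d[ad]
        if macro is not None:
            eps += macro.eps_bar
            E += macro.E_bar
            B += macro.B_bar
        return eps, epsdot, E, Edot, B, Adot

    def qp_weights(self) -> np.ndarray:
        """(n_elems, n_qp) integration weights (w * detJ)."""
        return np.array([[qp[0] for qp in el] for el in self.quadrature()])
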