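"""Periodic two-phase RVE geometry for cancellous bone.

The representative volume element is a cube of edge ``2a + b`` built from three
orthogonal square rods of cortical bone (cross-section ``b x b``) crossing at the
cube center, embedded in bone marrow.  The lengths parameters ``a`` (marrow
margin) and ``b`` (rod thickness) control the cortical volume fraction

    rho_b = (6 a b^2 + b^3) / (2a + b)^3 .

The mesh is a segment-aligned structured hexahedral grid: each axis is split
into the segments ``[a, b, a]``, each subdivided into ``elements_per_segment``
equal elements, so phase interfaces coincide exactly with element faces.  All
coordinates are stored internally in meters; the constructors accept the
conventional millimeter parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RVEParams",
    "HexMesh",
    "cortical_volume_fraction",
    "build_rve_mesh",
    "periodic_pairs",
]

#: local node ordering of the 8-node hexahedron in the reference cube
#: (counterclockwise bottom face z=-1, then top face z=+1); this fixes the
#: quadrature/assembly contract used throughout the package.
HEX_LOCAL_NODES = np.array(
    [
        [-1.0, -1.0, -1.0],
        [+1.0, -1.0, -1.0],
        [+1.0, +1.0, -1.0],
        [-1.0, +1.0, -1.0],
        [-1.0, -1.0, +1.0],
        [+1.0, -1.0, +1.0],
        [+1.0, +1.0, +1.0],
        [-1.0, +1.0, +1.0],
    ]
)

BONE = 1
MARROW = 0


def cortical_volume_fraction(a: float, b: float) -> float:
    """Volume fraction of cortical bone of the three-rod RVE.

    Parameters
    ----------
    a, b : float
        Lengths parameters (any consistent unit).  ``a`` must be positive,
        ``b`` non-negative.

    Returns
    -------
    float
        ``(6 a b^2 + b^3) / (2a + b)^3``, the exact union volume of the three
        orthogonal ``b x b`` rods divided by the cube volume.
    """
    if a <= 0.0:
        raise ValueError(f"lengths parameter a must be positive, got {a}")
    if b < 0.0:
        raise ValueError(f"lengths parameter b must be non-negative, got {b}")
    edge = 2.0 * a + b
    return (6.0 * a * b**2 + b**3) / edge**3


@dataclass(frozen=True)
class RVEParams:
    """Lengths parameters of the periodic bone RVE.

    Parameters are given in millimeters (the conventional unit of the RVE
    family); ``edge_length_mm`` and the cortical fraction are derived.
    ``elements_per_segment=2`` is the coarse 6^3 mesh, ``4`` the fine 12^3 one.
    """

    a_mm: float
    b_mm: float
    elements_per_segment: int = 2

    def __post_init__(self) -> None:
        if self.a_mm <= 0.0 or self.b_mm <= 0.0:
            raise ValueError("RVE lengths parameters a, b must be positive")
        if self.elements_per_segment < 1:
            raise ValueError("elements_per_segment must be a positive integer")

    @property
    def edge_length_mm(self) -> float:
        return 2.0 * self.a_mm + self.b_mm

    @property
    def edge_length(self) -> float:
        """Edge length in meters."""
        return self.edge_length_mm * 1e-3

    @property
    def rho_b(self) -> float:
        """Cortical bone volume fraction."""
        return cortical_volume_fraction(self.a_mm, self.b_mm)


@dataclass
class HexMesh:
    """Conforming 8-node hexahedral mesh with phase tags and boundary sets.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, coordinates in meters.
    elements : (n_elems, 8) int array, connectivity in the local ordering of
        :data:`HEX_LOCAL_NODES`.
    phase : (n_elems,) int array; ``BONE`` (1) or ``MARROW`` (0).  Empty for
        single-phase macro meshes.
    face_sets : mapping of named boundary node sets ("x-", "x+", ...).
    corner_nodes : int array of the 8 cube corners (periodic meshes only).
    periodic_pairs : (n_pairs, 2) int array of resolved (slave, master) node
        pairs; every slave has exactly one ultimate master.
    """

    nodes: np.ndarray
    elements: np.ndarray
    phase: np.ndarray
    face_sets: dict = field(default_factory=dict)
    corner_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    periodic_pairs: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int)
    )

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_volumes(self) -> np.ndarray:
        """Exact volumes via 2x2x2 Gauss quadrature of the Jacobian."""
        from .fem import element_volume

        return np.array([element_volume(self.nodes[e]) for e in self.elements])

    def bone_volume_fraction(self) -> float:
        vols = self.element_volumes()
        return float(vols[self.phase == BONE].sum() / vols.sum())


def _axis_breakpoints(a: float, b: float, n: int) -> np.ndarray:
    """Node coordinates along one axis: segments [a, b, a], n elements each."""
    pts = [np.linspace(0.0, a, n + 1)]
    pts.append(np.linspace(a, a + b, n + 1)[1:])
    pts.append(np.linspace(a + b, 2 * a + b, n + 1)[1:])
    return np.concatenate(pts)


def build_rve_mesh(params: RVEParams) -> HexMesh:
    """Build the periodic two-phase RVE mesh.

    An element is tagged bone iff at least two of its three segment indices
    fall in the middle (``b``) segment, reproducing the three crossing rods
    whose union volume is ``6ab^2 + b^3``.
    """
    a = params.a_mm * 1e-3
    b = params.b_mm * 1e-3
    n = params.elements_per_segment
    xs = _axis_breakpoints(a, b, n)
    nn = xs.size  # 3n + 1 nodes per axis

    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * nn + j) * nn + k

    ne = 3 * n
    elems = []
    phase = []
    for i in range(ne):
        for j in range(ne):
            for k in range(ne):
                # local ordering: ccw bottom face (z-), then top face (z+)
                elems.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
                seg = (i // n, j // n, k // n)
                n_mid = sum(s == 1 for s in seg)
                phase.append(BONE if n_mid >= 2 else MARROW)

    mesh = HexMesh(
        nodes=nodes,
        elements=np.asarray(elems, dtype=int),
        phase=np.asarray(phase, dtype=int),
    )

    idx = np.arange(nn)
    grid = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"), axis=-1).reshape(-1, 3)
    last = nn - 1
    face_sets = {}
    for d, name in enumerate("xyz"):
        face_sets[f"{name}-"] = np.flatnonzero(grid[:, d] == 0)
        face_sets[f"{name}+"] = np.flatnonzero(grid[:, d] == last)
    mesh.face_sets = face_sets

    on_bnd = (grid == 0) | (grid == last)
    n_bnd = on_bnd.sum(axis=1)
    mesh.corner_nodes = np.flatnonzero(n_bnd == 3)

    # canonical-image pairing: every max-face index is folded to the min face,
    # which resolves edge/corner chains to a single ultimate master in one pass
    is_slave = (grid == last).any(axis=1) & (n_bnd < 3)
    slaves = np.flatnonzero(is_slave)
    canon = np.where(grid[slaves] == last, 0, grid[slaves])
    masters = (canon[:, 0] * nn + canon[:, 1]) * nn + canon[:, 2]
    mesh.periodic_pairs = np.column_stack([slaves, masters])
    return mesh


def periodic_pairs(mesh: HexMesh, tol_rel: float = 1e-12) -> np.ndarray:
    """Resolved (slave, master) pairs by brute-force coordinate matching.

    Works for any geometrically periodic box mesh: nodes on each max face are
    matched to nodes on the opposite min face by their in-face coordinates
    (tolerance ``tol_rel`` times the edge length, translation invariant), and
    multi-face chains are folded until each slave points at a node that is not
    itself a slave.  The 8 box corners are excluded (they are fixed).
    """
    nodes = mesh.nodes
    lo = nodes.min(axis=0)
    hi = nodes.max(axis=0)
    edge = float(np.max(hi - lo))
    tol = tol_rel * edge if edge > 0 else tol_rel

    mapping: dict[int, int] = {}
    for d in range(3):
        minus = np.flatnonzero(np.abs(nodes[:, d] - lo[d]) <= tol)
        plus = np.flatnonzero(np.abs(nodes[:, d] - hi[d]) <= tol)
        if minus.size != plus.size:
            raise ValueError(f"non-matching opposite-face node layouts on axis {d}")
        others = [k for k in range(3) if k != d]
        # match by sorted in-face coordinates (translation invariant)
        order_m = minus[np.lexsort((nodes[minus, others[1]], nodes[minus, others[0]]))]
        order_p = plus[np.lexsort((nodes[plus, others[1]], nodes[plus, others[0]]))]
        if not np.allclose(
            nodes[order_m][:, others], nodes[order_p][:, others], atol=tol, rtol=0.0
        ):
            raise ValueError("non-matching opposite-face node layouts")
        for i, j in zip(order_p, order_m):
            mapping[int(i)] = int(j)

    on_lo = np.abs(nodes - lo) <= tol
    on_hi = np.abs(nodes - hi) <= tol
    corners = np.flatnonzero((on_lo | on_hi).all(axis=1))
    corner_set = set(corners.tolist())

    pairs = []
    for s in sorted(mapping):
        if s in corner_set:
            continue
        m = mapping[s]
        while m in mapping:  # fold edge/corner chains to the ultimate master
            m = mapping[m]
        if m in corner_set or m == s:
            continue
        pairs.append((s, m))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)
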