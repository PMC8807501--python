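"""Legacy-VTK (ASCII) unstructured-grid export/import for hexahedral meshes.

Writes field snapshots viewable in ParaView: point data (u, phi, A) and cell
data (phase, averaged fluxes).  The reader accepts the same legacy ASCII
format for user-supplied macro meshes.  Only the 8-node hexahedron (VTK cell
type 12) is supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .rve import HexMesh

__all__ = ["write_vtk", "read_vtk"]

VTK_HEXAHEDRON = 12


def write_vtk(
    path,
    mesh: HexMesh,
    point_data: dict | None = None,
    cell_data: dict | None = None,
    title: str = "bonefe2 snapshot",
) -> None:
    """Write the mesh and fields as a legacy ASCII VTK unstructured grid.

    ``point_data`` maps names to (n_nodes,) or (n_nodes, 3) arrays;
    ``cell_data`` likewise per element.  Vector fields become VECTORS
    entries, scalars SCALARS.
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for p in mesh.nodes:
        lines.append(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}")
    ne = mesh.n_elements
    lines.append(f"CELLS {ne} {9 * ne}")
    for conn in mesh.elements:
        lines.append("8 " + " ".join(str(int(c)) for c in conn))
    lines.append(f"CELL_TYPES {ne}")
    lines.extend([str(VTK_HEXAHEDRON)] * ne)

    def emit(block: dict, n: int, header: str):
        lines.append(f"{header} {n}")
        for name, arr in block.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                for row in arr:
                    lines.append(f"{row[0]:.12g} {row[1]:.12g} {row[2]:.12g}")
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                for x in arr.reshape(-1):
                    lines.append(f"{x:.12g}")

    if point_data:
        emit(point_data, mesh.n_nodes, "POINT_DATA")
    if cell_data:
        emit(cell_data, ne, "CELL_DATA")
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path) -> HexMesh:
    """Read a legacy ASCII VTK unstructured grid of 8-node hexahedra.

    Returns a :class:`HexMesh` with a ``phase`` cell field if present
    (otherwise all zeros).  Intended for user-supplied macro meshes.
    """
    tokens = Path(path).read_text().split()
    i = 0

    def find(word):
        nonlocal i
        while i < len(tokens) and tokens[i].upper() != word:
            i += 1
        if i == len(tokens):
            raise ValueError(f"VTK parse error: {word} section not found")

    find("POINTS")
    n_pts = int(tokens[i + 1])
    start = i + 3
    nodes = np.array(tokens[start : start + 3 * n_pts], dtype=float).reshape(-1, 3)
    i = start + 3 * n_pts
    find("CELLS")
    n_cells = int(tokens[i + 1])
    start = i + 3
    elems = []
    j = start
    for _ in range(n_cells):
        npts = int(tokens[j])
        if npts != 8:
            raise ValueError("only 8-node hexahedra are supported")
        elems.append([int(t) for t in tokens[j + 1 : j + 9]])
        j += 9
    i = j
    phase = np.zeros(n_cells, dtype=int)
    # optional phase cell field
    for k in range(i, len(tokens)):
        if tokens[k] == "phase":
            # skip "double 1 LOOKUP_TABLE default"
            vals = tokens[k + 5 : k + 5 + n_cells]
            phase = np.array(vals, dtype=float).astype(int)
            break
    return HexMesh(
        nodes=nodes, elements=np.asarray(elems, dtype=int), phase=phase
    )
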