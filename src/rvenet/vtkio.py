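"""Plain-text legacy VTK writers for solution fields.

Writes ASCII legacy VTK (DataFile 2.0): an unstructured hexahedral grid for
the matrix (point displacements, cell stress/von Mises) and a polydata line
set for the fiber network (point displacements, cell axial forces). The
legacy ASCII dialect is simple enough to emit directly and is readable by
ParaView and by the VTK/pyvista stack.
"""

from __future__ import annotations

import numpy as np


def _write_points(fh, points: np.ndarray) -> None:
    fh.write(f"POINTS {len(points)} double\n")
    for p in points:
        fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def _write_vectors(fh, name: str, vectors: np.ndarray) -> None:
    fh.write(f"VECTORS {name} double\n")
    for v in vectors:
        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")


def _write_scalars(fh, name: str, values: np.ndarray) -> None:
    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
    for v in values:
        fh.write(f"{v:.9g}\n")


def write_vtk_hex_grid(
    path,
    node_positions: np.ndarray,
    elements: np.ndarray,
    point_vectors: dict[str, np.ndarray] | None = None,
    cell_scalars: dict[str, np.ndarray] | None = None,
    cell_tensors: dict[str, np.ndarray] | None = None,
) -> None:
    """Hexahedral unstructured grid with optional point/cell data.

    ``cell_tensors`` values are (nel, 6) stress 6-vectors (xx,yy,zz,xy,yz,zx)
    written as full symmetric 3x3 tensors.
    """
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\nrvenet matrix solution\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        _write_points(fh, node_positions)
        nel = len(elements)
        fh.write(f"CELLS {nel} {9 * nel}\n")
        for conn in elements:
            fh.write("8 " + " ".join(str(int(c)) for c in conn) + "\n")
        fh.write(f"CELL_TYPES {nel}\n")
        fh.write("\n".join(["12"] * nel) + "\n")
        if point_vectors:
            fh.write(f"POINT_DATA {len(node_positions)}\n")
            for name, vec in point_vectors.items():
                _write_vectors(fh, name, vec)
        if cell_scalars or cell_tensors:
            fh.write(f"CELL_DATA {nel}\n")
            for name, vals in (cell_scalars or {}).items():
                _write_scalars(fh, name, vals)
            for name, s in (cell_tensors or {}).items():
                fh.write(f"TENSORS {name} double\n")
                for xx, yy, zz, xy, yz, zx in s:
                    fh.write(f"{xx:.9g} {xy:.9g} {zx:.9g}\n")
                    fh.write(f"{xy:.9g} {yy:.9g} {yz:.9g}\n")
                    fh.write(f"{zx:.9g} {yz:.9g} {zz:.9g}\n")


def write_vtk_polylines(
    path,
    node_positions: np.ndarray,
    lines: np.ndarray,
    point_vectors: dict[str, np.ndarray] | None = None,
    cell_scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Fiber network (or beam mesh) as VTK polydata line segments."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\nrvenet fiber network\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        _write_points(fh, node_positions)
        nl = len(lines)
        fh.write(f"LINES {nl} {3 * nl}\n")
        for a, b in lines:
            fh.write(f"2 {int(a)} {int(b)}\n")
        if point_vectors:
            fh.write(f"POINT_DATA {len(node_positions)}\n")
            for name, vec in point_vectors.items():
                _write_vectors(fh, name, vec)
        if cell_scalars:
            fh.write(f"CELL_DATA {nl}\n")
            for name, vals in cell_scalars.items():
                _write_scalars(fh, name, vals)
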