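"""Geometry of the cubic representative volume element (RVE).

All lengths are micrometres throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RVEGeometry:
    """Cubic RVE of a collagen scaffold.

    Parameters
    ----------
    edge_length
        Edge of the cube in micrometres. The default 10 µm cube is the
        baseline sample size used for all scaffold simulations.
    mesh_divisions
        Number of hexahedral matrix elements along each edge. The baseline
        matrix mesh uses 50 divisions (125,000 brick elements); coarser
        meshes are used for exploratory and scaled-down runs.
    """

    edge_length: float = 10.0
    mesh_divisions: int = 50

    def __post_init__(self) -> None:
        if not self.edge_length > 0:
            raise ValueError(f"edge_length must be positive, got {self.edge_length}")
        if int(self.mesh_divisions) != self.mesh_divisions or self.mesh_divisions < 1:
            raise ValueError(
                f"mesh_divisions must be a positive integer, got {self.mesh_divisions}"
            )

    @property
    def spacing(self) -> float:
        """Hexahedral element edge length in µm."""
        return self.edge_length / self.mesh_divisions

    @property
    def face_area(self) -> float:
        """Area of one cube face in µm²."""
        return self.edge_length**2

    @property
    def volume(self) -> float:
        """Cube volume in µm³."""
        return self.edge_length**3
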