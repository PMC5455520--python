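"""Linear-elastic 3D beam (space-frame) elements for the fibers.

Euler-Bernoulli beams with axial, bending and torsional stiffness; each
node carries 3 translations and 3 rotations. Internal force/stiffness units
follow the package convention (µm, nN, kPa; 1 nN/µm² = 1 kPa), with material
moduli given in Pa at the API surface.

Global DOF layout used by :func:`assemble_fiber_stiffness`: translations of
all beam nodes first (3 per node), then rotations of all beam nodes — this
matches the condensation applied by the coupling solver, which slaves the
translations to the matrix displacement field while keeping rotations as
independent unknowns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import BeamMesh

PA_TO_KPA = 1e-3


@dataclass(frozen=True)
class FiberMaterial:
    """Collagen fiber material: linear elastic, E = 50 MPa by default."""

    youngs_modulus: float = 5.0e7  # Pa
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("fiber Young's modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("fiber Poisson ratio must be in [0, 0.5)")

    @property
    def shear_modulus(self) -> float:
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))


@dataclass(frozen=True)
class BeamSection:
    """Circular fiber cross-section; derived properties follow from the diameter."""

    diameter: float = 0.062  # µm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("section diameter must be positive")

    @property
    def area(self) -> float:
        """Cross-section area, µm²."""
        return math.pi * self.diameter**2 / 4.0

    @property
    def bending_inertia(self) -> float:
        """Second moment of area, µm⁴."""
        return math.pi * self.diameter**4 / 64.0

    @property
    def torsion_constant(self) -> float:
        """Polar moment for a circular section, µm⁴."""
        return math.pi * self.diameter**4 / 32.0


def _local_stiffness(L, EA, EI, GJ):
    """12x12 Euler-Bernoulli frame stiffness in local coordinates.

    Local DOF order [ux1,uy1,uz1,rx1,ry1,rz1, ux2,uy2,uz2,rx2,ry2,rz2],
    local x along the beam axis. Supports batched L/EA/EI/GJ arrays.
    """
    L = np.asarray(L, dtype=float)
    shape = L.shape
    K = np.zeros(shape + (12, 12))
    ka = EA / L
    kt = GJ / L
    b12 = 12.0 * EI / L**3
    b6 = 6.0 * EI / L**2
    b4 = 4.0 * EI / L
    b2 = 2.0 * EI / L

    K[..., 0, 0] = K[..., 6, 6] = ka
    K[..., 0, 6] = K[..., 6, 0] = -ka
    K[..., 3, 3] = K[..., 9, 9] = kt
    K[..., 3, 9] = K[..., 9, 3] = -kt

    # bending in the local x-y plane: (uy1, rz1, uy2, rz2)
    for (i, j), v in {
        (1, 1): b12, (1, 5): b6, (1, 7): -b12, (1, 11): b6,
        (5, 5): b4, (5, 7): -b6, (5, 11): b2,
        (7, 7): b12, (7, 11): -b6,
        (11, 11): b4,
    }.items():
        K[..., i, j] = v
        K[..., j, i] = v
    # bending in the local x-z plane: (uz1, ry1, uz2, ry2) with opposite signs
    for (i, j), v in {
        (2, 2): b12, (2, 4): -b6, (2, 8): -b12, (2, 10): -b6,
        (4, 4): b4, (4, 8): b6, (4, 10): b2,
        (8, 8): b12, (8, 10): b6,
        (10, 10): b4,
    }.items():
        K[..., i, j] = v
        K[..., j, i] = v
    return K


def _element_axes(d: np.ndarray) -> np.ndarray:
    """Batched local triads: rows (e_x, e_y, e_z) with e_x along the beam."""
    d = np.atleast_2d(d)
    L = np.linalg.norm(d, axis=1, keepdims=True)
    ex = d / L
    # reference direction: global axis least aligned with the beam
    ref = np.zeros_like(ex)
    ref[np.arange(len(ex)), np.argmin(np.abs(ex), axis=1)] = 1.0
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey, axis=1, keepdims=True)
    ez = np.cross(ex, ey)
    return np.stack([ex, ey, ez], axis=1)


def beam_element_stiffness(
    node_a: np.ndarray,
    node_b: np.ndarray,
    section: BeamSection,
    material: FiberMaterial,
) -> np.ndarray:
    """Global-frame 12x12 stiffness of one beam element (nN, µm units)."""
    node_a = np.asarray(node_a, dtype=float)
    node_b = np.asarray(node_b, dtype=float)
    d = node_b - node_a
    L = float(np.linalg.norm(d))
    if L <= 0:
        raise ValueError("degenerate beam element: coincident nodes")
    E = material.youngs_modulus * PA_TO_KPA
    G = material.shear_modulus * PA_TO_KPA
    Kl = _local_stiffness(
        L, E * section.area, E * section.bending_inertia, G * section.torsion_constant
    )
    R = _element_axes(d[None, :])[0]
    Lam = np.kron(np.eye(4), R)
    return Lam.T @ Kl @ Lam


def _batched_global_stiffness(
    beam_mesh: BeamMesh, section: BeamSection, material: FiberMaterial
) -> np.ndarray:
    """Global-frame element stiffnesses (ne, 12, 12), vectorized."""
    pos = beam_mesh.node_positions
    conn = beam_mesh.elements
    d = pos[conn[:, 1]] - pos[conn[:, 0]]
    L = np.linalg.norm(d, axis=1)
    if np.any(L <= 0):
        raise ValueError("degenerate beam element: coincident nodes")
    ne = len(conn)
    E = material.youngs_modulus * PA_TO_KPA
    G = material.shear_modulus * PA_TO_KPA
    Kl = _local_stiffness(
        L, E * section.area, E * section.bending_inertia, G * section.torsion_constant
    )
    R = _element_axes(d)  # (ne, 3, 3)
    Lam = np.zeros((ne, 12, 12))
    for blk in range(4):
        Lam[:, 3 * blk : 3 * blk + 3, 3 * blk : 3 * blk + 3] = R
    return np.einsum("eji,ejk,ekl->eil", Lam, Kl, Lam, optimize=True)


def assemble_fiber_stiffness(
    beam_mesh: BeamMesh, section: BeamSection, material: FiberMaterial
) -> sp.csr_matrix:
    """Assemble the fiber-network stiffness, shape (6N, 6N).

    DOF order: translations [3N] then rotations [3N], N = number of beam
    nodes. Vectorized over elements.
    """
    n = beam_mesh.num_nodes
    ne = beam_mesh.num_elements
    if ne == 0:
        return sp.csr_matrix((6 * n, 6 * n))
    conn = beam_mesh.elements
    Kg = _batched_global_stiffness(beam_mesh, section, material)

    # global dof index per local dof: node a/b translations then rotations
    a, b = conn[:, 0], conn[:, 1]
    dofs = np.empty((ne, 12), dtype=np.int64)
    for c in range(3):
        dofs[:, 0 + c] = 3 * a + c
        dofs[:, 3 + c] = 3 * n + 3 * a + c
        dofs[:, 6 + c] = 3 * b + c
        dofs[:, 9 + c] = 3 * n + 3 * b + c
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    K = sp.coo_matrix((Kg.ravel(), (rows, cols)), shape=(6 * n, 6 * n))
    return K.tocsr()


def condensed_fiber_stiffness(
    beam_mesh: BeamMesh,
    section: BeamSection,
    material: FiberMaterial,
    reg_factor: float = 1e-9,
) -> sp.csr_matrix:
    """Fiber stiffness on the translational DOFs only, shape (3N, 3N).

    Rotational DOFs are eliminated by exact static condensation per fiber
    segment: each straight fiber is a continuous beam whose end and interior
    rotations carry no external load, so the Schur complement on the
    translations is the exact stiffness felt by the embedding. Rotations are
    kept segment-local, i.e. fiber crossings transmit forces but not
    moments (a moment-free entanglement joint rather than a welded
    crosslink). The free-twist mode of each segment is neutralized by a
    vanishing diagonal regularization (``reg_factor`` times the largest
    rotational diagonal) before the Schur solve; it has no translational
    coupling and does not affect the result.
    """
    n = beam_mesh.num_nodes
    ne = beam_mesh.num_elements
    if ne == 0:
        return sp.csr_matrix((3 * n, 3 * n))
    conn = beam_mesh.elements
    Kg = _batched_global_stiffness(beam_mesh, section, material)
    t_idx = np.array([0, 1, 2, 6, 7, 8])
    r_idx = np.array([3, 4, 5, 9, 10, 11])

    rows_all, cols_all, vals_all = [], [], []
    parents = beam_mesh.parent_segment
    order = np.argsort(parents, kind="stable")
    boundaries = np.flatnonzero(np.diff(parents[order])) + 1
    groups = np.split(order, boundaries)
    for els in groups:
        # chain node list in order; elements of one parent are consecutive
        chain = np.concatenate([[conn[els[0], 0]], conn[els, 1]])
        m = len(chain)
        local = {node: i for i, node in enumerate(chain)}
        Ktt = np.zeros((3 * m, 3 * m))
        Ktr = np.zeros((3 * m, 3 * m))
        Krr = np.zeros((3 * m, 3 * m))
        for e in els:
            a, b = local[conn[e, 0]], local[conn[e, 1]]
            sl = np.r_[3 * a : 3 * a + 3, 3 * b : 3 * b + 3]
            Ke = Kg[e]
            Ktt[np.ix_(sl, sl)] += Ke[np.ix_(t_idx, t_idx)]
            Ktr[np.ix_(sl, sl)] += Ke[np.ix_(t_idx, r_idx)]
            Krr[np.ix_(sl, sl)] += Ke[np.ix_(r_idx, r_idx)]
        reg = reg_factor * Krr.diagonal().max()
        Krr[np.diag_indices_from(Krr)] += reg
        Keff = Ktt - Ktr @ np.linalg.solve(Krr, Ktr.T)
        gdofs = (3 * chain[:, None] + np.arange(3)[None, :]).ravel()
        rows_all.append(np.repeat(gdofs, 3 * m))
        cols_all.append(np.tile(gdofs, 3 * m))
        vals_all.append(Keff.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(3 * n, 3 * n),
    ).tocsr()
    return (K + K.T) * 0.5


def fiber_axial_forces(
    beam_mesh: BeamMesh,
    section: BeamSection,
    material: FiberMaterial,
    translations: np.ndarray,
) -> np.ndarray:
    """Per-element axial force in nN (tension positive).

    ``translations`` is an (N, 3) array of beam-node displacements in µm.
    """
    u = np.asarray(translations, dtype=float).reshape(-1, 3)
    if beam_mesh.num_elements == 0:
        return np.zeros(0)
    pos = beam_mesh.node_positions
    conn = beam_mesh.elements
    d = pos[conn[:, 1]] - pos[conn[:, 0]]
    L = np.linalg.norm(d, axis=1)
    ex = d / L[:, None]
    du = u[conn[:, 1]] - u[conn[:, 0]]
    EA = material.youngs_modulus * PA_TO_KPA * section.area
    return EA * np.einsum("ij,ij->i", du, ex) / L
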