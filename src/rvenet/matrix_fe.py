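"""Hexahedral finite elements for the nearly-incompressible neo-Hookean matrix.

The interfibrillar matrix is a neo-Hookean solid with strain energy
W = (µ/2)(Ī₁ − 3) + (κ/2)(J̄ − 1)², where Ī₁ = J^(−2/3) tr(C) is the
isochoric first invariant of the right Cauchy–Green tensor and the
volumetric penalty with κ ≫ µ enforces near-incompressibility. Volumetric
locking is controlled by a mean-dilatation treatment: in the linearized
element the volumetric strain is element-averaged (B-bar), and in the
finite-strain element the penalty acts on the element-average Jacobian J̄.

Two element paths are provided:

* a linearized B-bar stiffness for the regular grid (one 24×24 matrix
  shared by all elements — the default analysis mode), and
* a finite-strain internal force with an exact tangent obtained by
  complex-step differentiation of the analytic force (used by the Newton
  solver and by consistency tests).

Units: coordinates µm, forces nN, moduli kPa internally; the public
material holds Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RVEGeometry

PA_TO_KPA = 1e-3

# trilinear brick node order (VTK hexahedron): natural-coordinate signs
_SIGNS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_GP = np.array(
    [[sx / np.sqrt(3), sy / np.sqrt(3), sz / np.sqrt(3)] for sx, sy, sz in _SIGNS]
)


class InvertedElementError(RuntimeError):
    """Deformation gradient with non-positive determinant."""


@dataclass(frozen=True)
class MatrixMaterial:
    """Nearly-incompressible neo-Hookean matrix.

    ``shear_modulus`` in Pa; the bulk modulus is ``bulk_ratio`` times the
    shear modulus (default 1e4, incompressibility error < 0.1% in the
    modulus). ``shear_modulus = 0`` requests the matrix-free case; the
    solver then substitutes a vanishing stabilization stiffness so the
    fiber network can still be loaded through the embedding mesh.
    """

    shear_modulus: float  # Pa
    bulk_ratio: float = 1.0e4

    def __post_init__(self) -> None:
        if self.shear_modulus < 0:
            raise ValueError("matrix shear modulus must be non-negative")
        if self.bulk_ratio < 1.0e3:
            raise ValueError("bulk_ratio must be at least 1e3 for near-incompressibility")

    @property
    def bulk_modulus(self) -> float:
        return self.bulk_ratio * self.shear_modulus

    @property
    def youngs_modulus_incompressible(self) -> float:
        """Small-strain Young's modulus 9κµ/(3κ+µ) → 3µ as κ/µ → ∞, Pa."""
        mu, kappa = self.shear_modulus, self.bulk_modulus
        if mu == 0:
            return 0.0
        return 9.0 * kappa * mu / (3.0 * kappa + mu)


@dataclass
class HexMesh:
    """Structured 8-node brick mesh of the cubic RVE."""

    node_positions: np.ndarray
    elements: np.ndarray
    divisions_per_edge: int
    edge_length: float

    @property
    def num_nodes(self) -> int:
        return len(self.node_positions)

    @property
    def num_elements(self) -> int:
        return len(self.elements)

    @property
    def spacing(self) -> float:
        return self.edge_length / self.divisions_per_edge


def build_hex_mesh(geometry: RVEGeometry) -> HexMesh:
    """Regular n×n×n brick mesh over the RVE cube."""
    n = geometry.mesh_divisions
    L = geometry.edge_length
    coords_1d = np.linspace(0.0, L, n + 1)
    zz, yy, xx = np.meshgrid(coords_1d, coords_1d, coords_1d, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def nid(i, j, k):
        return i + (n + 1) * (j + (n + 1) * k)

    e = np.arange(n**3)
    i, j, k = e % n, (e // n) % n, e // n**2  # x fastest: element id = i + n(j + nk)
    elements = np.column_stack(
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
    ).astype(np.int64)
    return HexMesh(nodes, elements, n, L)


def cauchy_stress(deformation_gradient: np.ndarray, material: MatrixMaterial) -> np.ndarray:
    """Cauchy stress (Pa) of the nearly-incompressible neo-Hookean solid.

    σ = (µ/J) dev(B̄) + κ(J − 1) I with B̄ = J^(−2/3) F Fᵀ.
    """
    F = np.asarray(deformation_gradient, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise InvertedElementError(f"det(F) = {J} <= 0")
    mu = material.shear_modulus
    kappa = material.bulk_modulus
    Bbar = J ** (-2.0 / 3.0) * (F @ F.T)
    dev = Bbar - np.trace(Bbar) / 3.0 * np.eye(3)
    return mu / J * dev + kappa * (J - 1.0) * np.eye(3)


def shape_gradients_natural(xi: np.ndarray) -> np.ndarray:
    """dN/dξ for the 8 trilinear shape functions at natural point xi, (8, 3)."""
    s = _SIGNS
    g = np.empty((8, 3))
    g[:, 0] = s[:, 0] * (1 + xi[1] * s[:, 1]) * (1 + xi[2] * s[:, 2]) / 8.0
    g[:, 1] = (1 + xi[0] * s[:, 0]) * s[:, 1] * (1 + xi[2] * s[:, 2]) / 8.0
    g[:, 2] = (1 + xi[0] * s[:, 0]) * (1 + xi[1] * s[:, 1]) * s[:, 2] / 8.0
    return g


def shape_functions(xi: np.ndarray) -> np.ndarray:
    s = _SIGNS
    return (
        (1 + xi[0] * s[:, 0]) * (1 + xi[1] * s[:, 1]) * (1 + xi[2] * s[:, 2]) / 8.0
    )


def _bmatrix(dNdx: np.ndarray) -> np.ndarray:
    """6×24 engineering-strain B matrix (rows xx, yy, zz, xy, yz, zx)."""
    B = np.zeros((6, 24))
    for i in range(8):
        gx, gy, gz = dNdx[i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def _elasticity_matrix(mu: float, kappa: float) -> np.ndarray:
    """Isotropic small-strain D (6×6, engineering shear strains)."""
    lam = kappa - 2.0 * mu / 3.0
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[:3, :3] += 2.0 * mu * np.eye(3)
    D[3:, 3:] = mu * np.eye(3)
    return D


def _bbar_matrices(h: float):
    """B-bar matrices at the 8 Gauss points and the centroid for a cube of edge h."""
    scale = 2.0 / h  # dξ/dx
    dNdx_gp = [shape_gradients_natural(xi) * scale for xi in _GP]
    dNdx_mean = sum(dNdx_gp) / len(dNdx_gp)
    Bs = []
    for dNdx in dNdx_gp:
        B = _bmatrix(dNdx)
        Bdil = np.zeros_like(B)
        for i in range(8):
            for d in range(3):
                corr = (dNdx_mean[i, d] - dNdx[i, d]) / 3.0
                Bdil[0:3, 3 * i + d] += corr
        Bs.append(B + Bdil)
    Bc = _bmatrix(dNdx_mean)  # centroid operator (B = B-bar there)
    return Bs, Bc


def hex_bbar_stiffness(h: float, mu_kpa: float, kappa_kpa: float) -> np.ndarray:
    """Linearized B-bar stiffness (24×24) of a cube element with edge h (µm).

    Moduli in kPa; the result is shared by every element of the regular grid.
    """
    Bs, _ = _bbar_matrices(h)
    D = _elasticity_matrix(mu_kpa, kappa_kpa)
    wJ = (h / 2.0) ** 3
    K = np.zeros((24, 24))
    for B in Bs:
        K += wJ * B.T @ D @ B
    return 0.5 * (K + K.T)


def centroid_stress_operator(h: float, mu_kpa: float, kappa_kpa: float) -> np.ndarray:
    """6×24 operator mapping element displacements to centroid stress (kPa)."""
    _, Bc = _bbar_matrices(h)
    return _elasticity_matrix(mu_kpa, kappa_kpa) @ Bc


def von_mises(stress6: np.ndarray) -> np.ndarray:
    """Von Mises stress from stress 6-vectors (rows xx,yy,zz,xy,yz,zx)."""
    s = np.atleast_2d(stress6)
    sx, sy, sz, sxy, syz, szx = (s[:, i] for i in range(6))
    vm = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )
    return vm if stress6.ndim > 1 else vm[0]


# ---------------------------------------------------------------------------
# finite-strain element (mean-dilatation volumetric term)
# ---------------------------------------------------------------------------


def _precompute_isoparametric(coords: np.ndarray):
    """Per-Gauss-point spatial shape gradients and integration weights."""
    dNdx_list, wdet = [], []
    for xi in _GP:
        dNdxi = shape_gradients_natural(xi)
        Jmat = coords.T @ dNdxi  # (3,3): dx/dξ
        det = np.linalg.det(Jmat)
        if det <= 0:
            raise InvertedElementError("non-positive isoparametric Jacobian")
        dNdx_list.append(dNdxi @ np.linalg.inv(Jmat))
        wdet.append(det)  # unit Gauss weights
    return np.array(dNdx_list), np.array(wdet)


def element_internal_force(
    coords: np.ndarray, disp: np.ndarray, mu_kpa: float, kappa_kpa: float
) -> np.ndarray:
    """Internal force (24-vector, nN) of one finite-strain neo-Hookean hex.

    Mean-dilatation formulation: deviatoric energy integrated pointwise,
    volumetric penalty applied to the element-average Jacobian. Implemented
    with complex-safe operations so the tangent can be obtained by
    complex-step differentiation.
    """
    coords = np.asarray(coords, dtype=float).reshape(8, 3)
    U = np.asarray(disp).reshape(8, 3)
    dNdx, wdet = _precompute_isoparametric(coords)
    V = wdet.sum()
    dtype = complex if np.iscomplexobj(U) else float
    f = np.zeros((8, 3), dtype=dtype)

    Fs, Finvs, Js = [], [], []
    for g in range(8):
        F = np.eye(3, dtype=dtype) + U.T @ dNdx[g]
        J = np.linalg.det(F)
        if dtype is float and J.real <= 0:
            raise InvertedElementError("inverted element during evaluation")
        Fs.append(F)
        Finvs.append(np.linalg.inv(F))
        Js.append(J)
    Jbar = sum(wdet[g] * Js[g] for g in range(8)) / V

    for g in range(8):
        F, Finv, J = Fs[g], Finvs[g], Js[g]
        I1 = np.trace(F @ F.T)
        # deviatoric first Piola-Kirchhoff stress
        P = mu_kpa * J ** (-2.0 / 3.0) * (F - I1 / 3.0 * Finv.T)
        # mean-dilatation volumetric contribution
        P = P + kappa_kpa * (Jbar - 1.0) * J * Finv.T
        f += wdet[g] * dNdx[g] @ P.T
    return f.reshape(24)


def element_internal_force_and_tangent(
    coords: np.ndarray, disp: np.ndarray, material: MatrixMaterial
) -> tuple[np.ndarray, np.ndarray]:
    """Internal force (nN) and consistent 24×24 tangent (nN/µm) of one hex.

    The tangent is the exact linearization of the force, computed by
    complex-step differentiation (step 1e-30), and therefore matches a
    finite-difference check of the force to numerical precision.
    """
    mu = material.shear_modulus * PA_TO_KPA
    kappa = material.bulk_modulus * PA_TO_KPA
    u = np.asarray(disp, dtype=float).reshape(24)
    f = element_internal_force(coords, u, mu, kappa)
    h = 1e-30
    K = np.empty((24, 24))
    for k in range(24):
        up = u.astype(complex)
        up[k] += 1j * h
        K[:, k] = element_internal_force(coords, up, mu, kappa).imag / h
    return f, 0.5 * (K + K.T)


# ---------------------------------------------------------------------------
# batched finite-strain routines for the regular grid (all elements congruent)
# ---------------------------------------------------------------------------


class RegularGridKinematics:
    """Shared isoparametric data for the congruent cube elements of the grid."""

    def __init__(self, h: float):
        self.h = h
        scale = 2.0 / h
        self.dNdx = np.array([shape_gradients_natural(xi) * scale for xi in _GP])  # (8gp,8,3)
        self.wdet = np.full(8, (h / 2.0) ** 3)
        self.volume = h**3


def batch_internal_force(
    kin: RegularGridKinematics, u_elems: np.ndarray, mu_kpa: float, kappa_kpa: float
) -> np.ndarray:
    """Internal forces for many congruent elements, (nel, 24) from (nel, 24)."""
    nel = u_elems.shape[0]
    U = u_elems.reshape(nel, 8, 3)
    dtype = complex if np.iscomplexobj(U) else float
    f = np.zeros((nel, 8, 3), dtype=dtype)
    eye = np.eye(3, dtype=dtype)

    Fs = np.empty((8, nel, 3, 3), dtype=dtype)
    Js = np.empty((8, nel), dtype=dtype)
    Finvs = np.empty((8, nel, 3, 3), dtype=dtype)
    for g in range(8):
        F = eye + np.einsum("nia,ib->nab", U, kin.dNdx[g])
        Fs[g] = F
        Js[g] = np.linalg.det(F)
        Finvs[g] = np.linalg.inv(F)
    if dtype is float and np.any(Js.real <= 0):
        raise InvertedElementError("inverted element in batch evaluation")
    Jbar = np.einsum("g,gn->n", kin.wdet, Js) / kin.volume

    for g in range(8):
        F, Finv, J = Fs[g], Finvs[g], Js[g]
        I1 = np.einsum("nab,nab->n", F, F)
        FinvT = np.swapaxes(Finv, 1, 2)
        P = mu_kpa * (J ** (-2.0 / 3.0))[:, None, None] * (
            F - (I1 / 3.0)[:, None, None] * FinvT
        )
        P = P + (kappa_kpa * (Jbar - 1.0) * J)[:, None, None] * FinvT
        f += kin.wdet[g] * np.einsum("ib,nab->nia", kin.dNdx[g], P)
    return f.reshape(nel, 24)


def batch_tangent(
    kin: RegularGridKinematics, u_elems: np.ndarray, mu_kpa: float, kappa_kpa: float
) -> np.ndarray:
    """Exact tangents (nel, 24, 24) via batched complex-step differentiation."""
    nel = u_elems.shape[0]
    K = np.empty((nel, 24, 24))
    h = 1e-30
    base = u_elems.astype(complex)
    for k in range(24):
        up = base.copy()
        up[:, k] += 1j * h
        K[:, :, k] = batch_internal_force(kin, up, mu_kpa, kappa_kpa).imag / h
    return 0.5 * (K + np.swapaxes(K, 1, 2))


def batch_centroid_cauchy(
    kin: RegularGridKinematics, u_elems: np.ndarray, mu_kpa: float, kappa_kpa: float
) -> np.ndarray:
    """Centroid Cauchy stress 6-vectors (kPa) for congruent elements, (nel, 6)."""
    nel = u_elems.shape[0]
    U = u_elems.reshape(nel, 8, 3)
    dNdx_c = kin.dNdx.mean(axis=0)  # centroid gradients
    F = np.eye(3) + np.einsum("nia,ib->nab", U, dNdx_c)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedElementError("inverted element at centroid")
    B = np.einsum("nab,ncb->nac", F, F)
    Bbar = (J ** (-2.0 / 3.0))[:, None, None] * B
    trB = np.einsum("naa->n", Bbar)
    dev = Bbar - (trB / 3.0)[:, None, None] * np.eye(3)
    sig = (mu_kpa / J)[:, None, None] * dev + (kappa_kpa * (J - 1.0))[:, None, None] * np.eye(3)
    out = np.empty((nel, 6))
    out[:, 0] = sig[:, 0, 0]
    out[:, 1] = sig[:, 1, 1]
    out[:, 2] = sig[:, 2, 2]
    out[:, 3] = sig[:, 0, 1]
    out[:, 4] = sig[:, 1, 2]
    out[:, 5] = sig[:, 2, 0]
    return out
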