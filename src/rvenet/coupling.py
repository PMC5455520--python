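"""Embedded-element coupling of the fiber beams and the matrix mesh.

The fiber network is embedded in the matrix with the standard
embedded-element constraint: the translation of every beam node is slaved
to the trilinear interpolation of the displacements of the hexahedral
element hosting it, u_beam = Σ w_i u_host,i, while beam rotations are unconstrained by the
host (the continuum carries no rotational DOFs) and, carrying no external
load, are eliminated by exact per-fiber static condensation. The beam
stiffness is condensed onto the host DOFs through the interpolation
operator, giving a symmetric coupled system solved under unconfined
uniaxial compression: the top face receives a uniform normal displacement
with free tangential sliding, the bottom face is held at zero normal
displacement, lateral faces are traction-free, and two corner pins remove
the in-plane rigid modes.

Matrix volume overlapped by fibers is not subtracted (the usual
embedded-element redundancy; the error is of the order of the fiber volume
fraction, ~0.1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .beam_fe import BeamSection, FiberMaterial, condensed_fiber_stiffness
from .geometry import RVEGeometry
from .matrix_fe import (
    PA_TO_KPA,
    HexMesh,
    InvertedElementError,
    MatrixMaterial,
    RegularGridKinematics,
    batch_centroid_cauchy,
    batch_internal_force,
    batch_tangent,
    build_hex_mesh,
    centroid_stress_operator,
    hex_bbar_stiffness,
    shape_functions,
)
from .network import BeamMesh

#: Diagonal regularization factor for the free-twist modes of isolated fibers.
ROTATION_REG_FACTOR = 1e-9
#: Ground-spring factor used only for the matrix-free (µ = 0) case.
MATRIX_FREE_SPRING_FACTOR = 1e-12


class EmbeddingError(RuntimeError):
    """A beam node falls outside every host element."""


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge after step halving."""


@dataclass(frozen=True)
class LoadCase:
    """Uniaxial compression applied to the top face of the RVE."""

    applied_strain: float = 0.05
    strain_increments: int = 5
    mode: str = "linear"  # "linear" or "finite"

    def __post_init__(self) -> None:
        if not (0.0 < self.applied_strain < 0.2):
            raise ValueError("applied_strain must be in (0, 0.2)")
        if self.strain_increments < 1:
            raise ValueError("strain_increments must be >= 1")
        if self.mode not in ("linear", "finite"):
            raise ValueError("mode must be 'linear' or 'finite'")


@dataclass
class EmbeddingMap:
    """Host element and trilinear interpolation data per beam node."""

    host_element: np.ndarray  # (nb,)
    natural_coords: np.ndarray  # (nb, 3) in [-1, 1]^3
    weights: np.ndarray  # (nb, 8), non-negative, rows sum to 1


def locate_hosts(beam_mesh: BeamMesh, hex_mesh: HexMesh, tol: float = 1e-9) -> EmbeddingMap:
    """Find the host brick of every beam node on the regular grid.

    Structured-grid lookup (integer division by the cell size) followed by
    the closed-form local-coordinate solve; exact for the regular mesh.
    """
    n = hex_mesh.divisions_per_edge
    h = hex_mesh.spacing
    p = beam_mesh.node_positions
    if p.size == 0:
        return EmbeddingMap(
            np.zeros(0, dtype=np.int64), np.zeros((0, 3)), np.zeros((0, 8))
        )
    if p.min() < -tol or p.max() > hex_mesh.edge_length + tol:
        raise EmbeddingError("beam node outside the RVE cube")
    cell = np.clip(np.floor(p / h).astype(np.int64), 0, n - 1)
    xi = 2.0 * (p - cell * h) / h - 1.0
    host = cell[:, 0] + n * (cell[:, 1] + n * cell[:, 2])
    weights = np.array([shape_functions(x) for x in xi])
    return EmbeddingMap(host_element=host, natural_coords=xi, weights=weights)


def interpolation_operator(
    embedding: EmbeddingMap, hex_mesh: HexMesh, num_beam_nodes: int
) -> sp.csr_matrix:
    """Sparse operator T with u_beam = T u_matrix, shape (3 nb, 3 nm)."""
    nm = hex_mesh.num_nodes
    nb = num_beam_nodes
    if nb == 0:
        return sp.csr_matrix((0, 3 * nm))
    conn = hex_mesh.elements[embedding.host_element]  # (nb, 8)
    rows, cols, vals = [], [], []
    for d in range(3):
        rows.append(np.repeat(3 * np.arange(nb) + d, 8))
        cols.append((3 * conn + d).ravel())
        vals.append(embedding.weights.ravel())
    T = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * nb, 3 * nm),
    )
    return T.tocsr()


def assemble_matrix_stiffness(hex_mesh: HexMesh, material: MatrixMaterial) -> sp.csr_matrix:
    """Linearized B-bar matrix stiffness on the translational DOFs (3 nm)."""
    nm = hex_mesh.num_nodes
    mu = material.shear_modulus * PA_TO_KPA
    kappa = material.bulk_modulus * PA_TO_KPA
    if mu == 0.0:
        return sp.csr_matrix((3 * nm, 3 * nm))
    Ke = hex_bbar_stiffness(hex_mesh.spacing, mu, kappa)
    conn = hex_mesh.elements
    dofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    data = np.tile(Ke.ravel(), hex_mesh.num_elements)
    return sp.coo_matrix((data, (rows, cols)), shape=(3 * nm, 3 * nm)).tocsr()


@dataclass
class CoupledSystem:
    """Assembled coupled RVE: matrix + condensed fiber stiffness.

    Global unknowns are the matrix node translations (3 nm). Beam
    translations are slaved to the matrix field through the interpolation
    operator (master-slave condensation of the embedded-element
    constraint); beam rotations, which carry no external load, have been
    eliminated beforehand by exact per-fiber static condensation, so the
    fiber network enters as a symmetric stiffness on the matrix DOFs.
    """

    geometry: RVEGeometry
    hex_mesh: HexMesh
    beam_mesh: BeamMesh | None
    embedding: EmbeddingMap | None
    matrix_material: MatrixMaterial
    section: BeamSection | None
    fiber_material: FiberMaterial | None
    K_matrix: sp.csr_matrix  # (N, N), zero beyond the matrix block
    K_fiber: sp.csr_matrix  # (N, N)
    K_aux: sp.csr_matrix  # regularization/stabilization, excluded from phase forces
    T: sp.csr_matrix | None  # beam-translation interpolation operator

    @property
    def num_matrix_dofs(self) -> int:
        return 3 * self.hex_mesh.num_nodes

    @property
    def num_dofs(self) -> int:
        return self.K_matrix.shape[0]


def assemble_coupled_system(
    hex_mesh: HexMesh,
    material: MatrixMaterial,
    beam_mesh: BeamMesh | None = None,
    section: BeamSection | None = None,
    fiber_material: FiberMaterial | None = None,
    embedding: EmbeddingMap | None = None,
    geometry: RVEGeometry | None = None,
) -> CoupledSystem:
    """Assemble the symmetric coupled stiffness on [u_matrix; θ_beam]."""
    if geometry is None:
        geometry = RVEGeometry(hex_mesh.edge_length, hex_mesh.divisions_per_edge)
    N = 3 * hex_mesh.num_nodes
    nb = beam_mesh.num_nodes if beam_mesh is not None else 0

    K_matrix = assemble_matrix_stiffness(hex_mesh, material)
    aux = sp.csr_matrix((N, N))
    T = None
    if nb and beam_mesh.num_elements:
        if embedding is None:
            embedding = locate_hosts(beam_mesh, hex_mesh)
        if section is None or fiber_material is None:
            raise ValueError("fiber section and material required with a beam mesh")
        Kb = condensed_fiber_stiffness(
            beam_mesh, section, fiber_material, reg_factor=ROTATION_REG_FACTOR
        )
        T = interpolation_operator(embedding, hex_mesh, nb)
        K_fiber = (T.T @ Kb @ T).tocsr()
    else:
        K_fiber = sp.csr_matrix((N, N))
        beam_mesh = beam_mesh if nb else None

    if material.shear_modulus == 0.0 and nb:
        # matrix-free case: vanishing ground springs keep the embedding mesh
        # solvable; they carry a negligible share of the reaction
        ea_per_len = (
            fiber_material.youngs_modulus
            * PA_TO_KPA
            * section.area
            / max(beam_mesh.element_lengths().mean(), 1e-12)
        )
        aux = aux + sp.diags(np.full(N, MATRIX_FREE_SPRING_FACTOR * ea_per_len))

    return CoupledSystem(
        geometry=geometry,
        hex_mesh=hex_mesh,
        beam_mesh=beam_mesh,
        embedding=embedding,
        matrix_material=material,
        section=section,
        fiber_material=fiber_material,
        K_matrix=K_matrix.tocsr(),
        K_fiber=K_fiber,
        K_aux=aux.tocsr(),
        T=T,
    )


@dataclass
class RVESolution:
    """Solution of one compression load case.

    Reactions are reported as positive compressive magnitudes in nN;
    stresses are per-element centroid Cauchy stress 6-vectors in Pa
    (rows xx, yy, zz, xy, yz, zx).
    """

    strains: np.ndarray  # (m,)
    total_reaction: np.ndarray  # (m,) nN
    matrix_reaction: np.ndarray  # (m,) nN
    fiber_reaction: np.ndarray  # (m,) nN
    matrix_stress: np.ndarray  # (m, nel, 6) Pa
    displacements: np.ndarray  # (N,) at the final increment
    face_area: float  # µm²
    num_matrix_dofs: int
    residual_norm: float = 0.0
    bottom_reaction: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def nominal_stress(self) -> np.ndarray:
        """Nominal compressive stress per increment, Pa (reaction / face area)."""
        return self.total_reaction / self.face_area * 1e3  # kPa -> Pa

    def beam_translations(self, system: CoupledSystem) -> np.ndarray:
        """(nb, 3) beam-node displacements recovered from the embedding."""
        if system.T is None:
            return np.zeros((0, 3))
        return (system.T @ self.displacements[: self.num_matrix_dofs]).reshape(-1, 3)


def _boundary_dofs(system: CoupledSystem, applied_strain: float):
    """Constrained DOF indices and prescribed values at full load."""
    mesh = system.hex_mesh
    n = mesh.divisions_per_edge
    L = mesh.edge_length
    z = mesh.node_positions[:, 2]
    top = np.flatnonzero(np.abs(z - L) < 1e-9 * max(L, 1.0))
    bottom = np.flatnonzero(np.abs(z) < 1e-9 * max(L, 1.0))
    top_z = 3 * top + 2
    bottom_z = 3 * bottom + 2
    # corner pins against in-plane rigid modes; consistent with the
    # homogeneous lateral-expansion field (no spurious constraint forces)
    pin_xy = np.array([0, 1, 3 * n + 1], dtype=np.int64)  # (0,0,0):x,y  (L,0,0):y
    fixed = np.concatenate([top_z, bottom_z, pin_xy])
    values = np.concatenate(
        [np.full(top_z.size, -applied_strain * L), np.zeros(bottom_z.size + 3)]
    )
    return fixed, values, top_z, bottom_z


def _face_sums(f: np.ndarray, top_z: np.ndarray, bottom_z: np.ndarray):
    """Compressive reaction magnitudes on the two faces from an internal force."""
    return -float(f[top_z].sum()), float(f[bottom_z].sum())


def solve_compression(
    system: CoupledSystem,
    load_case: LoadCase = LoadCase(),
    factor_cache: dict | None = None,
) -> RVESolution:
    """Solve the compression case and return per-increment reactions/stresses.

    ``factor_cache`` (used by :class:`ScaffoldModel`) may hold a sparse LU
    of the same system at a different matrix shear modulus; since the
    matrix stiffness is proportional to µ at fixed κ/µ, that factorization
    is a spectrally-bounded preconditioner and the solve reduces to a short
    conjugate-gradient iteration instead of a fresh factorization.
    """
    if load_case.mode == "finite":
        return _solve_finite(system, load_case)
    return _solve_linear(system, load_case, factor_cache)


def _solve_linear(
    system: CoupledSystem, load_case: LoadCase, factor_cache: dict | None = None
) -> RVESolution:
    N = system.num_dofs
    K = (system.K_matrix + system.K_fiber + system.K_aux).tocsr()
    fixed, values, top_z, bottom_z = _boundary_dofs(system, load_case.applied_strain)
    free = np.setdiff1d(np.arange(N), fixed)

    u = np.zeros(N)
    u[fixed] = values
    Kff = K[free][:, free].tocsc()
    # decoupled DOFs (possible with an empty fiber set and zero matrix): unit diag
    dia = Kff.diagonal()
    dead = np.abs(dia) < 1e-300
    if dead.any():
        Kff = Kff + sp.diags(dead.astype(float))
    rhs = -K[free][:, fixed] @ values
    if free.size:
        u[free] = _solve_spd(Kff, np.asarray(rhs), system, factor_cache)

    fm = system.K_matrix @ u
    ff = system.K_fiber @ u
    fa = system.K_aux @ u
    resid = np.linalg.norm((fm + ff + fa)[free]) / max(np.linalg.norm(fm + ff + fa), 1e-300)

    m = load_case.strain_increments
    fracs = np.arange(1, m + 1) / m
    strains = load_case.applied_strain * fracs

    Rm_top, _ = _face_sums(fm, top_z, bottom_z)
    Rf_top, _ = _face_sums(ff, top_z, bottom_z)
    Rt_top, Rt_bot = _face_sums(fm + ff + fa, top_z, bottom_z)

    mat = system.matrix_material
    mu = mat.shear_modulus * PA_TO_KPA
    nel = system.hex_mesh.num_elements
    if mu > 0:
        S = centroid_stress_operator(system.hex_mesh.spacing, mu, mat.bulk_modulus * PA_TO_KPA)
        ue = u[: system.num_matrix_dofs].reshape(-1, 3)[system.hex_mesh.elements].reshape(nel, 24)
        sig_full = ue @ S.T * 1e3  # kPa -> Pa
    else:
        sig_full = np.zeros((nel, 6))

    return RVESolution(
        strains=strains,
        total_reaction=Rt_top * fracs,
        matrix_reaction=Rm_top * fracs,
        fiber_reaction=Rf_top * fracs,
        matrix_stress=sig_full[None, :, :] * fracs[:, None, None],
        displacements=u,
        face_area=system.geometry.face_area,
        num_matrix_dofs=system.num_matrix_dofs,
        residual_norm=resid,
        bottom_reaction=Rt_bot * fracs,
    )


def _solve_spd(
    Kff: sp.csc_matrix,
    rhs: np.ndarray,
    system: CoupledSystem,
    factor_cache: dict | None,
) -> np.ndarray:
    """Direct solve, or preconditioned CG when a reference LU is cached.

    The cached LU must come from the same mesh/network at a positive
    reference µ; the matrix-free case (µ = 0) always uses a direct solve
    because the preconditioned spectrum degenerates as µ → 0.
    """
    mu = system.matrix_material.shear_modulus
    if factor_cache is None or mu == 0.0:
        return spla.splu(Kff).solve(rhs)
    cached = factor_cache.get("lu")
    if cached is not None and factor_cache.get("n") == Kff.shape[0] and mu > 0:
        lu = cached
        M = spla.LinearOperator(Kff.shape, matvec=lu.solve)
        x, info = spla.cg(Kff, rhs, M=M, rtol=1e-12, atol=0.0, maxiter=200)
        if info == 0:
            return x
    lu = spla.splu(Kff)
    factor_cache["lu"] = lu
    factor_cache["n"] = Kff.shape[0]
    factor_cache["mu"] = mu
    return lu.solve(rhs)


def _solve_finite(system: CoupledSystem, load_case: LoadCase) -> RVESolution:
    """Newton solution with the finite-strain matrix element (mean dilatation)."""
    mat = system.matrix_material
    mu = mat.shear_modulus * PA_TO_KPA
    kappa = mat.bulk_modulus * PA_TO_KPA
    mesh = system.hex_mesh
    kin = RegularGridKinematics(mesh.spacing)
    nm3 = system.num_matrix_dofs
    N = system.num_dofs
    nel = mesh.num_elements
    conn = mesh.elements
    edofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()

    def matrix_force(u: np.ndarray) -> np.ndarray:
        out = np.zeros(N)
        if mu == 0:
            return out
        ue = u[:nm3].reshape(-1, 3)[conn].reshape(nel, 24)
        fe = batch_internal_force(kin, ue, mu, kappa)
        np.add.at(out, edofs.ravel(), fe.ravel())
        return out

    def matrix_tangent(u: np.ndarray) -> sp.csr_matrix:
        if mu == 0:
            return sp.csr_matrix((N, N))
        ue = u[:nm3].reshape(-1, 3)[conn].reshape(nel, 24)
        Ke = batch_tangent(kin, ue, mu, kappa)
        return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(N, N)).tocsr()

    fixed, values_full, top_z, bottom_z = _boundary_dofs(system, load_case.applied_strain)
    free = np.setdiff1d(np.arange(N), fixed)

    m = load_case.strain_increments
    strains, Rt, Rm, Rf, Rb = [], [], [], [], []
    stresses = []
    u = np.zeros(N)
    resid = 0.0

    targets = list(np.arange(1, m + 1) / m)
    level = 0.0
    pending = targets.copy()
    halvings = 0
    while pending:
        frac = pending[0]
        u_trial = u.copy()
        u_trial[fixed] = values_full * frac
        converged = False

        def residual(u_vec):
            f_int = matrix_force(u_vec) + (system.K_fiber + system.K_aux) @ u_vec
            return f_int, f_int[free]

        f_int, r = residual(u_trial)
        for _ in range(25):
            scale = max(np.linalg.norm(f_int[fixed]), 1.0)
            rnorm = np.linalg.norm(r)
            if rnorm <= 1e-8 * scale:
                converged = True
                resid = rnorm / scale
                break
            Kt = matrix_tangent(u_trial) + system.K_fiber + system.K_aux
            Kff = Kt[free][:, free].tocsc()
            dia = Kff.diagonal()
            dead = np.abs(dia) < 1e-300
            if dead.any():
                Kff = Kff + sp.diags(dead.astype(float))
            du = spla.splu(Kff).solve(-r)
            # backtracking on the residual norm guards against overshoot of
            # the stiff volumetric penalty
            alpha = 1.0
            while True:
                u_new = u_trial.copy()
                u_new[free] += alpha * du
                try:
                    f_new, r_new = residual(u_new)
                except InvertedElementError:
                    alpha *= 0.5
                    if alpha < 1e-4:
                        raise
                    continue
                if np.linalg.norm(r_new) <= (1.0 - 1e-4 * alpha) * rnorm or alpha < 1 / 64:
                    break
                alpha *= 0.5
            u_trial, f_int, r = u_new, f_new, r_new
        if not converged:
            halvings += 1
            if halvings > 6:
                raise ConvergenceError("Newton failed to converge after step halving")
            pending.insert(0, (level + frac) / 2.0)
            continue
        u = u_trial
        level = frac
        pending.pop(0)
        if not any(np.isclose(frac, t) for t in targets):
            continue
        fm = matrix_force(u)
        ff = system.K_fiber @ u
        fa = system.K_aux @ u
        strains.append(frac * load_case.applied_strain)
        Rm.append(_face_sums(fm, top_z, bottom_z)[0])
        Rf.append(_face_sums(ff, top_z, bottom_z)[0])
        t_top, t_bot = _face_sums(fm + ff + fa, top_z, bottom_z)
        Rt.append(t_top)
        Rb.append(t_bot)
        if mu > 0:
            ue = u[:nm3].reshape(-1, 3)[conn].reshape(nel, 24)
            stresses.append(batch_centroid_cauchy(kin, ue, mu, kappa) * 1e3)
        else:
            stresses.append(np.zeros((nel, 6)))

    return RVESolution(
        strains=np.array(strains),
        total_reaction=np.array(Rt),
        matrix_reaction=np.array(Rm),
        fiber_reaction=np.array(Rf),
        matrix_stress=np.array(stresses),
        displacements=u,
        face_area=system.geometry.face_area,
        num_matrix_dofs=nm3,
        residual_norm=resid,
        bottom_reaction=np.array(Rb),
    )


def phase_reactions(solution: RVESolution) -> tuple[float, float]:
    """(F_matrix, F_fiber) on the loaded face at the final increment, nN."""
    return float(solution.matrix_reaction[-1]), float(solution.fiber_reaction[-1])


class ScaffoldModel:
    """Reusable RVE model: one network/mesh, many matrix shear moduli.

    Caches the fiber stiffness, embedding, and a unit matrix stiffness
    (the matrix stiffness is proportional to µ at fixed κ/µ), so sweeps
    and reverse fits pay only one sparse factorization per µ.
    """

    def __init__(
        self,
        geometry: RVEGeometry,
        beam_mesh: BeamMesh | None = None,
        section: BeamSection | None = None,
        fiber_material: FiberMaterial | None = None,
        bulk_ratio: float = 1.0e4,
    ):
        self.geometry = geometry
        self.hex_mesh = build_hex_mesh(geometry)
        self.beam_mesh = beam_mesh
        self.section = section or BeamSection()
        self.fiber_material = fiber_material or FiberMaterial()
        self.bulk_ratio = bulk_ratio
        self._factor_cache: dict = {}
        self._unit = assemble_coupled_system(
            self.hex_mesh,
            MatrixMaterial(1.0, bulk_ratio),
            beam_mesh,
            self.section,
            self.fiber_material,
            geometry=geometry,
        )

    def system(self, mu_pa: float) -> CoupledSystem:
        base = self._unit
        if mu_pa == 0.0:
            return assemble_coupled_system(
                self.hex_mesh,
                MatrixMaterial(0.0, self.bulk_ratio),
                self.beam_mesh,
                self.section,
                self.fiber_material,
                embedding=base.embedding,
                geometry=self.geometry,
            )
        return CoupledSystem(
            geometry=self.geometry,
            hex_mesh=self.hex_mesh,
            beam_mesh=self.beam_mesh,
            embedding=base.embedding,
            matrix_material=MatrixMaterial(mu_pa, self.bulk_ratio),
            section=self.section,
            fiber_material=self.fiber_material,
            K_matrix=(base.K_matrix * mu_pa).tocsr(),
            K_fiber=base.K_fiber,
            K_aux=base.K_aux,
            T=base.T,
        )

    def solve(self, mu_pa: float, load_case: LoadCase = LoadCase()) -> RVESolution:
        return solve_compression(self.system(mu_pa), load_case, self._factor_cache)
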