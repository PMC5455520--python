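"""Headline scaffold quantities derived from RVE solutions.

This module turns coupled fiber-matrix solutions into the quantities used
to characterize collagen scaffolds: the equilibrium compressive modulus
(slope of nominal stress vs. applied strain), the matrix/fiber load-sharing
split on the loaded face, the heterogeneity of the normalized matrix
von Mises stress relative to the affine (fiber-free) reference, the reverse
fit of the matrix shear modulus to a target scaffold modulus, and the
empirical linear law E = a µ + b C_f + c relating scaffold modulus to
matrix shear modulus and collagen concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .beam_fe import BeamSection, FiberMaterial
from .coupling import LoadCase, RVESolution, ScaffoldModel
from .geometry import RVEGeometry
from .matrix_fe import MatrixMaterial, von_mises
from .network import discretize_fibers, network_for_concentration


class InfeasibleTargetError(ValueError):
    """Target modulus outside the range reachable by varying µ."""


@dataclass
class StressStrainSeries:
    """Nominal stress (Pa) vs. applied compressive strain."""

    strains: np.ndarray
    stresses: np.ndarray  # Pa

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, dtype=float)
        self.stresses = np.asarray(self.stresses, dtype=float)
        if self.strains.size != self.stresses.size:
            raise ValueError("strain and stress arrays must have equal length")
        if self.strains.size and np.any(np.diff(self.strains) <= 0):
            raise ValueError("strains must be strictly increasing")

    @classmethod
    def from_solution(cls, solution: RVESolution) -> "StressStrainSeries":
        return cls(solution.strains, solution.nominal_stress())


def equilibrium_modulus(series: StressStrainSeries) -> float:
    """Equilibrium compressive modulus in Pa: OLS slope of stress on strain."""
    if series.strains.size < 2:
        raise ValueError("at least 2 stress-strain points are required")
    slope = np.polyfit(series.strains, series.stresses, 1)[0]
    return float(abs(slope))


def load_share_fractions(f_matrix: float, f_fiber: float) -> tuple[float, float]:
    """Percent of the face reaction carried by matrix and fiber phases."""
    total = f_matrix + f_fiber
    if total == 0:
        raise ValueError("total reaction is zero; load shares undefined")
    m = 100.0 * f_matrix / total
    return m, 100.0 - m


@dataclass
class StressHistogram:
    """Distribution of normalized matrix von Mises stress σ_vm / µ.

    ``affine_value`` is the normalized stress of the affine reference, i.e.
    the homogeneous fiber-free matrix at the same applied strain. Sample
    mean/variance are of the underlying per-element values (volume
    weighting is uniform on the regular grid).
    """

    bin_edges: np.ndarray
    masses: np.ndarray
    affine_value: float
    sample_mean: float
    sample_variance: float

    def __post_init__(self) -> None:
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise ValueError("histogram masses must sum to 1")

    def mass_within(self, fraction: float) -> float:
        """Probability mass within ±fraction of the affine value (from bins)."""
        lo = self.affine_value * (1.0 - fraction)
        hi = self.affine_value * (1.0 + fraction)
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(self.masses[(centers >= lo) & (centers <= hi)].sum())


def stress_heterogeneity(
    solution: RVESolution, material: MatrixMaterial, bins: int = 50
) -> StressHistogram:
    """Histogram of σ_vm / µ over matrix elements at the final increment."""
    if material.shear_modulus <= 0:
        raise ValueError("normalized stress requires a positive shear modulus")
    vm = von_mises(solution.matrix_stress[-1]) / material.shear_modulus
    strain = float(solution.strains[-1])
    affine = material.youngs_modulus_incompressible * strain / material.shear_modulus
    lo, hi = float(vm.min()), float(vm.max())
    if hi - lo < 1e-12:
        lo, hi = lo - 1e-12, hi + 1e-12
    counts, edges = np.histogram(vm, bins=bins, range=(lo, hi))
    masses = counts / counts.sum()
    return StressHistogram(
        bin_edges=edges,
        masses=masses,
        affine_value=affine,
        sample_mean=float(vm.mean()),
        sample_variance=float(vm.var()),
    )


def scaffold_modulus(
    model: ScaffoldModel, mu_pa: float, load_case: LoadCase = LoadCase()
) -> float:
    """Equilibrium compressive modulus (Pa) of one RVE model at matrix µ."""
    sol = model.solve(mu_pa, load_case)
    return equilibrium_modulus(StressStrainSeries.from_solution(sol))


def reverse_fit_mu(
    target_modulus: float,
    model: ScaffoldModel,
    load_case: LoadCase = LoadCase(),
    bracket: tuple[float, float] = (0.1, 1000.0),
    rtol: float = 1e-4,
) -> float:
    """Matrix shear modulus (Pa) whose simulated scaffold modulus hits the target.

    Scalar root find (Brent) on µ over ``bracket``; relies on the strict
    monotonicity of the scaffold modulus in µ at fixed network.
    """
    lo, hi = bracket
    e_lo = scaffold_modulus(model, lo, load_case)
    e_hi = scaffold_modulus(model, hi, load_case)
    if target_modulus < e_lo:
        raise InfeasibleTargetError(
            f"target {target_modulus} Pa below the modulus {e_lo:.3g} Pa at µ = {lo} Pa "
            "(fiber-dominated floor)"
        )
    if target_modulus > e_hi:
        raise InfeasibleTargetError(
            f"target {target_modulus} Pa above the modulus {e_hi:.3g} Pa at µ = {hi} Pa"
        )
    return float(
        brentq(
            lambda mu: scaffold_modulus(model, mu, load_case) - target_modulus,
            lo,
            hi,
            rtol=rtol,
        )
    )


def run_sweep(
    mu_list: list[float],
    cf_list: list[float],
    replicates: int = 3,
    geometry: RVEGeometry | None = None,
    base_seed: int = 0,
    section: BeamSection | None = None,
    fiber_material: FiberMaterial | None = None,
    load_case: LoadCase = LoadCase(),
    element_length: float = 0.1,
    bulk_ratio: float = 1.0e4,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulated scaffold modulus over a (µ, C_f) grid with replicate networks.

    For each collagen concentration and replicate a fresh calibrated network
    is generated (seed = base_seed + replicate index) and reused across all
    matrix shear moduli, so µ comparisons are paired on the same network.
    Returns a tidy frame with columns mu_pa, cf_mg_ml, replicate, seed, E_pa.
    """
    if not mu_list or not cf_list:
        raise ValueError("mu_list and cf_list must be non-empty")
    geometry = geometry or RVEGeometry(mesh_divisions=20)
    section = section or BeamSection()
    fiber_material = fiber_material or FiberMaterial()
    rows = []
    for cf in cf_list:
        for rep in range(replicates):
            seed = base_seed + rep
            network = network_for_concentration(geometry, cf, seed, diameter=section.diameter)
            beam = discretize_fibers(network, element_length) if network.num_segments else None
            model = ScaffoldModel(geometry, beam, section, fiber_material, bulk_ratio)
            for mu in mu_list:
                E = scaffold_modulus(model, mu, load_case)
                rows.append(
                    {"mu_pa": mu, "cf_mg_ml": cf, "replicate": rep, "seed": seed, "E_pa": E}
                )
                if progress:
                    print(f"cf={cf} rep={rep} mu={mu}: E = {E:.2f} Pa", flush=True)
    return pd.DataFrame(rows)


@dataclass
class SweepFit:
    """OLS fit E = a µ + b C_f + c over the replicate-averaged sweep grid."""

    slope_mu: float  # Pa / Pa
    slope_cf: float  # Pa per mg/mL
    intercept: float  # Pa
    r_squared: float
    grid: pd.DataFrame


def fit_empirical_law(sweep: pd.DataFrame, mu_max: float | None = 50.0) -> SweepFit:
    """Fit the linear scaffold-modulus law on the replicate-averaged grid.

    Points with µ above ``mu_max`` are excluded (the law holds only in the
    moderate-glycation regime); pass ``mu_max=None`` to fit all points.
    """
    df = sweep if mu_max is None else sweep[sweep["mu_pa"] <= mu_max]
    grid = df.groupby(["mu_pa", "cf_mg_ml"], as_index=False)["E_pa"].mean()
    if len(grid) < 4:
        raise ValueError("need at least 4 grid points for the fit")
    if grid["mu_pa"].nunique() < 2 or grid["cf_mg_ml"].nunique() < 2:
        raise ValueError("need at least 2 distinct values in each predictor")
    import statsmodels.api as sm

    X = sm.add_constant(grid[["mu_pa", "cf_mg_ml"]])
    res = sm.OLS(grid["E_pa"], X).fit()
    return SweepFit(
        slope_mu=float(res.params["mu_pa"]),
        slope_cf=float(res.params["cf_mg_ml"]),
        intercept=float(res.params["const"]),
        r_squared=float(res.rsquared),
        grid=grid,
    )
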