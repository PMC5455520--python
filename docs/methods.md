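# Methods

## Model overview

`rvenet` predicts the equilibrium compressive modulus of collagen
scaffolds from a coupled fiber–matrix representative volume element
(RVE). The scaffold is a 10 µm cube containing

* a **fiber network**: the edge skeleton of a Voronoi tessellation of
  uniformly random seed points, clipped to the cube. Each edge is a
  straight collagen fiber of diameter 62 nm, discretized into 100 nm
  Euler–Bernoulli beam elements with Young's modulus 50 MPa (Poisson
  ratio 0.3, entering only the torsion constant). The number of fibers
  scales linearly with collagen concentration, anchored at 698 fibers at
  1.5 mg/mL; a calibration search over the seed count, followed by
  pruning of the shortest boundary-clipped segments, hits the target
  count exactly.
* a **matrix**: the interfibrillar phase, a nearly-incompressible
  neo-Hookean solid with strain energy W = (µ/2)(Ī₁ − 3) + (κ/2)(J̄ − 1)²,
  κ = 10⁴ µ, discretized on a regular grid of trilinear bricks (50³ at
  full resolution). The matrix shear modulus µ is the glycation dial:
  11, 30, 50 Pa correspond to 0, 50, 100 mM ribose.

The two phases interact through the **embedded-element constraint**: the
translation of every beam node is slaved to the trilinear interpolation
of its host brick's displacements. Matrix volume overlapped by fibers is
not subtracted (standard embedded-element redundancy; the error is of
the order of the fiber volume fraction, ~0.1–0.3%). Beam rotations are
not constrained by the host. Because they also carry no external load,
they are eliminated by *exact static condensation per fiber segment*
before the global solve; rotations are segment-local, so fiber crossings
transmit forces but not moments. We consider the moment-free crossing
the better picture of fiber entanglement (as opposed to covalent
crosslinks) and it reduces the global system to the matrix translations
only, which is what makes the replicate sweeps affordable. The
condensation is verified in the tests against the explicit Schur
complement of the full 6-DOF-per-node beam assembly.

## Loading and boundary conditions

Unconfined uniaxial compression to 5% strain: the top face receives a
uniform normal displacement with free tangential sliding, the bottom
face is fixed in the normal direction only, lateral faces are
traction-free, and two corner pins (consistent with the homogeneous
lateral-expansion field, hence force-free for a fiber-free RVE) remove
the in-plane rigid modes. For a fiber-free RVE this reproduces the
incompressible closed form E = 3µ to better than 0.1%.

Two analysis modes:

* **linear** (default): the constitutive law and kinematics are
  linearized; one sparse Cholesky-like factorization (SuperLU) per case,
  strain increments obtained by exact scaling. The scaffold modulus is
  the OLS slope of nominal stress (face reaction / face area) on strain,
  matching the linear-fit definition of the equilibrium modulus.
* **finite**: total-Lagrangian neo-Hookean bricks with a mean-dilatation
  volumetric term, full Newton iteration with an exact tangent obtained
  by complex-step differentiation of the analytic internal force
  (machine-precision linearization; verified against central differences
  at 1e-6), residual-norm backtracking line search, and step halving on
  non-convergence. At 5% strain the secant modulus differs from the
  linearized one by a few percent, consistent with the neo-Hookean
  closed form; the linear mode is therefore the default for modulus
  extraction.

Within one model the sparse LU computed at the first shear modulus is
reused as a conjugate-gradient preconditioner for the other moduli: the
matrix stiffness is proportional to µ at fixed κ/µ, so the
preconditioned spectrum is bounded by the µ-ratio and CG converges in a
few dozen iterations at rtol 1e-12 (with an automatic direct-solve
fallback). The matrix-free case µ = 0 adds vanishing diagonal ground
springs (10⁻¹² × fiber EA/L) so the embedding mesh stays solvable; the
springs are excluded from the phase-reaction split and carry ~10⁻⁹ of
the reaction.

## Outputs

* **Load sharing**: the internal-force operators of the two phases are
  applied separately to the solution; their face sums decompose the
  total reaction exactly (conservation is asserted at 1e-6 relative).
* **Stress heterogeneity**: element-centroid von Mises stress of the
  matrix, normalized by µ, binned into 50 uniform bins over the observed
  range (volume weighting is uniform on the regular grid). The affine
  reference is the fiber-free homogeneous value E·ε/µ ≈ 3ε. Sample mean
  and variance are computed from the raw per-element values, not the
  bins.
* **Reverse fit**: Brent root-finding of µ ∈ [0.1, 1000] Pa so the
  simulated modulus matches a target, valid because E is strictly
  increasing in µ (tested).
* **Empirical law**: E regressed on (µ, C_f, 1) by OLS (statsmodels)
  over the replicate-averaged grid µ ∈ {11, 30, 50} Pa ×
  C_f ∈ {1, 1.5, 3} mg/mL, excluding the µ = 0 and 500 Pa extremes where
  the response is strongly nonlinear. Three network realizations per
  grid point (seed = base seed + replicate index; networks are reused
  across µ so modulus ratios are paired on the same realization).

## Problem sizes

Full resolution is the 50³ matrix mesh (125,000 bricks, 132,651 nodes).
Production analyses in this package — the replicate sweep, the
three-fold-stiffening and heterogeneity checks, and the acceptance
script — run on the scaled-down 20³ mesh (8,000 bricks, ~28k matrix
DOFs, ~8.5k beam nodes at baseline density), which keeps the full
3×3-grid × 3-replicate sweep around ten minutes on one core. Unit tests
use a 5³ "tiny" fixture (20 fibers) that solves in well under a second.

## Known limitations

* **Discretization error of the embedding is large until the brick size
  resolves the fiber spacing.** Measured baseline scaffold moduli at
  µ = 11 Pa: 2948 / 868 / 435 / 318 Pa at 10/15/20/25 divisions — a
  coarse matrix mesh cannot develop the non-affine, bending-dominated
  relaxation of the sub-isostatic Voronoi network and therefore
  over-stiffens the fiber phase. The modulus softens monotonically under
  refinement; results at 20³ carry an O(30%) discretization surplus and
  correspondingly *understate* the stiffening ratio E(µ=50)/E(µ=11)
  (1.2 / 1.6 / 1.9 / 2.1 at 10/15/20/25 divisions on one realization,
  ~1.8 replicate-averaged at 20³, rising with refinement) and the matrix
  load share (10% → 21% from µ = 11 to 50 Pa at 20³). Absolute moduli
  should be read with this in mind; trends in µ and C_f, load-share
  directions, and heterogeneity directions are robust across meshes.
* Fibers are straight, of a single diameter, geometrically linear, and
  hinged at crossings; no explicit crosslink objects, no fiber buckling,
  no viscoelasticity or poroelasticity (the equilibrium modulus is
  modeled as purely elastic).
* The synthetic network emulates the fiber count, diameter, and density
  scaling of reconstituted collagen at 37 °C, not the curvature,
  polydispersity, or bundling of real fibers; its total fiber length
  (volume fraction ~2.5e-3 at baseline) overshoots the 1.5 mg/mL mass
  balance (~1.1e-3) by ~2.3×, because Poisson–Voronoi edges at the
  anchored count are ~1.2 µm long on average. Passing tests therefore
  validate the mechanics pipeline and the direction/shape of the
  reported trends, not a quantitative match to any particular gel.
* Internal units are µm / nN / kPa (1 nN/µm² = 1 kPa); all public
  interfaces use Pa, µm, mg/mL. Node-merging tolerance at fiber
  intersections is 1e-6 µm; segments shorter than 0.2 µm (two beam
  elements) after clipping are discarded; one integer seed controls all
  randomness, replicates use seed + k.
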