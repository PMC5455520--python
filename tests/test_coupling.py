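"""Embedded-element coupling: interpolation, assembly, and the RVE solve."""

import numpy as np
import pytest

import rvenet as rv
from rvenet.beam_fe import BeamSection, FiberMaterial
from rvenet.coupling import (
    EmbeddingError,
    LoadCase,
    ScaffoldModel,
    assemble_coupled_system,
    interpolation_operator,
    locate_hosts,
    phase_reactions,
    solve_compression,
)
from rvenet.matrix_fe import MatrixMaterial, build_hex_mesh
from rvenet.network import BeamMesh
from rvenet.postprocess import StressStrainSeries, equilibrium_modulus


def _beam_of_points(points):
    points = np.asarray(points, float)
    n = len(points)
    conn = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    lengths = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return BeamMesh(points, conn, target_element_length=float(lengths.max()),
                    parent_segment=np.zeros(n - 1, dtype=np.int64))


class TestEmbedding:
    def test_element_centroid_gets_equal_weights(self):
        mesh = build_hex_mesh(rv.RVEGeometry(10.0, 5))
        beam = _beam_of_points([[1.0, 1.0, 1.0], [1.0, 1.0, 1.2]])
        emb = locate_hosts(beam, mesh)
        np.testing.assert_allclose(emb.weights[0], 0.125, rtol=1e-12)

    def test_hex_corner_gets_unit_weight(self):
        mesh = build_hex_mesh(rv.RVEGeometry(10.0, 5))
        beam = _beam_of_points([[2.0, 4.0, 6.0], [2.0, 4.0, 6.3]])
        emb = locate_hosts(beam, mesh)
        w = np.sort(emb.weights[0])
        assert np.isclose(w[-1], 1.0, atol=1e-12)
        np.testing.assert_allclose(w[:-1], 0.0, atol=1e-12)

    def test_interpolation_reconstructs_random_positions(self, rng):
        mesh = build_hex_mesh(rv.RVEGeometry(10.0, 7))
        pts = rng.uniform(0, 10, (1000, 3))
        beam = _beam_of_points(pts)
        emb = locate_hosts(beam, mesh)
        assert np.all(emb.weights >= -1e-14)
        np.testing.assert_allclose(emb.weights.sum(axis=1), 1.0, atol=1e-12)
        T = interpolation_operator(emb, mesh, beam.num_nodes)
        rebuilt = (T @ mesh.node_positions.ravel()).reshape(-1, 3)
        assert np.abs(rebuilt - pts).max() < 1e-9

    def test_node_outside_cube_rejected(self):
        mesh = build_hex_mesh(rv.RVEGeometry(10.0, 5))
        beam = _beam_of_points([[5.0, 5.0, 5.0], [5.0, 5.0, 10.5]])
        with pytest.raises(EmbeddingError):
            locate_hosts(beam, mesh)


class TestAssembly:
    def test_no_fibers_reduces_to_matrix_only(self):
        mesh = build_hex_mesh(rv.RVEGeometry(10.0, 3))
        sys_ = assemble_coupled_system(mesh, MatrixMaterial(11.0))
        assert sys_.K_fiber.nnz == 0
        assert sys_.num_dofs == 3 * mesh.num_nodes

    def test_rigid_translation_is_force_free(self, tiny_model):
        sys_ = tiny_model.system(11.0)
        K = sys_.K_matrix + sys_.K_fiber + sys_.K_aux
        u = np.tile([0.3, -0.2, 0.7], sys_.num_dofs // 3)
        scale = np.abs(K.diagonal()).max() * np.abs(u).max()
        assert np.abs(K @ u).max() < 1e-9 * scale

    def test_spanning_fiber_adds_axial_stiffness_in_parallel(self):
        """A straight fiber across the cube acts as a spring in parallel:
        at vanishing matrix stiffness the face reaction is EA * strain."""
        g = rv.RVEGeometry(10.0, 4)
        z = np.linspace(0.0, 10.0, 101)
        pts = np.column_stack([np.full_like(z, 5.0), np.full_like(z, 5.0), z])
        beam = _beam_of_points(pts)
        section, fmat = BeamSection(0.062), FiberMaterial()
        model = ScaffoldModel(g, beam, section, fmat)
        sol = model.solve(1e-6, LoadCase(applied_strain=0.05))
        EA = fmat.youngs_modulus * 1e-3 * section.area
        assert np.isclose(sol.total_reaction[-1], EA * 0.05, rtol=1e-2)


class TestCompression:
    def test_pure_matrix_modulus_is_three_mu(self):
        g = rv.RVEGeometry(10.0, 10)
        sys_ = assemble_coupled_system(build_hex_mesh(g), MatrixMaterial(11.0), geometry=g)
        sol = solve_compression(sys_, LoadCase())
        E = equilibrium_modulus(StressStrainSeries.from_solution(sol))
        assert abs(E - 33.0) / 33.0 < 0.02

    def test_locking_free_across_bulk_ratios(self):
        g = rv.RVEGeometry(10.0, 5)
        errs = []
        for ratio in (1e3, 1e4, 1e5):
            sys_ = assemble_coupled_system(
                build_hex_mesh(g), MatrixMaterial(11.0, ratio), geometry=g
            )
            sol = solve_compression(sys_, LoadCase())
            E = equilibrium_modulus(StressStrainSeries.from_solution(sol))
            errs.append(abs(E - 33.0) / 33.0)
        assert errs[2] <= errs[0] + 1e-6
        assert max(errs) < 0.02

    def test_reaction_scales_linearly_with_mu_without_fibers(self):
        g = rv.RVEGeometry(10.0, 5)
        mesh = build_hex_mesh(g)
        r = []
        for mu in (11.0, 22.0):
            sol = solve_compression(
                assemble_coupled_system(mesh, MatrixMaterial(mu), geometry=g), LoadCase()
            )
            r.append(sol.total_reaction[-1])
        assert np.isclose(r[1], 2 * r[0], rtol=1e-9)

    def test_phase_reactions_conserve_total(self, tiny_solution):
        f_m, f_f = phase_reactions(tiny_solution)
        total = tiny_solution.total_reaction[-1]
        assert abs(f_m + f_f - total) <= 1e-6 * abs(total)

    def test_loaded_and_support_faces_balance(self, tiny_solution):
        top = tiny_solution.total_reaction
        bottom = tiny_solution.bottom_reaction
        np.testing.assert_allclose(top, bottom, rtol=1e-8)

    def test_fibers_only_add_stiffness(self, tiny_model):
        g = tiny_model.geometry
        matrix_only = solve_compression(
            assemble_coupled_system(tiny_model.hex_mesh, MatrixMaterial(11.0), geometry=g),
            LoadCase(),
        )
        coupled = tiny_model.solve(11.0)
        assert coupled.total_reaction[-1] >= matrix_only.total_reaction[-1]

    def test_matrix_free_network_carries_all_load(self, tiny_model):
        sol = tiny_model.solve(0.0)
        f_m, f_f = phase_reactions(sol)
        assert sol.total_reaction[-1] > 0
        assert abs(f_m) <= 1e-6 * sol.total_reaction[-1]

    def test_reactions_scale_with_strain(self, tiny_model):
        a = tiny_model.solve(11.0, LoadCase(applied_strain=0.01))
        b = tiny_model.solve(11.0, LoadCase(applied_strain=0.05))
        assert np.isclose(5 * a.total_reaction[-1], b.total_reaction[-1], rtol=1e-9)


class TestFiniteStrain:
    def test_finite_strain_pure_matrix_follows_neo_hookean_secant(self):
        g = rv.RVEGeometry(10.0, 4)
        sys_ = assemble_coupled_system(build_hex_mesh(g), MatrixMaterial(11.0), geometry=g)
        sol = solve_compression(sys_, LoadCase(0.05, 5, mode="finite"))
        assert sol.residual_norm < 1e-8
        # incompressible neo-Hookean nominal stress: mu (l - 1/l^2), l = 1 - eps
        lam = 1.0 - sol.strains
        expected = 11.0 * np.abs(lam - 1.0 / lam**2)
        np.testing.assert_allclose(sol.nominal_stress(), expected, rtol=5e-3)

    def test_finite_and_linear_modes_agree_at_small_strain(self, tiny_model):
        lin = tiny_model.solve(11.0, LoadCase(applied_strain=0.004, strain_increments=2))
        fin = solve_compression(
            tiny_model.system(11.0), LoadCase(0.004, 2, mode="finite")
        )
        np.testing.assert_allclose(
            fin.total_reaction[-1], lin.total_reaction[-1], rtol=2e-2
        )
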