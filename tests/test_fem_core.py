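"""Constitutive law, force assembly, constraints, and relaxation."""

import math

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from frillsim.fem_core import (
    Material,
    NumericalError,
    SolverConfig,
    SolverState,
    alpha_from_poisson,
    apply_constraints,
    assemble_nodal_forces,
    cauchy_stress,
    materials_by_region,
    relax_to_steady_state,
    strain_energy_density,
)
from frillsim.geometry import TetMesh
from frillsim.growth import GrowthTargets, build_element_growth

from conftest import two_tet_mesh


def test_material_constants():
    """alpha = (2+2nu)/(3-6nu), K = alpha mu, E = 2 mu (1+nu)."""
    m = Material(mu=2.0, nu=0.45)
    assert m.alpha == pytest.approx((2 + 0.9) / (3 - 2.7))
    assert m.K == pytest.approx(m.alpha * 2.0)
    assert m.young_E == pytest.approx(2 * 2.0 * 1.45)
    with pytest.raises(ValueError):
        alpha_from_poisson(0.5)


class TestStrainEnergy:
    def test_reference_state(self):
        assert strain_energy_density(np.eye(3), 1.0, 1.0) == 0.0

    def test_pure_dilation_hand_value(self):
        """F = 1.1 I: isochoric term vanishes, W = K/2 (J-1)^2."""
        F = np.diag([1.1, 1.1, 1.1])
        W = strain_energy_density(F, mu=1.0, K=1.0)
        assert W == pytest.approx(0.5 * (1.1**3 - 1.0) ** 2)
        assert W == pytest.approx(0.0547805, abs=1e-7)

    def test_simple_shear_hand_value(self):
        """Simple shear gamma = 0.5: J = 1, W = mu/2 (tr(B) - 3) = 0.125."""
        F = np.eye(3)
        F[0, 1] = 0.5
        assert strain_energy_density(F, mu=1.0, K=1.0) == pytest.approx(0.125)

    def test_objectivity_and_nonnegativity(self, rng):
        """W(RF) = W(F) for rotations R; W >= 0 with W = 0 iff rotation."""
        for i in range(10):
            F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.05:
                continue
            R = special_ortho_group.rvs(3, random_state=int(rng.integers(1 << 31)))
            W = strain_energy_density(F, 1.3, 4.0)
            WR = strain_energy_density(R @ F, 1.3, 4.0)
            assert WR == pytest.approx(W, rel=1e-12, abs=1e-12)
            assert W >= -1e-12
        assert strain_energy_density(special_ortho_group.rvs(3, random_state=7), 1.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_inverted_rejected(self):
        with pytest.raises(NumericalError):
            strain_energy_density(np.diag([1.0, 1.0, -1.0]), 1.0, 1.0)


class TestCauchyStress:
    def test_zero_at_identity(self):
        assert np.allclose(cauchy_stress(np.eye(3), 1.0, 1.0), 0.0)

    def test_pure_dilation_closed_form(self):
        """F = gI: deviatoric part exactly zero, sigma = K(g^3-1) I."""
        g = 1.2
        s = cauchy_stress(np.diag([g, g, g]), mu=1.0, K=2.5)
        assert np.allclose(s, 2.5 * (g**3 - 1.0) * np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_difference_of_energy(self, seed):
        """sigma = (1/J) dW/dF F^T against central differences of W."""
        rng = np.random.default_rng(seed)
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        assert np.linalg.det(F) > 0
        mu, K = 1.4, 6.0
        h = 1e-6
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                P[i, j] = (
                    strain_energy_density(Fp, mu, K) - strain_energy_density(Fm, mu, K)
                ) / (2 * h)
        sigma_fd = P @ F.T / np.linalg.det(F)
        sigma = cauchy_stress(F, mu, K)
        assert np.allclose(sigma, sigma_fd, rtol=1e-5, atol=1e-8)
        assert np.allclose(sigma, sigma.T, atol=1e-12 * np.linalg.norm(sigma))


class TestForceAssembly:
    def _setup(self, g_s=1.0):
        mesh = two_tet_mesh()
        growth = build_element_growth(
            mesh, GrowthTargets(g_surface=g_s, uniform=True)
        )
        materials = materials_by_region(mesh, Material(mu=1.0, nu=0.4))
        return mesh, growth, materials

    def test_zero_forces_ungrown_undeformed(self):
        mesh, growth, materials = self._setup()
        state = SolverState.initial(mesh)
        f = assemble_nodal_forces(state, mesh, growth, materials)
        assert np.abs(f).max() < 1e-12
        assert state.total_energy == pytest.approx(0.0, abs=1e-15)

    def test_forces_sum_to_zero(self, rng):
        """Face tractions of constant-stress elements balance: the total
        force on the unconstrained body vanishes."""
        mesh, growth, materials = self._setup(g_s=1.2)
        state = SolverState.initial(mesh)
        state.x = state.x + 0.05 * rng.standard_normal(state.x.shape)
        f = assemble_nodal_forces(state, mesh, growth, materials)
        assert np.linalg.norm(f.sum(axis=0)) < 1e-10 * (np.linalg.norm(f, axis=1).max() + 1e-30)

    @pytest.mark.parametrize("g_s", [1.0, 1.15])
    def test_forces_equal_negative_energy_gradient(self, g_s, rng):
        """Traction-assembled forces match -dE/dx by central differences
        on a two-tet mesh (the linear-tet identity)."""
        mesh, growth, materials = self._setup(g_s=g_s)
        state = SolverState.initial(mesh)
        state.x = state.x + 0.08 * rng.standard_normal(state.x.shape)
        f = assemble_nodal_forces(state, mesh, growth, materials)

        def total_energy(x):
            s = SolverState.initial(mesh)
            s.x = x
            assemble_nodal_forces(s, mesh, growth, materials)
            return s.total_energy

        h = 1e-6
        grad = np.zeros_like(state.x)
        for i in range(mesh.n_nodes):
            for d in range(3):
                xp, xm = state.x.copy(), state.x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                grad[i, d] = (total_energy(xp) - total_energy(xm)) / (2 * h)
        scale = np.abs(grad).max()
        assert np.allclose(f, -grad, rtol=1e-5, atol=1e-5 * scale)

    def test_mean_dilatation_forces_match_energy_gradient(self, rng):
        """With hex-cluster volumetric averaging the assembled forces
        still equal -dE/dx (finite differences on a small lattice)."""
        from frillsim.geometry import GeometryParams, Kind, build_mesh

        params = GeometryParams(
            kind=Kind.SEMICYLINDER,
            thickness_T=0.08,
            boundary_length_L=1.0,
            resolution=(2, 3),
            through_thickness_layers=2,
        )
        mesh = build_mesh(params)
        growth = build_element_growth(
            mesh, GrowthTargets(g_surface=1.1, uniform=True)
        )
        materials = materials_by_region(mesh, Material(mu=1.0, nu=0.45))
        config = SolverConfig.fast()
        assert config.volumetric_averaging
        state = SolverState.initial(mesh)
        state.x = state.x + 0.002 * rng.standard_normal(state.x.shape)
        f = assemble_nodal_forces(state, mesh, growth, materials, config=config)

        def total_energy(xx):
            s = SolverState.initial(mesh)
            s.x = xx
            assemble_nodal_forces(s, mesh, growth, materials, config=config)
            return s.total_energy

        h = 1e-6
        grad = np.zeros_like(state.x)
        for i in range(mesh.n_nodes):
            for d in range(3):
                xp, xm = state.x.copy(), state.x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                grad[i, d] = (total_energy(xp) - total_energy(xm)) / (2 * h)
        scale = np.abs(grad).max()
        assert np.allclose(f, -grad, rtol=1e-4, atol=1e-5 * scale)

    def test_inverted_element_reported_with_index(self):
        mesh, growth, materials = self._setup()
        state = SolverState.initial(mesh)
        state.x[4] = [0.0, 0.0, -5.0]  # fold the second tet through itself
        with pytest.raises(NumericalError) as err:
            assemble_nodal_forces(state, mesh, growth, materials)
        assert err.value.tet_index == 1


class TestConstraints:
    def test_fixed_nodes_zeroed(self, coarse_lobe):
        _, mesh = coarse_lobe
        state = SolverState.initial(mesh)
        state.v = np.ones_like(state.v)
        state.f = np.ones_like(state.f)
        apply_constraints(state, mesh, "SINGLE_SHEET")
        fixed = mesh.node_sets["FIXED_INNER"]
        assert np.abs(state.v[fixed]).max() == 0.0
        assert np.abs(state.f[fixed]).max() == 0.0

    def test_single_sheet_crease_projected_onto_C(self, coarse_lobe, rng):
        _, mesh = coarse_lobe
        state = SolverState.initial(mesh)
        state.v = rng.standard_normal(state.v.shape)
        apply_constraints(state, mesh, "SINGLE_SHEET")
        crease = mesh.node_sets["CREASE"]
        C = mesh.crease_direction
        residual = state.v[crease] - np.outer(state.v[crease] @ C, C)
        assert np.abs(residual).max() < 1e-12

    def test_multi_layer_crease_plane(self, coarse_bilayer, rng):
        _, mesh = coarse_bilayer
        state = SolverState.initial(mesh)
        state.v = rng.standard_normal(state.v.shape)
        apply_constraints(state, mesh, "MULTI_LAYER")
        crease = mesh.node_sets["CREASE"]
        # the crease plane of the parametric lobe is x = 0
        assert np.abs(state.v[crease, 0]).max() < 1e-12

    def test_unknown_mode_rejected(self, coarse_lobe):
        _, mesh = coarse_lobe
        state = SolverState.initial(mesh)
        with pytest.raises(ValueError):
            apply_constraints(state, mesh, "BOGUS")


class TestRelaxation:
    def test_no_growth_stays_put(self, coarse_lobe):
        """Clamped ungrown sheet: converges immediately with zero energy
        and (up to the removed perturbation) zero displacement."""
        _, mesh = coarse_lobe
        growth = build_element_growth(mesh, GrowthTargets(g_surface=1.0, uniform=True))
        materials = materials_by_region(mesh, Material(mu=1.0, nu=0.45))
        config = SolverConfig.fast(max_iterations=100_000, rng_seed=3)
        state = SolverState.initial(mesh)
        relax_to_steady_state(state, mesh, growth, materials, config)
        assert state.converged
        assert state.total_energy < 1e-8 * mesh.tet_volumes().sum()
        assert np.abs(state.displacement()).max() < 0.1 * mesh.thickness_T

    def test_free_uniform_growth_is_stress_free(self):
        """A single unconstrained tet under G = gI relaxes to the scaled
        tet with negligible residual energy (no frustration, no stress)."""
        mesh = two_tet_mesh()
        # keep only the first tet
        mesh = TetMesh(
            node_positions=mesh.node_positions[:4].copy(),
            tets=np.array([[0, 1, 2, 3]]),
            region_of_tet=np.zeros(1, dtype=np.int64),
            node_sets={
                "FIXED_INNER": np.array([], dtype=np.int64),
                "CREASE": np.array([], dtype=np.int64),
                "ANTERIOR_SURFACE": np.arange(4),
                "FREE_EDGE": np.array([], dtype=np.int64),
            },
            reference_normal_of_tet=np.array([[0.0, 0.0, 1.0]]),
            crease_direction=np.array([0.0, 1.0, 0.0]),
            spacing_a=1.0,
            inner_boundary_length_L=1.0,
            thickness_T=0.1,
            band_fraction=np.zeros(4),
            arc_coord=mesh.node_positions[:4, 0].copy(),
        )
        g = 1.25
        growth = build_element_growth(
            mesh, GrowthTargets(g_surface=g, uniform=True)
        )
        # isotropic growth: override the tangential tensor with gI
        growth.G_of_tet = np.tile(g * np.eye(3), (1, 1, 1))
        materials = materials_by_region(mesh, Material(mu=1.0, nu=0.3))
        config = SolverConfig.fast(
            max_iterations=400_000,
            energy_window=2000,
            disp_tol=1e-7,
            perturbation_amplitude=1e-3,
            rng_seed=0,
        )
        state = SolverState.initial(mesh)
        relax_to_steady_state(state, mesh, growth, materials, config)
        vol = mesh.tet_volumes().sum()
        assert state.converged
        assert state.total_energy < 1e-8 * vol
        # edges scaled by g
        e_ref = mesh.node_positions[1] - mesh.node_positions[0]
        e_def = state.x[1] - state.x[0]
        assert np.linalg.norm(e_def) == pytest.approx(g * np.linalg.norm(e_ref), rel=1e-3)

    def test_determinism_same_seed(self, coarse_lobe):
        """Identical config and seed give bit-identical energy histories."""
        _, mesh = coarse_lobe
        growth = build_element_growth(mesh, GrowthTargets(g_surface=1.15, uniform=True))
        materials = materials_by_region(mesh, Material(mu=1.0, nu=0.45))

        def run():
            config = SolverConfig.fast(max_iterations=3000, rng_seed=11)
            state = SolverState.initial(mesh)
            try:
                relax_to_steady_state(state, mesh, growth, materials, config)
            except NumericalError:
                pass  # convergence not required for the determinism check
            return [e for _, e, _ in state.energy_history]

        h1, h2 = run(), run()
        assert h1 == h2

    def test_crease_plane_drift_bounded(self, coarse_bilayer):
        """Multi-layer crease nodes stay in the crease plane over a run."""
        params, mesh = coarse_bilayer
        from frillsim.fem_core import bilayer_materials

        skin, sub = bilayer_materials(100.0)
        materials = materials_by_region(mesh, skin, sub)
        growth = build_element_growth(mesh, GrowthTargets(g_surface=1.1, g_crease=1.2))
        config = SolverConfig.fast(
            max_iterations=6000, mode="MULTI_LAYER", rng_seed=5
        )
        state = SolverState.initial(mesh)
        try:
            relax_to_steady_state(state, mesh, growth, materials, config)
        except NumericalError:
            pass
        crease = mesh.node_sets["CREASE"]
        assert np.abs(state.x[crease, 0]).max() < 1e-9 * params.boundary_length_L
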