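"""Smooth distance function, its gradient, and level-set sampling."""

import math

import numpy as np
import pytest

from celllists import (
    DegenerateGradientError,
    EmptyNeighborhoodError,
    PointCloud,
    SamplerConfig,
    SmoothDistanceModel,
    ValidationError,
    harmonic_level_potential,
    nuts_sample,
    sample_surface,
    sigma_tilde,
    smooth_distance,
    smooth_distance_gradient,
    smooth_distance_value_and_grad,
    toy_structure,
)

from oracles import batch_se, direct_sigma_tilde, direct_smooth_distance, radial_target_mean


def random_cluster(rng, n_atoms=10, spread=3.0, rc=10.0):
    """Atoms inside a ball so every query near the centre sees all of them."""
    coords = rng.normal(0, 1, (n_atoms, 3))
    coords *= spread / np.abs(coords).max()
    radii = rng.uniform(1.1, 1.9, n_atoms)
    return SmoothDistanceModel.build(PointCloud(coords=coords, radii=radii), rc)


class TestSigmaTilde:
    def test_single_atom_gives_its_radius(self):
        model = SmoothDistanceModel.build(toy_structure("single_atom"), 10.0)
        assert sigma_tilde([1.0, 2.0, 0.5], model) == pytest.approx(1.7)

    def test_two_equidistant_atoms_average_their_radii(self):
        atoms = PointCloud(
            coords=np.array([[-2.0, 0, 0], [2.0, 0, 0]]), radii=np.array([1.2, 1.8])
        )
        model = SmoothDistanceModel.build(atoms, 10.0)
        assert sigma_tilde([0.0, 1.0, 0.0], model) == pytest.approx(1.5)

    def test_matches_direct_weighted_mean_oracle(self, rng):
        model = random_cluster(rng)
        for _ in range(20):
            x = rng.uniform(-2, 2, 3)
            expected = direct_sigma_tilde(
                x, model.atoms.coords, model.atoms.radii, model.rc
            )
            assert sigma_tilde(x, model) == pytest.approx(expected, rel=1e-12)

    def test_is_a_convex_combination_of_radii(self, rng):
        model = random_cluster(rng)
        lo, hi = model.atoms.radii.min(), model.atoms.radii.max()
        for _ in range(50):
            val = sigma_tilde(rng.uniform(-3, 3, 3), model)
            assert lo - 1e-12 <= val <= hi + 1e-12


class TestSmoothDistance:
    def test_single_atom_equals_euclidean_distance(self, rng):
        model = SmoothDistanceModel.build(toy_structure("single_atom"), 10.0)
        for _ in range(50):
            x = rng.uniform(-5, 5, 3)
            assert smooth_distance(x, model) == pytest.approx(
                float(np.linalg.norm(x)), abs=1e-12
            )

    def test_zero_at_the_only_atom_center(self):
        model = SmoothDistanceModel.build(toy_structure("single_atom"), 10.0)
        assert smooth_distance([0.0, 0.0, 0.0], model) == pytest.approx(0.0, abs=1e-12)

    def test_matches_gridless_direct_sum_oracle(self, rng):
        model = random_cluster(rng, n_atoms=50, spread=4.0)
        for _ in range(20):
            x = rng.uniform(-3, 3, 3)
            expected = direct_smooth_distance(
                x, model.atoms.coords, model.atoms.radii, model.rc
            )
            assert smooth_distance(x, model) == pytest.approx(expected, rel=1e-10)

    def test_uniform_radii_soft_min_is_below_true_min_distance(self, rng):
        for _ in range(100):
            coords = rng.uniform(-3, 3, (8, 3))
            model = SmoothDistanceModel.build(
                PointCloud(coords=coords, radii=np.full(8, 1.6)), 10.0
            )
            x = rng.uniform(-2, 2, 3)
            dmin = float(np.linalg.norm(coords - x, axis=1).min())
            assert smooth_distance(x, model) <= dmin + 1e-12

    def test_empty_neighborhood_raises_with_query_point(self):
        model = SmoothDistanceModel.build(toy_structure("single_atom"), 2.0)
        with pytest.raises(EmptyNeighborhoodError) as err:
            smooth_distance([10.0, 0.0, 0.0], model)
        assert np.allclose(err.value.x, [10.0, 0.0, 0.0])

    def test_stable_at_the_cutoff_fringe(self):
        # at distance ~rc every exp(-r/sigma) underflows unshifted for tiny sigma
        atoms = PointCloud(coords=np.zeros((1, 3)), radii=np.array([0.01]))
        model = SmoothDistanceModel.build(atoms, 10.0)
        val = smooth_distance([9.99, 0.0, 0.0], model)
        assert math.isfinite(val) and val == pytest.approx(9.99, rel=1e-9)

    def test_model_requires_radii(self):
        with pytest.raises(ValidationError):
            SmoothDistanceModel.build(PointCloud(coords=np.zeros((1, 3))), 10.0)


class TestGradient:
    def test_single_atom_gradient_is_unit_radial(self, rng):
        model = SmoothDistanceModel.build(toy_structure("single_atom"), 10.0)
        x = np.array([1.0, 2.0, 2.0])
        grad = smooth_distance_gradient(x, model)
        assert np.allclose(grad, x / 3.0)
        assert np.linalg.norm(grad) == pytest.approx(1.0)

    def test_midplane_symmetry_kills_axial_component(self):
        model = SmoothDistanceModel.build(toy_structure("dumbbell", separation=4.0), 10.0)
        grad = smooth_distance_gradient([0.0, 1.5, -0.7], model)
        assert grad[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_central_finite_differences(self, rng):
        h = 1e-5
        for _ in range(100):
            model = random_cluster(rng, n_atoms=int(rng.integers(2, 12)))
            x = rng.uniform(-2, 2, 3)
            if np.linalg.norm(model.atoms.coords - x, axis=1).min() < 0.05:
                x = x + 0.1
            grad = smooth_distance_gradient(x, model)
            fd = np.array(
                [
                    (smooth_distance(x + h * e, model) - smooth_distance(x - h * e, model))
                    / (2 * h)
                    for e in np.eye(3)
                ]
            )
            assert np.abs(grad - fd).max() <= 1e-5 * max(np.abs(fd).max(), 1.0)

    def test_atom_center_raises_degenerate_gradient(self):
        model = SmoothDistanceModel.build(toy_structure("single_atom"), 10.0)
        with pytest.raises(DegenerateGradientError):
            smooth_distance_gradient([0.0, 0.0, 0.0], model)


class TestHarmonicPotential:
    def test_zero_energy_and_gradient_on_the_level_set(self):
        model = SmoothDistanceModel.build(toy_structure("single_atom"), 10.0)
        x = np.array([1.05, 0.0, 0.0])  # SDF = ||x|| for a single atom
        energy, grad = harmonic_level_potential(x, model, level=1.05, stiffness=50.0)
        assert energy == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(grad, 0.0)

    def test_energy_is_nonnegative(self, rng):
        model = random_cluster(rng)
        for _ in range(30):
            energy, _ = harmonic_level_potential(
                rng.uniform(-3, 3, 3), model, level=1.05, stiffness=50.0
            )
            assert energy >= 0.0

    def test_gradient_matches_finite_differences_of_energy(self, rng):
        model = random_cluster(rng)
        h = 1e-5
        for _ in range(30):
            x = rng.uniform(-2, 2, 3)
            if np.linalg.norm(model.atoms.coords - x, axis=1).min() < 0.05:
                continue
            energy, grad = harmonic_level_potential(x, model, 1.05, 50.0)
            fd = np.array(
                [
                    (
                        harmonic_level_potential(x + h * e, model, 1.05, 50.0)[0]
                        - harmonic_level_potential(x - h * e, model, 1.05, 50.0)[0]
                    )
                    / (2 * h)
                    for e in np.eye(3)
                ]
            )
            assert np.abs(grad - fd).max() <= 1e-5 * max(np.abs(fd).max(), 1.0)

    def test_empty_neighborhood_confines_back_toward_atoms(self):
        model = SmoothDistanceModel.build(toy_structure("single_atom"), 2.0)
        x = np.array([30.0, 0.0, 0.0])
        energy, grad = harmonic_level_potential(x, model, 1.05, 50.0)
        assert energy >= 1.0e4
        # descent direction (-grad) points back toward the atom at the origin
        assert float(-grad @ (model.atoms.coords[0] - x)) > 0


class TestNuts:
    def test_same_seed_gives_bit_identical_chains(self):
        cfg = SamplerConfig(n_samples=200, warmup=100, seed=7)
        pot = lambda x: (0.5 * float(x @ x), x.copy())
        a = nuts_sample(pot, np.zeros(3), cfg)
        b = nuts_sample(pot, np.zeros(3), cfg)
        assert np.array_equal(a.samples, b.samples)
        assert a.step_size == b.step_size

    def test_recovers_standard_gaussian_moments(self):
        cfg = SamplerConfig(n_samples=4000, warmup=800, seed=11)
        pot = lambda x: (0.5 * float(x @ x), x.copy())
        trace = nuts_sample(pot, np.zeros(3), cfg)
        for k in range(3):
            comp = trace.samples[:, k]
            assert abs(comp.mean()) <= 3.0 * batch_se(comp)
            sq = comp**2
            assert abs(sq.mean() - 1.0) <= 3.0 * batch_se(sq)

    def test_non_finite_start_raises(self):
        cfg = SamplerConfig(n_samples=10, warmup=10, seed=1)
        pot = lambda x: (float("inf"), np.zeros_like(x))
        with pytest.raises(Exception):
            nuts_sample(pot, np.zeros(2), cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SamplerConfig(level=-1.0)
        with pytest.raises(ValidationError):
            SamplerConfig(target_accept=1.5)


class TestSampleSurface:
    def test_defaults_match_case_study_settings(self):
        cfg = SamplerConfig()
        assert cfg.n_samples == 5000
        assert cfg.level == pytest.approx(1.05)

    def test_single_atom_samples_concentrate_on_the_level_sphere(self):
        cfg = SamplerConfig(n_samples=3000, warmup=600, seed=2)
        result = sample_surface(toy_structure("single_atom"), 10.0, cfg)
        r = np.linalg.norm(result.points.coords, axis=1)
        # the radial measure r^2 tilts the mean above the level by ~2/(k*d0)
        expected = radial_target_mean(cfg.stiffness, cfg.level)
        assert abs(r.mean() - expected) <= 3.0 * batch_se(r)
        assert r.std() == pytest.approx(1.0 / math.sqrt(cfg.stiffness), rel=0.35)

    def test_dumbbell_sdf_values_track_the_level(self):
        cfg = SamplerConfig(n_samples=800, warmup=300, seed=4)
        result = sample_surface(toy_structure("dumbbell", separation=4.0), 10.0, cfg)
        # allow the curvature-measure tilt of order 2/(k*d0) plus MC noise
        assert abs(np.nanmean(result.sdf) - cfg.level) < 0.06
        assert len(result) == 800

    def test_seeded_determinism_end_to_end(self, dumbbell):
        cfg = SamplerConfig(n_samples=100, warmup=80, seed=9)
        a = sample_surface(dumbbell, 10.0, cfg)
        b = sample_surface(dumbbell, 10.0, cfg)
        assert np.array_equal(a.points.coords, b.points.coords)
        assert np.array_equal(a.sdf, b.sdf)

    def test_grid_neighborhoods_equal_gridless_evaluation(self, rng):
        model = SmoothDistanceModel.build(toy_structure("shell", m=60, shell_radius=8.0), 10.0)
        for _ in range(20):
            x = rng.uniform(-9, 9, 3)
            try:
                ours = smooth_distance(x, model)
            except EmptyNeighborhoodError:
                continue
            expected = direct_smooth_distance(
                x, model.atoms.coords, model.atoms.radii, model.rc
            )
            assert ours == pytest.approx(expected, rel=1e-10)
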