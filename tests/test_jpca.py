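import numpy as np
import pytest

from rotwave import (
    PreprocessConfig,
    StackedMatrix,
    WaveModelParams,
    evolve,
    fit_skew,
    fit_unconstrained_r2,
    generate_dataset,
    mean_angular_velocity,
    stack_conditions,
)
from rotwave.preprocess import apply as preprocess_apply


def random_skew(k, rng, scale=1.0):
    A = rng.normal(size=(k, k)) * scale
    return 0.5 * (A - A.T)


def trajectories_from_generator(M, starts, t_grid):
    """Stacked exact solutions of xdot = M x from several initial states."""
    blocks = [evolve(M, x0, t_grid) for x0 in starts]
    X = np.vstack(blocks)
    t = len(t_grid)
    bounds = tuple((i * t, (i + 1) * t) for i in range(len(blocks)))
    return StackedMatrix(X, bounds, dt=t_grid[1] - t_grid[0])


class TestFitSkew:
    def test_recovers_known_generator(self):
        rng = np.random.default_rng(12)
        M = random_skew(4, rng)
        starts = rng.normal(size=(8, 4))
        sm = trajectories_from_generator(M, starts, np.linspace(0.0, 6.0, 600))
        res = fit_skew(sm, k=4, center=False)
        err = np.linalg.norm(res.ambient_generator() - M) / np.linalg.norm(M)
        assert err < 1e-3

    def test_planar_rotation_rate(self):
        omega = 0.7
        t = np.linspace(0.0, 3 * 2 * np.pi / omega, 2000)
        X = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
        sm = StackedMatrix(X, ((0, len(t)),), dt=t[1] - t[0])
        res = fit_skew(sm, k=2, center=False)
        expected = np.array([[0.0, -omega], [omega, 0.0]])
        np.testing.assert_allclose(res.ambient_generator(), expected, atol=1e-3)
        assert res.frequencies[0] == pytest.approx(omega, rel=1e-3)

    def test_skew_constraint_exact_and_spectrum_imaginary(self, wave_ds):
        sm = stack_conditions(preprocess_apply(wave_ds))
        res = fit_skew(sm, k=6)
        np.testing.assert_array_equal(res.M_skew, -res.M_skew.T)
        assert np.max(np.abs(np.linalg.eigvals(res.M_skew).real)) < 1e-10

    def test_orthonormal_bases(self, wave_ds):
        sm = stack_conditions(preprocess_apply(wave_ds))
        res = fit_skew(sm, k=6)
        np.testing.assert_allclose(res.pca_basis.T @ res.pca_basis, np.eye(6), atol=1e-10)
        np.testing.assert_allclose(res.plane_basis.T @ res.plane_basis, np.eye(2), atol=1e-10)

    def test_skew_fit_never_beats_unconstrained(self, wave_ds):
        sm = stack_conditions(preprocess_apply(wave_ds))
        assert fit_skew(sm, k=6).fit_r2 <= fit_unconstrained_r2(sm, k=6) + 1e-12

    def test_fit_is_global_optimum(self):
        """Convexity probe: no random skew perturbation lowers the residual."""
        rng = np.random.default_rng(3)
        M = random_skew(4, rng)
        sm = trajectories_from_generator(M, rng.normal(size=(5, 4)),
                                         np.linspace(0.0, 4.0, 200))
        res = fit_skew(sm, k=4, center=False)
        scores = (sm.X - res.pca_mean) @ res.pca_basis
        d_scores = np.vstack([np.gradient(scores[s:e], sm.dt, axis=0)
                              for s, e in sm.boundaries])
        best = np.linalg.norm(d_scores - scores @ res.M_skew.T) ** 2
        for _ in range(100):
            P = random_skew(4, rng, scale=1e-3)
            perturbed = np.linalg.norm(d_scores - scores @ (res.M_skew + P).T) ** 2
            assert perturbed >= best - 1e-12

    def test_odd_k_rejected(self, small_wave_ds):
        with pytest.raises(ValueError):
            fit_skew(stack_conditions(small_wave_ds), k=5)

    def test_rank_deficient_data_raises_helpfully(self):
        X = np.outer(np.linspace(0, 1, 30), np.ones(6))
        sm = StackedMatrix(X, ((0, 30),))
        with pytest.raises(np.linalg.LinAlgError, match="lower k"):
            fit_skew(sm, k=4)


class TestEvolve:
    def test_norm_conserved(self):
        rng = np.random.default_rng(0)
        M = random_skew(6, rng)
        x0 = rng.normal(size=6)
        X = evolve(M, x0, np.linspace(0.0, 10.0, 200))
        np.testing.assert_allclose(np.linalg.norm(X, axis=1), np.linalg.norm(x0),
                                   atol=1e-10)

    def test_zero_generator_is_constant(self):
        X = evolve(np.zeros((3, 3)), np.array([1.0, -2.0, 0.5]), np.arange(5.0))
        np.testing.assert_array_equal(X, np.tile([1.0, -2.0, 0.5], (5, 1)))

    def test_period_of_planar_rotation(self):
        omega = 2.0
        M = np.array([[0.0, -omega], [omega, 0.0]])
        X = evolve(M, np.array([1.0, 0.0]), np.array([0.0, 2 * np.pi / omega]))
        np.testing.assert_allclose(X[1], X[0], atol=1e-12)

    def test_non_skew_rejected(self):
        with pytest.raises(ValueError):
            evolve(np.array([[0.1, 0.0], [0.0, 0.0]]), np.ones(2), np.arange(3.0))


class TestProjections:
    def test_wave_conditions_rotate_in_common_direction(self, wave_ds):
        sm = stack_conditions(preprocess_apply(wave_ds))
        res = fit_skew(sm, k=6)
        signs = [np.sign(mean_angular_velocity(p)) for p in res.projections]
        assert all(s == signs[0] for s in signs)
        assert signs[0] > 0  # counter-clockwise orientation convention

    def test_evolved_model_projects_to_constant_radius(self):
        rng = np.random.default_rng(5)
        M = random_skew(4, rng)
        sm = trajectories_from_generator(M, rng.normal(size=(3, 4)),
                                         np.linspace(0.0, 5.0, 300))
        res = fit_skew(sm, k=4, center=False)
        # evolve within the fitted reduced space from a plane state
        x0 = res.plane_basis[:, 0]
        traj = evolve(res.M_skew, x0, np.linspace(0.0, 5.0, 100)) @ res.plane_basis
        radii = np.linalg.norm(traj, axis=1)
        np.testing.assert_allclose(radii, radii[0], rtol=1e-8)

    def test_frequency_agrees_with_differential_covariance_on_planar_data(self):
        """On a near-planar wave both methods see the same rotating mode
        (threshold frozen from a brute-force pre-computation)."""
        from rotwave import differential_covariance

        ds = generate_dataset(WaveModelParams(b=0.1, sigma=10.0))
        sm = stack_conditions(preprocess_apply(ds, PreprocessConfig(kernel_ms=0.0)))
        res = fit_skew(sm, k=2)
        M = differential_covariance(sm, side="neuron")
        C = sm.X.T @ sm.X
        vals, vecs = np.linalg.eig(M)
        i = int(np.argmax(np.abs(vals)))
        v = vecs[:, i]
        omega = abs(vals[i].imag) / np.real(np.conj(v) @ C @ v)
        assert abs(res.frequencies[0] - omega) / omega < 0.15
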