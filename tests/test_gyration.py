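import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rotwave import (
    PopulationDataset,
    PreprocessConfig,
    StackedMatrix,
    WaveModelParams,
    differential_covariance,
    eigenspectrum,
    generate_dataset,
    gyration_number,
    gyration_pipeline,
    gyration_plane,
    stack_conditions,
)


def rotation_matrix_data(omega=1.0, periods=3, n=1500, radius=1.0):
    t = np.linspace(0.0, 2 * np.pi * periods / omega, n)
    X = radius * np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    return StackedMatrix(X, ((0, n),), dt=t[1] - t[0])


class TestDifferentialCovariance:
    def test_circular_motion_gives_skew_matrix(self):
        M = differential_covariance(rotation_matrix_data(), side="neuron")
        sym = 0.5 * (M + M.T)
        assert np.linalg.norm(sym) / np.linalg.norm(M) < 1e-3

    def test_pure_growth_gives_symmetric_matrix(self):
        t = np.linspace(0.0, 2.0, 500)
        X = np.column_stack([np.exp(t), np.zeros_like(t)])
        M = differential_covariance(StackedMatrix(X, ((0, 500),), dt=t[1] - t[0]))
        assert M[0, 1] == 0 and M[1, 0] == 0
        assert M[0, 0] > 0

    def test_wave_dataset_nearly_skew(self, wave_ds):
        """Travelling-wave data: symmetric residual comes only from the
        window-edge cutoff (threshold frozen from a brute-force run)."""
        M = differential_covariance(stack_conditions(wave_ds))
        sym = 0.5 * (M + M.T)
        assert np.linalg.norm(sym) / np.linalg.norm(M) < 0.12

    def test_sides_share_nonzero_spectrum(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 30))
        sm = StackedMatrix(X, ((0, 30), (30, 60)))
        ev_n = np.sort_complex(eigenspectrum(differential_covariance(sm, "neuron")))
        ev_t = eigenspectrum(differential_covariance(sm, "time"))
        ev_t = np.sort_complex(ev_t[np.argsort(-np.abs(ev_t))][:30])
        scale = np.abs(ev_n).max()
        np.testing.assert_allclose(ev_n, ev_t, atol=1e-8 * scale)

    def test_short_block_rejected(self):
        sm = StackedMatrix(np.zeros((4, 3)), ((0, 2), (2, 4)))
        with pytest.raises(ValueError):
            differential_covariance(sm)


class TestEigenspectrum:
    def test_rotation_generator(self):
        ev = eigenspectrum(np.array([[0.0, -2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(sorted(ev.imag), [-2.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(ev.real, 0.0, atol=1e-12)

    def test_diagonal_matrix(self):
        ev = eigenspectrum(np.diag([3.0, 1.0]))
        np.testing.assert_allclose(ev, [3.0, 1.0])

    def test_sorted_by_modulus_descending(self):
        rng = np.random.default_rng(1)
        ev = eigenspectrum(rng.normal(size=(12, 12)))
        mods = np.abs(ev)
        assert np.all(np.diff(mods) <= 1e-12)


class TestGyrationNumber:
    def test_planar_rotation_is_pure_imaginary(self):
        res = gyration_number(rotation_matrix_data())
        assert res.x == pytest.approx(0.0, abs=1e-3)
        assert res.y == pytest.approx(1.0, abs=1e-3)
        assert res.is_structural_rotation

    def test_pure_decay_has_no_rotation(self):
        t = np.linspace(0.0, 3.0, 400)
        X = np.column_stack([np.exp(-t), 0.5 * np.exp(-2.0 * t)])
        res = gyration_number(StackedMatrix(X, ((0, 400),), dt=t[1] - t[0]))
        assert res.y == pytest.approx(0.0, abs=1e-8)
        assert not res.is_structural_rotation

    def test_coordinates_in_unit_square(self, wave_ds):
        res = gyration_pipeline(wave_ds)
        assert 0.0 <= res.x <= 1.0 and 0.0 <= res.y <= 1.0

    def test_spectrum_closed_under_conjugation(self, wave_ds):
        res = gyration_pipeline(wave_ds)
        ev = res.eigenvalues
        scale = np.abs(ev).max()
        conj_sorted = np.sort_complex(np.conj(ev))
        np.testing.assert_allclose(np.sort_complex(ev), conj_sorted, atol=1e-8 * scale)

    def test_both_product_sizes_give_same_coordinates(self):
        ds = generate_dataset(
            WaveModelParams(n_neurons=12, n_time=40, n_conditions=2, a=5.0, b=2.0, sigma=5.0)
        )
        sm = stack_conditions(ds)
        res_n = gyration_number(sm)
        ev_t = eigenspectrum(differential_covariance(sm, "time"))
        total = np.abs(ev_t).sum()
        y_t = (abs(ev_t[0].imag) + abs(ev_t[1].imag)) / total
        assert res_n.y == pytest.approx(y_t, rel=1e-8, abs=1e-10)

    def test_invariant_under_orthogonal_neuron_rotation(self, small_wave_ds):
        rng = np.random.default_rng(9)
        n = small_wave_ds.n_neurons
        q, _ = np.linalg.qr(rng.normal(size=(n, n)))
        rotated = small_wave_ds.with_rates(small_wave_ds.rates @ q)
        a = gyration_number(small_wave_ds)
        b = gyration_number(rotated)
        assert b.x == pytest.approx(a.x, abs=1e-8)
        assert b.y == pytest.approx(a.y, abs=1e-8)

    def test_all_zero_data_rejected(self):
        ds = PopulationDataset(np.zeros((2, 10, 3)), 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            gyration_number(ds)

    def test_slow_wave_collapses_to_decay(self):
        """A near-standing wave clipped at the window edge is pure decay."""
        slow = gyration_pipeline(generate_dataset(WaveModelParams(b=0.01)))
        ref = gyration_pipeline(generate_dataset(WaveModelParams(b=1.0)))
        assert slow.y < ref.y
        assert slow.x > 0.9 and not slow.is_structural_rotation
        assert ref.is_structural_rotation

    def test_fast_narrow_wave_loses_decay_component(self):
        """Speeding the wave up and narrowing it empties the decay axis."""
        cfg = PreprocessConfig(kernel_ms=0.0)
        res = gyration_pipeline(
            generate_dataset(WaveModelParams(b=2.0, sigma=5.0)), cfg
        )
        assert res.x < 0.01 and res.y > res.x

    def test_dominance_threshold_gates_classification(self, wave_ds):
        lax = gyration_pipeline(wave_ds, dominance_threshold=0.0)
        strict = gyration_pipeline(wave_ds, dominance_threshold=0.99)
        assert lax.is_structural_rotation
        assert not strict.is_structural_rotation

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_coordinates_bounded_for_random_data(self, seed):
        rng = np.random.default_rng(seed)
        ds = PopulationDataset(rng.normal(size=(2, 8, 4)), 1.0)
        res = gyration_number(ds)
        assert 0.0 <= res.x <= 1.0
        assert 0.0 <= res.y <= 1.0
        assert res.x + res.y <= np.sqrt(2.0) * res.pair_share + 1e-12


class TestGyrationPlane:
    def test_scatter_with_and_without_insets(self, small_wave_ds, tmp_path):
        res = gyration_pipeline(small_wave_ds)
        fig = gyration_plane([("wave", res)], path=tmp_path / "plane.png",
                             insets={"wave": np.random.default_rng(0).normal(size=(30, 2))})
        assert (tmp_path / "plane.png").exists()
        assert fig.axes
        gyration_plane([("wave", res)])  # empty-inset mode

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gyration_plane([])
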