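import numpy as np
import pytest

from qmricsr.forward_model import (
    DualPreconditioner,
    NufftOperator,
    batch_adjoint,
    batch_forward,
    build_preconditioner,
    nudft_adjoint,
    nudft_forward,
    power_method_norm,
)
from conftest import dense_nudft_matrix


class TestExactNudft:
    def test_forward_matches_dense_oracle(self, small_instance):
        shape, coords, u, mat = small_instance
        got = nudft_forward(u, coords)
        want = mat @ u.ravel()
        assert np.linalg.norm(got - want) <= 1e-12 * np.linalg.norm(want)

    def test_adjoint_matches_dense_oracle(self, small_instance, rng):
        shape, coords, u, mat = small_instance
        s = rng.standard_normal(len(coords)) + 1j * rng.standard_normal(len(coords))
        got = nudft_adjoint(s, coords, shape)
        want = (mat.conj().T @ s).reshape(shape)
        assert np.linalg.norm(got - want) <= 1e-12 * np.linalg.norm(want)

    def test_centered_delta_gives_flat_spectrum(self, small_instance):
        shape, coords, _, _ = small_instance
        delta = np.zeros(shape, complex)
        delta[shape[0] // 2, shape[1] // 2, shape[2] // 2] = 1.0
        np.testing.assert_allclose(nudft_forward(delta, coords), 1.0, atol=1e-12)

    def test_dc_sample_is_image_sum(self, small_instance):
        shape, _, u, _ = small_instance
        s = nudft_forward(u, np.zeros((1, 3)))
        assert s[0] == pytest.approx(u.sum(), rel=1e-12)

    def test_adjoint_of_dc_sample_is_constant(self, small_instance):
        shape, _, _, _ = small_instance
        v = nudft_adjoint(np.ones(1, complex), np.zeros((1, 3)), shape)
        np.testing.assert_allclose(v, 1.0, atol=1e-13)

    def test_psf_center_is_sample_count(self, small_instance):
        shape, coords, _, _ = small_instance
        delta = np.zeros(shape, complex)
        c = (shape[0] // 2, shape[1] // 2, shape[2] // 2)
        delta[c] = 1.0
        psf = nudft_adjoint(nudft_forward(delta, coords), coords, shape)
        assert psf[c].real == pytest.approx(len(coords), rel=1e-12)

    def test_out_of_range_coords_rejected(self):
        with pytest.raises(ValueError):
            NufftOperator(np.array([[0.5, 0.0, 0.0]]), (8, 8, 8))
        with pytest.raises(ValueError):
            NufftOperator(np.array([[np.nan, 0.0, 0.0]]), (8, 8, 8))


class TestGridding:
    @pytest.fixture(scope="class")
    def instance(self):
        rng = np.random.default_rng(7)
        shape = (16, 16, 16)
        coords = rng.uniform(-0.5, np.nextafter(0.5, 0), (600, 3))
        u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        return shape, coords, u

    def test_matches_exact_nudft(self, instance):
        shape, coords, u = instance
        op = NufftOperator(coords, shape, mode="gridding")
        ref = nudft_forward(u, coords)
        assert np.linalg.norm(op.forward(u) - ref) <= 1e-5 * np.linalg.norm(ref)

    def test_adjoint_matches_exact(self, instance, rng):
        shape, coords, u = instance
        op = NufftOperator(coords, shape, mode="gridding")
        s = rng.standard_normal(len(coords)) + 1j * rng.standard_normal(len(coords))
        ref = nudft_adjoint(s, coords, shape)
        assert np.linalg.norm(op.adjoint(s) - ref) <= 1e-5 * np.linalg.norm(ref)

    def test_on_grid_coords_reproduce_fft(self, rng):
        shape = (16, 16, 16)
        ii = rng.integers(-8, 8, (300, 3))
        coords = ii / 16.0
        u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        op = NufftOperator(coords, shape, mode="gridding", oversampling=2.0)
        ref = nudft_forward(u, coords)  # the exact transform == centered FFT samples
        assert np.linalg.norm(op.forward(u) - ref) <= 1e-8 * np.linalg.norm(ref)

    def test_forward_adjoint_are_exact_transposes(self, instance, rng):
        shape, coords, u = instance
        op = NufftOperator(coords, shape, mode="gridding")
        y = rng.standard_normal(len(coords)) + 1j * rng.standard_normal(len(coords))
        lhs = np.vdot(y, op.forward(u))
        rhs = np.vdot(op.adjoint(y), u)
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_linearity(self, instance, rng):
        shape, coords, u = instance
        op = NufftOperator(coords, shape, mode="gridding")
        v = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        np.testing.assert_allclose(
            op.forward(u + v), op.forward(u) + op.forward(v), rtol=1e-12
        )

    def test_error_decreases_with_kernel_width(self, instance):
        shape, coords, u = instance
        ref = nudft_forward(u, coords)
        errs = []
        for w in (4, 6, 8):
            op = NufftOperator(coords, shape, mode="gridding", kernel_width=w)
            errs.append(np.linalg.norm(op.forward(u) - ref))
        assert errs[0] > errs[1] > errs[2]

    def test_batch_paths_match_per_contrast(self, instance, rng):
        shape, coords, u = instance
        ops = [
            NufftOperator(
                rng.uniform(-0.5, np.nextafter(0.5, 0), (100, 3)), shape, mode="gridding"
            )
            for _ in range(3)
        ]
        u4 = rng.standard_normal(shape + (3,)) + 1j * rng.standard_normal(shape + (3,))
        got = batch_forward(ops, u4)
        for n, op in enumerate(ops):
            np.testing.assert_allclose(got[n], op.forward(u4[..., n]), rtol=1e-12)
        s2 = rng.standard_normal((3, 100)) + 1j * rng.standard_normal((3, 100))
        back = batch_adjoint(ops, s2)
        for n, op in enumerate(ops):
            np.testing.assert_allclose(back[..., n], op.adjoint(s2[n]), rtol=1e-12)

    def test_odd_kernel_width_rejected(self, instance):
        shape, coords, _ = instance
        with pytest.raises(ValueError):
            NufftOperator(coords, shape, mode="gridding", kernel_width=5)
        with pytest.raises(ValueError):
            NufftOperator(coords, shape, mode="gridding", oversampling=0.8)


class TestPreconditioner:
    def test_row_sum_matches_dense_oracle(self, small_instance):
        shape, coords, _, mat = small_instance
        op = NufftOperator(coords, shape, mode="exact_nudft")
        got = build_preconditioner(op, strategy="row_sum").weights
        want = 1.0 / np.abs(mat).sum(axis=1)
        np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_row_sum_single_voxel_is_one(self):
        op = NufftOperator(np.zeros((5, 3)), (1, 1, 1), mode="exact_nudft")
        np.testing.assert_allclose(
            build_preconditioner(op, strategy="row_sum").weights, 1.0
        )

    def test_uniform_cartesian_sampling_gives_equal_weights(self):
        n = 8
        g = np.stack(
            [a.ravel() for a in np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")],
            axis=1,
        ) / n
        op = NufftOperator(g, (n, n, n), mode="exact_nudft")
        for strategy in ("row_sum", "gram"):
            w = build_preconditioner(op, strategy=strategy).weights
            np.testing.assert_allclose(w, w[0], rtol=1e-8)

    def test_gram_matches_dense_formula(self, small_instance):
        shape, coords, _, mat = small_instance
        op = NufftOperator(coords, shape, mode="exact_nudft")
        got = build_preconditioner(op, strategy="gram").weights
        gram = mat @ mat.conj().T
        want = np.real(np.diag(gram)) / (np.abs(gram) ** 2).sum(axis=1)
        np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_weights_depend_only_on_geometry(self, small_instance):
        shape, coords, _, _ = small_instance
        a = build_preconditioner(NufftOperator(coords, shape, mode="exact_nudft"), "gram")
        b = build_preconditioner(NufftOperator(coords, shape, mode="exact_nudft"), "gram")
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_positive_weights_enforced(self):
        with pytest.raises(ValueError):
            DualPreconditioner(weights=np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            DualPreconditioner(weights=np.array([1.0, np.inf]))


class TestPowerMethod:
    def test_identity_operator(self):
        lam = power_method_norm(lambda x: x, (5,), iters=10, seed=0)
        assert lam == pytest.approx(1.0, rel=1e-10)

    def test_diagonal_closed_form(self):
        k = np.diag([3.0, 1.0])
        lam = power_method_norm(lambda x: k.T @ (k @ x), (2,), iters=200, seed=0)
        assert lam == pytest.approx(9.0, rel=1e-6)

    def test_dense_random_matches_eigendecomposition(self, rng):
        k = rng.standard_normal((12, 9)) + 1j * rng.standard_normal((12, 9))
        p = rng.uniform(0.5, 2.0, 12)
        normal = lambda x: k.conj().T @ (p * (k @ x))
        want = np.linalg.eigvalsh(k.conj().T @ (p[:, None] * k)).max()
        got = power_method_norm(normal, (9,), iters=2000, seed=1, tol=1e-10)
        assert got == pytest.approx(want, rel=1e-4)

    def test_warns_when_not_converged(self):
        k = np.diag([1.0, 0.999])
        with pytest.warns(UserWarning):
            power_method_norm(lambda x: k @ x, (2,), iters=2, seed=0, tol=0.0)
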