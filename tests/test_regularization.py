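import numpy as np
import pytest
from scipy.optimize import minimize

from qmricsr.regularization import (
    BlockPartition,
    assemble_blocks,
    extract_blocks,
    grad_contrast,
    grad_contrast_adjoint,
    grad_spatial,
    grad_spatial_adjoint,
    huber_dual_prox,
    huber_value,
    llr_prox,
    nuclear_norm_sum,
    svt,
    tv_dual_prox,
)


# -- gradients -------------------------------------------------------------

class TestGradients:
    def test_constant_volume_has_zero_gradient(self):
        u = np.full((5, 6, 7, 3), 2.5 + 1j)
        assert np.all(grad_spatial(u) == 0)
        assert np.all(grad_contrast(u) == 0)

    def test_linear_ramp_gradient(self):
        u = np.zeros((6, 5, 5, 2), complex)
        u += 3.0 * np.arange(6)[:, None, None, None]
        g = grad_spatial(u)
        assert np.allclose(g[0, :-1], 3.0)
        assert np.all(g[0, -1] == 0)  # Neumann boundary
        assert np.all(g[1] == 0) and np.all(g[2] == 0)

    def test_contrast_progression(self):
        u = np.zeros((4, 4, 4, 5), complex) + np.arange(0, 10, 2)
        g = grad_contrast(u)
        assert g.shape[-1] == 4
        assert np.allclose(g, 2.0)

    def _dense(self, op, in_shape, out_shape, rng):
        """Build the dense matrix of a linear map by applying it to a basis."""
        n = int(np.prod(in_shape))
        cols = []
        for i in range(n):
            e = np.zeros(n, complex)
            e[i] = 1.0
            cols.append(op(e.reshape(in_shape)).ravel())
        return np.array(cols).T

    def test_spatial_adjoint_matches_dense_transpose(self, rng):
        shape = (4, 3, 3, 2)
        mat = self._dense(grad_spatial, shape, None, rng)
        y = rng.standard_normal((3,) + shape) + 1j * rng.standard_normal((3,) + shape)
        got = grad_spatial_adjoint(y).ravel()
        want = mat.conj().T @ y.ravel()
        assert np.linalg.norm(got - want) <= 1e-12 * max(np.linalg.norm(want), 1)

    def test_contrast_adjoint_matches_dense_transpose(self, rng):
        shape = (3, 3, 3, 4)
        mat = self._dense(grad_contrast, shape, None, rng)
        y = rng.standard_normal(shape[:3] + (3,)) + 1j * rng.standard_normal(shape[:3] + (3,))
        got = grad_contrast_adjoint(y).ravel()
        want = mat.conj().T @ y.ravel()
        assert np.linalg.norm(got - want) <= 1e-12 * max(np.linalg.norm(want), 1)


# -- numeric prox oracles --------------------------------------------------

def _numeric_prox(f, v, t, method="Nelder-Mead"):
    """prox_{t f}(v) for complex vectors by brute-force minimization."""
    v = np.asarray(v, complex)

    def obj(xr):
        x = xr[: v.size] + 1j * xr[v.size:]
        return 0.5 * np.sum(np.abs(x - v.ravel()) ** 2) + t * f(x.reshape(v.shape))

    x0 = np.concatenate([v.real.ravel(), v.imag.ravel()])
    if method == "Nelder-Mead":
        res = minimize(obj, x0, method=method,
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 40000})
    else:  # smooth near the solution: quasi-Newton with tight gradient tol
        res = minimize(obj, x0, method=method, options={"gtol": 1e-12, "maxiter": 10000})
    return (res.x[: v.size] + 1j * res.x[v.size:]).reshape(v.shape)


class TestTvDualProx:
    def test_inside_ball_unchanged(self, rng):
        y = 0.1 * (rng.standard_normal((3, 2, 2, 2, 1)) + 0j)
        out = tv_dual_prox(y, weight=10.0, coupled_axis=0)
        np.testing.assert_allclose(out, y)

    def test_radial_scaling(self):
        y = np.zeros((3, 1, 1, 1, 1), complex)
        y[0] = 2.0
        out = tv_dual_prox(y, weight=1.0, coupled_axis=0)
        assert out[0, 0, 0, 0, 0] == pytest.approx(1.0)
        assert np.all(out[1:] == 0)

    def test_moreau_identity_against_numeric_primal_prox(self, rng):
        """prox of the conjugate (projection) + numeric prox of w*||.||_2 = id."""
        w, sigma = 0.7, 1.3
        v = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        dual = tv_dual_prox(v.reshape(3, 1, 1, 1, 1), weight=w, coupled_axis=0).ravel()
        primal = _numeric_prox(lambda x: w * np.linalg.norm(x), v / sigma, 1.0 / sigma)
        np.testing.assert_allclose(dual + sigma * primal, v, atol=2e-5)

    def test_scalar_coupling_projects_entrywise(self, rng):
        y = np.array([3.0 + 4.0j, 0.1j])
        out = tv_dual_prox(y, weight=1.0, coupled_axis=None)
        assert abs(out[0]) == pytest.approx(1.0)
        assert out[1] == 0.1j

    def test_nonexpansive(self, rng):
        a = rng.standard_normal((3, 4)) + 1j * rng.standard_normal((3, 4))
        b = rng.standard_normal((3, 4)) + 1j * rng.standard_normal((3, 4))
        pa = tv_dual_prox(a, 0.5, coupled_axis=0)
        pb = tv_dual_prox(b, 0.5, coupled_axis=0)
        assert np.linalg.norm(pa - pb) <= np.linalg.norm(a - b) + 1e-12


class TestHuber:
    def test_value_branches(self):
        g = 0.4
        assert huber_value(0.0, g) == 0.0
        assert huber_value(g, g) == pytest.approx(g / 2)
        assert huber_value(3 * g, g) == pytest.approx(2.5 * g)

    def test_value_continuity_at_knee(self):
        g = 0.7
        eps = 1e-9
        below = huber_value(g - eps, g)
        above = huber_value(g + eps, g)
        assert above - below == pytest.approx(0.0, abs=1e-8)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            huber_value(1.0, 0.0)

    def test_gamma_zero_limit_is_tv_prox(self, rng):
        y = rng.standard_normal((3, 2, 2, 2, 2)) + 1j * rng.standard_normal((3, 2, 2, 2, 2))
        a = huber_dual_prox(y, weight=0.5, gamma=0.0, sigma=1.0, coupled_axis=0)
        b = tv_dual_prox(y, weight=0.5, coupled_axis=0)
        np.testing.assert_allclose(a, b)

    def test_zero_maps_to_zero(self):
        y = np.zeros((3, 1, 1, 1, 1), complex)
        assert np.all(huber_dual_prox(y, 1.0, 0.1, 1.0, 0) == 0)

    def test_moreau_identity_against_numeric_oracle(self, rng):
        """Dual prox of weight*H_gamma verified through the Moreau identity
        with a brute-force numeric primal prox."""
        w, g, sigma = 0.8, 0.3, 1.7
        v = np.array([rng.standard_normal() + 1j * rng.standard_normal()])

        def f(x):
            return w * float(huber_value(np.abs(x), g).sum())

        dual = huber_dual_prox(v, weight=w, gamma=g, sigma=sigma, coupled_axis=None)
        primal = _numeric_prox(f, v / sigma, 1.0 / sigma)
        np.testing.assert_allclose(dual + sigma * primal, v, atol=2e-5)


# -- blocks / SVT ----------------------------------------------------------

class TestBlocks:
    def test_global_block_limit(self, rng):
        u = rng.standard_normal((4, 4, 4, 3)) + 0j
        blocks = extract_blocks(u, BlockPartition(block_size=4))
        assert blocks.shape == (1, 64, 3)

    def test_block_indexing(self):
        u = np.arange(4 ** 3 * 2, dtype=float).reshape(4, 4, 4, 2) + 0j
        blocks = extract_blocks(u, BlockPartition(block_size=2, shifts=(0, 0, 0)))
        assert blocks.shape == (8, 8, 2)
        np.testing.assert_array_equal(blocks[0, 0], u[0, 0, 0])

    @pytest.mark.parametrize("shape,b", [((4, 4, 4, 3), 2), ((6, 6, 6, 2), 4), ((8, 6, 4, 2), 3)])
    def test_round_trip_exact_with_random_shifts(self, shape, b, rng):
        u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        for _ in range(3):
            part = BlockPartition(block_size=b, shifts=tuple(rng.integers(0, b, 3)))
            back = assemble_blocks(extract_blocks(u, part), part, u.shape)
            np.testing.assert_array_equal(back, u)

    def test_oversized_block_rejected(self, rng):
        u = rng.standard_normal((4, 4, 4, 2)) + 0j
        with pytest.raises(ValueError):
            extract_blocks(u, BlockPartition(block_size=5))

    def test_shift_bookkeeping_is_lossless(self, rng):
        """Extracting at shift s equals extracting the pre-rolled volume at
        shift 0: the translation bookkeeping loses nothing."""
        u = rng.standard_normal((8, 8, 8, 3)) + 1j * rng.standard_normal((8, 8, 8, 3))
        for s in [(1, 2, 3), (3, 0, 2)]:
            a = nuclear_norm_sum(u, 4, shifts=s)
            rolled = np.roll(u, shift=[-x for x in s], axis=(0, 1, 2))
            b = nuclear_norm_sum(rolled, 4, shifts=(0, 0, 0))
            assert a == pytest.approx(b, rel=1e-12)
        # and for a globally rank-1 series the block nuclear norms collapse
        # to Frobenius norms under every shift
        v = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        c = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        u1 = v[..., None] * c
        for s in [(0, 0, 0), (1, 2, 3)]:
            blocks = extract_blocks(u1, BlockPartition(4, s))
            want = sum(np.linalg.norm(b) for b in blocks)
            assert nuclear_norm_sum(u1, 4, shifts=s) == pytest.approx(want, rel=1e-10)


class TestSvt:
    def test_zero_threshold_identity(self, rng):
        m = rng.standard_normal((6, 3)) + 1j * rng.standard_normal((6, 3))
        np.testing.assert_array_equal(svt(m, 0.0), m)

    def test_diagonal_closed_form(self):
        m = np.diag([3.0, 1.0]).astype(complex)
        np.testing.assert_allclose(svt(m, 2.0), np.diag([1.0, 0.0]), atol=1e-12)

    def test_matches_numeric_nuclear_prox(self, rng):
        """SVT vs brute-force minimization of 0.5||X-M||_F^2 + t ||X||_*."""
        m = rng.standard_normal((4, 2))  # real instance keeps the search space small
        t = 0.6

        def f(x):
            return float(np.linalg.svd(x.reshape(4, 2), compute_uv=False).sum())

        got = svt(m.astype(complex), t)
        want = _numeric_prox(lambda x: f(x.real), m.astype(complex), t, method="BFGS")
        assert np.linalg.norm(got - want) <= 1e-5 * max(np.linalg.norm(want), 1)

    def test_rank_nonincreasing_and_vanishing(self, rng):
        m = rng.standard_normal((8, 3)) + 1j * rng.standard_normal((8, 3))
        smax = np.linalg.svd(m, compute_uv=False).max()
        ranks = [
            np.linalg.matrix_rank(svt(m, t), tol=1e-10)
            for t in (0.0, 0.3 * smax, 0.8 * smax, smax)
        ]
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))
        assert ranks[-1] == 0

    def test_nonexpansive(self, rng):
        a = rng.standard_normal((5, 3)) + 1j * rng.standard_normal((5, 3))
        b = rng.standard_normal((5, 3)) + 1j * rng.standard_normal((5, 3))
        assert np.linalg.norm(svt(a, 0.7) - svt(b, 0.7)) <= np.linalg.norm(a - b) + 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            svt(np.array([[np.inf, 0.0]]), 1.0)


def test_llr_prox_preserves_rank_one_structure(rng):
    v = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
    c = rng.standard_normal(4) + 1j * rng.standard_normal(4)
    u = v[..., None] * c
    out = llr_prox(u, threshold=1e-3, block_size=4, shifts=(2, 1, 3))
    blocks = extract_blocks(out, BlockPartition(4, (0, 0, 0)))
    s = np.linalg.svd(blocks, compute_uv=False)
    assert np.all(s[:, 1:] <= 1e-6 * s[:, :1])
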