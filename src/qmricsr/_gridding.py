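"""Low-level gather/scatter kernels for Kaiser-Bessel gridding.

Compiled with numba when available; a vectorized numpy fallback keeps the
package functional (slower) without it.  Both paths are exact transposes of
each other, which the adjoint-identity tests rely on.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False, fastmath=True)
def _interp3_nb(grid, ix, wx, iy, wy, iz, wz, out):  # pragma: no cover - compiled
    m, w = ix.shape
    for i in range(m):
        acc = 0.0 + 0.0j
        for a in range(w):
            ga = grid[ix[i, a]]
            fa = wx[i, a]
            for b in range(w):
                gb = ga[iy[i, b]]
                fab = fa * wy[i, b]
                for c in range(w):
                    acc += gb[iz[i, c]] * (fab * wz[i, c])
        out[i] = acc


@njit(cache=False, fastmath=True)
def _spread3_nb(grid, ix, wx, iy, wy, iz, wz, s):  # pragma: no cover - compiled
    m, w = ix.shape
    for i in range(m):
        v = s[i]
        for a in range(w):
            fa = wx[i, a]
            for b in range(w):
                fab = fa * wy[i, b]
                for c in range(w):
                    grid[ix[i, a], iy[i, b], iz[i, c]] += v * (fab * wz[i, c])


def _interp3_np(grid, ix, wx, iy, wy, iz, wz, out):
    w = ix.shape[1]
    out[:] = 0
    for a in range(w):
        for b in range(w):
            wab = wx[:, a] * wy[:, b]
            sub = grid[ix[:, a], iy[:, b]]  # (m, Gz)
            for c in range(w):
                out += sub[np.arange(ix.shape[0]), iz[:, c]] * (wab * wz[:, c])


def _spread3_np(grid, ix, wx, iy, wy, iz, wz, s):
    g1, g2, g3 = grid.shape
    flat = grid.ravel()
    w = ix.shape[1]
    for a in range(w):
        base_a = ix[:, a] * (g2 * g3)
        for b in range(w):
            base_ab = base_a + iy[:, b] * g3
            wab = s * (wx[:, a] * wy[:, b])
            for c in range(w):
                idx = base_ab + iz[:, c]
                vals = wab * wz[:, c]
                flat.real += np.bincount(idx, weights=vals.real, minlength=flat.size)
                flat.imag += np.bincount(idx, weights=vals.imag, minlength=flat.size)


if _HAVE_NUMBA:
    interp3, spread3 = _interp3_nb, _spread3_nb
else:  # pragma: no cover
    interp3, spread3 = _interp3_np, _spread3_np
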