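"""T1 / S0 estimation from a variable-flip-angle image series.

Two routes, both operating on magnitudes (the signal model describes the
magnitude; phase is a separate component):

* :func:`linear_t1_fit` — the classical linearization of the steady-state
  signal equation: plotting ``S/sin(FA)`` against ``S/tan(FA)`` gives a line
  with slope ``E = exp(-TR/T1)`` and intercept ``S0 (1 - E)``.  Fast and
  vectorized; used to screen reconstructions during the grid search.
* :func:`nlls_t1_fit` — per-voxel bounded non-linear least squares on the
  signal equation itself, initialized from the linear fit; used for the
  final maps.

Voxels where a fit is impossible (zero signal, slope outside (0, 1)) carry
the sentinel 0 in both maps and are excluded from metrics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .phantom import AcqParams

__all__ = ["QMaps", "linear_t1_fit", "nlls_t1_fit", "vfa_model"]

T1_BOUNDS_MS = (1.0, 1e5)


@dataclass(frozen=True)
class QMaps:
    """T1 (ms) and S0 volumes with an ROI mask and per-voxel residuals.

    ``t1 > 0`` inside ``roi_mask`` where the fit succeeded; failed voxels
    hold the sentinel 0 (and are masked out of ``roi_mask``'s valid subset
    by consumers via ``valid_mask``).
    """

    t1: np.ndarray
    s0: np.ndarray
    roi_mask: np.ndarray
    fit_residual: np.ndarray

    @property
    def valid_mask(self) -> np.ndarray:
        return self.roi_mask & (self.t1 > 0)


def vfa_model(s0, t1, fa_rad, tr):
    """Steady-state spoiled VFA magnitude signal."""
    e = np.exp(-tr / t1)
    return s0 * (1.0 - e) * np.sin(fa_rad) / (1.0 - e * np.cos(fa_rad))


def linear_t1_fit(series: np.ndarray, acq: AcqParams, mask: np.ndarray | None = None) -> QMaps:
    """Linearized fit: OLS line through ``(S/tan FA, S/sin FA)`` per voxel."""
    if series.shape[-1] != acq.n_contrasts:
        raise ValueError("series contrast count does not match acq")
    if series.shape[-1] < 2:
        raise ValueError("need at least two flip angles")
    s = np.abs(series).astype(np.float64)
    if mask is None:
        mask = np.any(s > 0, axis=-1)

    fa = acq.flip_angles_rad
    xs = s / np.tan(fa)
    ys = s / np.sin(fa)
    n = float(acq.n_contrasts)
    xm = xs.mean(axis=-1, keepdims=True)
    ym = ys.mean(axis=-1, keepdims=True)
    sxx = ((xs - xm) ** 2).sum(axis=-1)
    sxy = ((xs - xm) * (ys - ym)).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        t1 = np.where(
            (slope > 0) & (slope < 1), -acq.tr / np.log(np.clip(slope, 1e-300, 1 - 1e-16)), 0.0
        )
        s0 = np.where(
            (slope > 0) & (slope < 1),
            (ym[..., 0] - slope * xm[..., 0]) / (1.0 - slope),
            0.0,
        )
    bad = ~mask | ~np.isfinite(t1) | (t1 <= 0) | ~np.isfinite(s0) | (s0 < 0)
    t1 = np.where(bad, 0.0, t1)
    s0 = np.where(bad, 0.0, s0)

    resid = np.zeros(mask.shape)
    ok = ~bad
    if np.any(ok):
        pred = vfa_model(s0[ok][:, None], t1[ok][:, None], fa[None, :], acq.tr)
        resid[ok] = np.linalg.norm(s[ok] - pred, axis=-1)
    return QMaps(t1=t1, s0=s0, roi_mask=np.asarray(mask, bool), fit_residual=resid)


def nlls_t1_fit(
    series: np.ndarray,
    acq: AcqParams,
    mask: np.ndarray | None = None,
    init: QMaps | None = None,
) -> QMaps:
    """Per-voxel bounded non-linear least squares on the VFA signal equation.

    Parameters are ``(S0, T1)`` with ``T1`` in [1, 1e5] ms and ``S0 >= 0``;
    initialization comes from ``init`` (typically the linear fit) clipped
    into bounds.  Non-convergent voxels fall back to their initial values,
    flagged through ``fit_residual``.
    """
    if init is None:
        init = linear_t1_fit(series, acq, mask)
    if mask is None:
        mask = init.roi_mask
    mask = np.asarray(mask, bool)
    s = np.abs(series).astype(np.float64)
    fa = acq.flip_angles_rad
    tr = acq.tr

    t1 = np.zeros(mask.shape)
    s0 = np.zeros(mask.shape)
    resid = np.zeros(mask.shape)

    idx = np.argwhere(mask)
    for vox in idx:
        v = tuple(vox)
        y = s[v]
        if not np.any(y > 0):
            continue
        t1_0 = init.t1[v] if init.t1[v] > 0 else 1000.0
        s0_0 = init.s0[v] if init.s0[v] > 0 else float(y.max())
        x0 = np.array(
            [max(s0_0, 1e-12), float(np.clip(t1_0, T1_BOUNDS_MS[0], T1_BOUNDS_MS[1]))]
        )

        def fun(x, y=y):
            return vfa_model(x[0], x[1], fa, tr) - y

        def jac(x):
            e = np.exp(-tr / x[1])
            den = 1.0 - e * np.cos(fa)
            d_s0 = (1.0 - e) * np.sin(fa) / den
            de_dt1 = e * tr / x[1] ** 2
            d_e = x[0] * np.sin(fa) * (np.cos(fa) - 1.0) / den**2
            return np.stack([d_s0, d_e * de_dt1], axis=1)

        try:
            sol = least_squares(
                fun,
                x0,
                jac=jac,
                bounds=([0.0, T1_BOUNDS_MS[0]], [np.inf, T1_BOUNDS_MS[1]]),
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
            )
            s0[v], t1[v] = sol.x
            resid[v] = float(np.linalg.norm(sol.fun))
        except Exception:
            s0[v], t1[v] = x0
            resid[v] = float(np.linalg.norm(fun(x0)))
    return QMaps(t1=t1, s0=s0, roi_mask=mask, fit_residual=resid)
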