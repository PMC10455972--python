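"""Preconditioned primal-dual proximal splitting for the five reconstruction models.

Solves, over the complex image series ``u`` of shape ``(Nx, Ny, Nz, Nc)``,

    LS       : min_u  sum_n ||A_n u_n - m_n||^2
    sTV_cTV  : ... + alpha * ||grad_s u||_1  + beta * ||grad_c u||_1
    sH_cH    : ... + alpha * H_g1(grad_s u)  + beta * H_g2(grad_c u)
    LLR      : ... + alpha * sum_b ||C_b u||_*
    sTV_LLR  : ... + alpha * ||grad_s u||_1  + beta * sum_b ||C_b u||_*

with the Chambolle-Pock-type primal-dual iteration: the data term and the
gradient terms are dualized (the data resolvent carries a diagonal k-space
preconditioner, the gradient duals are ball projections), while the
nuclear-norm term is kept in the primal function G and handled by blockwise
singular-value thresholding with a fresh random spatial shift each iteration.
Step sizes follow sigma = 1, tau = margin / ||K^T P K||_2 with the operator
norm estimated by the power method; the unpreconditioned reference variant
uses sigma = tau = 1 / ||K||_2.  Iterations stop when the relative
differences across the last ``stop_window`` objective values all drop below
``stop_tol``, or at ``max_iters``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_model import (NufftOperator, batch_adjoint, batch_forward,
                            build_preconditioner, power_method_norm)
from .regularization import (
    grad_contrast,
    grad_contrast_adjoint,
    grad_spatial,
    grad_spatial_adjoint,
    huber_dual_prox,
    huber_value,
    llr_prox,
    nuclear_norm_sum,
    tv_dual_prox,
)

__all__ = ["MODELS", "Weights", "SolverSettings", "ReconProblem", "SolveResult",
           "objective", "estimate_norm", "pdps_ls", "pdps_solve"]

MODELS = ("LS", "sTV_cTV", "sH_cH", "LLR", "sTV_LLR")


@dataclass(frozen=True)
class Weights:
    """Regularization weights; which fields matter depends on the model.

    ``alpha``/``beta`` weight the first/second regularization term of the
    chosen model (for LLR, ``alpha`` weights the nuclear term; for sTV_LLR,
    ``alpha`` is spatial TV and ``beta`` the nuclear term).  ``gamma1`` and
    ``gamma2`` are the Huber knees for the spatial and contrast gradients.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    block_size: int = 8


@dataclass(frozen=True)
class SolverSettings:
    theta: float = 1.0
    sigma: float = 1.0
    max_iters: int = 500
    stop_window: int = 20
    stop_tol: float = 1e-3
    seed: int = 0
    preconditioned: bool = True
    precond_strategy: str = "gram"
    power_iters: int = 80
    tau_margin: float = 0.99
    # the power method approaches ||K^T P K|| from below (slowly, when the
    # top eigenvalues cluster); inflating the estimate keeps sigma*tau on the
    # convergent side of the strict step-size inequality
    norm_inflation: float = 1.05


@dataclass
class ReconProblem:
    """One reconstruction: per-contrast operators and data, model, weights, settings."""

    operators: tuple[NufftOperator, ...]
    data: np.ndarray  # (Nc, n_samples) complex
    model: str
    weights: Weights = field(default_factory=Weights)
    settings: SolverSettings = field(default_factory=SolverSettings)
    #: optional precomputed dual-preconditioner weights (Nc, n_samples) and
    #: raw ||K^T P K|| estimate; they depend only on the sampling geometry
    #: and which gradient blocks are active, so callers sweeping a weight
    #: grid can reuse them across reconstructions
    precond: "np.ndarray | None" = None
    norm_estimate: "float | None" = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        self.operators = tuple(self.operators)
        self.data = np.ascontiguousarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.operators):
            raise ValueError("data must be (Nc, n_samples) with one operator per contrast")
        shp = self.operators[0].image_shape
        for op in self.operators:
            if op.image_shape != shp:
                raise ValueError("all operators must share one image shape")
            if op.n_samples != self.data.shape[1]:
                raise ValueError("operator/data sample count mismatch")
        w = self.weights
        if self.model == "sH_cH":
            if w.alpha > 0 and w.gamma1 <= 0:
                raise ValueError("sH_cH with alpha > 0 requires gamma1 > 0")
            if w.beta > 0 and w.gamma2 <= 0:
                raise ValueError("sH_cH with beta > 0 requires gamma2 > 0")
        if self.model in ("LLR", "sTV_LLR") and w.block_size < 1:
            raise ValueError("LLR models require block_size >= 1")
        for name in ("alpha", "beta", "gamma1", "gamma2"):
            if getattr(w, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.operators[0].image_shape

    @property
    def n_contrasts(self) -> int:
        return len(self.operators)

    # which penalty sits on which block for this model
    @property
    def _terms(self) -> dict:
        w = self.weights
        m = self.model
        return {
            "grad_s": w.alpha if m in ("sTV_cTV", "sH_cH", "sTV_LLR") else 0.0,
            "grad_c": w.beta if m in ("sTV_cTV", "sH_cH") else 0.0,
            "llr": w.alpha if m == "LLR" else (w.beta if m == "sTV_LLR" else 0.0),
            "huber": m == "sH_cH",
        }


@dataclass(frozen=True)
class SolveResult:
    image: np.ndarray
    objective_trace: np.ndarray
    iterations_run: int
    stop_reason: str  # "criterion" | "max_iters"


def objective(problem: ReconProblem, u: np.ndarray) -> float:
    """Model objective at ``u`` (LLR terms evaluated at zero shift for determinism)."""
    if u.shape != problem.image_shape + (problem.n_contrasts,):
        raise ValueError("image series has the wrong shape")
    r = batch_forward(problem.operators, u) - problem.data
    val = float(np.vdot(r, r).real)
    t = problem._terms
    w = problem.weights
    if t["grad_s"] > 0:
        mag = np.sqrt((np.abs(grad_spatial(u)) ** 2).sum(axis=0))
        if t["huber"]:
            val += t["grad_s"] * float(huber_value(mag, w.gamma1).sum())
        else:
            val += t["grad_s"] * float(mag.sum())
    if t["grad_c"] > 0:
        mag = np.abs(grad_contrast(u))
        if t["huber"]:
            val += t["grad_c"] * float(huber_value(mag, w.gamma2).sum())
        else:
            val += t["grad_c"] * float(mag.sum())
    if t["llr"] > 0:
        val += t["llr"] * nuclear_norm_sum(u, w.block_size)
    return val


def estimate_norm(
    ops,
    precond: np.ndarray,
    grad_s_active: bool,
    grad_c_active: bool,
    power_iters: int = 80,
    seed: int = 0,
) -> float:
    """Raw power-method estimate of ||K^T P K|| for the stacked model operator."""
    shape4 = ops[0].image_shape + (len(ops),)

    def normal_apply(u: np.ndarray) -> np.ndarray:
        out = batch_adjoint(ops, precond * batch_forward(ops, u))
        if grad_s_active:
            out += grad_spatial_adjoint(grad_spatial(u))
        if grad_c_active:
            out += grad_contrast_adjoint(grad_contrast(u))
        return out

    return power_method_norm(normal_apply, shape4, iters=power_iters, seed=seed)


def _shift_stream(seed: int, iteration: int, block_size: int) -> tuple[int, int, int]:
    """Counter-based random spatial shift: reproducible and restartable."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(101, int(iteration)))
    )
    return tuple(int(s) for s in rng.integers(0, block_size, size=3))


def pdps_solve(problem: ReconProblem) -> SolveResult:
    """Run the (preconditioned) primal-dual iteration for any model."""
    st = problem.settings
    t = problem._terms
    w = problem.weights
    nc = problem.n_contrasts
    shape = problem.image_shape
    shape4 = shape + (nc,)
    m = problem.data
    ops = problem.operators

    if not st.preconditioned:
        precond = np.ones_like(m, dtype=np.float64)
    elif problem.precond is not None:
        precond = np.asarray(problem.precond, dtype=np.float64)
    else:
        precond = np.stack(
            [build_preconditioner(op, st.precond_strategy).weights for op in ops]
        )

    if problem.norm_estimate is not None:
        lam = float(problem.norm_estimate)
    else:
        lam = estimate_norm(
            ops, precond, t["grad_s"] > 0, t["grad_c"] > 0, st.power_iters, st.seed
        )
    lam = max(lam * st.norm_inflation, np.finfo(float).tiny)
    if st.preconditioned:
        sigma = st.sigma
        tau = st.tau_margin / (sigma * lam)
    else:
        sigma = tau = 1.0 / np.sqrt(lam)

    def reg_value(uu: np.ndarray) -> float:
        val = 0.0
        if t["grad_s"] > 0:
            mag = np.sqrt((np.abs(grad_spatial(uu)) ** 2).sum(axis=0))
            val += t["grad_s"] * float(
                huber_value(mag, w.gamma1).sum() if t["huber"] else mag.sum()
            )
        if t["grad_c"] > 0:
            mag = np.abs(grad_contrast(uu))
            val += t["grad_c"] * float(
                huber_value(mag, w.gamma2).sum() if t["huber"] else mag.sum()
            )
        if t["llr"] > 0:
            val += t["llr"] * nuclear_norm_sum(uu, w.block_size)
        return val

    dt = ops[0].dtype if hasattr(ops[0], "dtype") else np.dtype(np.complex128)
    precond = precond.astype(np.float32 if dt == np.dtype(np.complex64) else np.float64)
    m = m.astype(dt)
    u = np.zeros(shape4, dtype=dt)
    u_prev = u.copy()
    p = np.zeros_like(m)
    ys = np.zeros((3,) + shape4, dtype=dt) if t["grad_s"] > 0 else None
    yc = np.zeros(shape[:3] + (nc - 1,), dtype=dt) if t["grad_c"] > 0 else None
    # forward transforms of the current and previous iterate: by linearity
    # A ubar = 2 A u_k - A u_{k-1}, so the over-relaxed dual step and the
    # objective's residual share one forward transform per iteration.
    au_cur = np.zeros_like(m)
    au_prev = np.zeros_like(m)

    objs: list[float] = []
    stop_reason = "max_iters"
    iters_run = st.max_iters
    for k in range(st.max_iters):
        ubar = 2.0 * u - u_prev  # theta = 1 over-relaxation
        au_bar = 2.0 * au_cur - au_prev

        p = (p + precond * sigma * (au_bar - m)) / (1.0 + precond * sigma / 2.0)
        if ys is not None:
            z = ys + sigma * grad_spatial(ubar)
            if t["huber"]:
                ys = huber_dual_prox(z, t["grad_s"], w.gamma1, sigma, coupled_axis=0)
            else:
                ys = tv_dual_prox(z, t["grad_s"], coupled_axis=0)
        if yc is not None:
            z = yc + sigma * grad_contrast(ubar)
            if t["huber"]:
                yc = huber_dual_prox(z, t["grad_c"], w.gamma2, sigma, coupled_axis=None)
            else:
                yc = tv_dual_prox(z, t["grad_c"], coupled_axis=None)

        g = batch_adjoint(ops, p)
        if ys is not None:
            g += grad_spatial_adjoint(ys)
        if yc is not None:
            g += grad_contrast_adjoint(yc)

        u_new = u - tau * g
        if t["llr"] > 0:
            shifts = _shift_stream(st.seed, k, w.block_size)
            u_new = llr_prox(u_new, tau * t["llr"], w.block_size, shifts)

        u_prev, u = u, u_new
        au_prev = au_cur
        au_cur = batch_forward(ops, u)

        resid = au_cur - m
        f = float(np.vdot(resid, resid).real) + reg_value(u)
        if not np.isfinite(f):
            raise RuntimeError(f"objective diverged at iteration {k + 1}")
        objs.append(f)
        if len(objs) > st.stop_window:
            tail = objs[-(st.stop_window + 1):]
            rel = max(
                abs(tail[i + 1] - tail[i]) / abs(tail[i + 1]) for i in range(st.stop_window)
            )
            if rel < st.stop_tol:
                stop_reason = "criterion"
                iters_run = k + 1
                break
    else:
        iters_run = st.max_iters
        stop_reason = "max_iters"

    return SolveResult(
        image=u,
        objective_trace=np.asarray(objs),
        iterations_run=iters_run,
        stop_reason=stop_reason,
    )


def pdps_ls(problem: ReconProblem) -> SolveResult:
    """Least-squares specialization (Algorithm-2-style loop)."""
    if problem.model != "LS":
        raise ValueError("pdps_ls requires model='LS'")
    return pdps_solve(problem)
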