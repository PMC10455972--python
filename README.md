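# qmricsr

Compressed-sensing reconstruction and T1 mapping for **3D radial
variable-flip-angle (VFA) quantitative MRI**.

Quantitative T1 mapping needs several volumes at different flip angles,
which makes 3D acquisitions slow; center-out radial sampling plus
compressed sensing recovers the image series from a fraction of the data.
This package implements and compares the standard sparse and low-rank
reconstruction models for that setting, for researchers who want a
self-contained, CPU-only reference implementation with a simulated ground
truth.

## What it implements

Given per-contrast radial k-space `m_n = A_n u_n + e_n` (`A_n` a NUFFT),
five reconstructions of the complex series `u`:

* **LS** — `min Σ_n ‖A_n u_n − m_n‖²` (no regularization),
* **sTV+cTV** — `+ α‖∇_s u‖₁ + β‖∇_c u‖₁` (isotropic spatial TV, contrast TV),
* **sH+cH** — Huber-smoothed gradients `+ α H_γ1(∇_s u) + β H_γ2(∇_c u)`,
* **LLR** — locally low rank: `+ α Σ_b ‖C_b u‖_*` over 8³ Casorati blocks,
* **sTV+LLR** — spatial TV plus the nuclear-norm term,

all solved by one **primal-dual proximal splitting** loop with a diagonal
k-space preconditioner for the dual variable (σ = 1,
τ = 0.99/‖KᵀPK‖₂ via the power method; stop when 20 successive relative
objective differences drop below 1e-3, or at 500 iterations).  T1 and S0
maps come from the steady-state VFA signal equation
`S = S0 (1−E) sin FA / (1 − E cos FA)`, `E = exp(−TR/T1)`, by a linearized
fit (grid-search screening) and bounded non-linear least squares (final
maps); maps are scored with nRMSE and SSIM inside a region of interest.

A synthetic study is built in: a digital relaxometry phantom (separate S0,
T1, phase volumes), complementary uniform center-out trajectories that are
unique per contrast, exact-NUDFT k-space simulation and 2% complex
Gaussian noise.  See `docs/methods.md` for the model equations,
conventions and numerical choices.

## Worked example

```python
import numpy as np
from qmricsr import (AcqParams, ExperimentConfig, NufftOperator, ReconProblem,
                     SolverSettings, Weights, downsample, generate_trajectory,
                     linear_t1_fit, make_phantom, nrmse, pdps_solve,
                     simulate_kspace, vfa_signal)

# simulate a 32^3 phantom acquisition: 12 flip angles, 2% noise
ph = make_phantom((32, 32, 32), seed=1)
acq = AcqParams(tr=5.0)                      # 1..8,10,12,14,20 degrees
series = vfa_signal(ph, acq)
trajs = [generate_trajectory(32, 64, 48, contrast_index=n, seed=1)
         for n in range(acq.n_contrasts)]
ks = simulate_kspace(series, trajs, noise_pct=2.0, seed=1)

# reconstruct at acceleration factor 8 with spatial+contrast TV
ops, data = [], []
for n, t in enumerate(trajs):
    sub, plan = downsample(t, 8)
    ops.append(NufftOperator(sub.all_coords(), ph.shape, mode="gridding",
                             oversampling=1.5, kernel_width=4))
    data.append(ks.samples[n][:sub.n_samples])
res = pdps_solve(ReconProblem(
    operators=tuple(ops), data=np.stack(data), model="sTV_cTV",
    weights=Weights(alpha=0.03, beta=0.06),
    settings=SolverSettings(max_iters=100, stop_tol=1e-3, seed=1)))
maps = linear_t1_fit(res.image, acq, ph.support_mask)
roi = ph.support_mask & maps.valid_mask
print(f"{res.iterations_run} iterations ({res.stop_reason}); "
      f"T1 nRMSE vs ground truth: {nrmse(maps.t1, ph.t1, roi):.4f}")
```

prints

```
100 iterations (max_iters); T1 nRMSE vs ground truth: 0.1500
```

i.e. the TV-regularized T1 map is within ~15% of the ground truth at
eight-fold undersampling, where the unregularized LS reconstruction of the
same data reaches ~0.40 on the linearized fit.  The full sweep (five
models × accelerations 4/8/20, grid-searched weights, NLLS-refit winners)
is one call:

```python
report = run_experiment(ExperimentConfig(), output_dir="results/exp")
```

which writes `summary.csv` / `report.json` with one row per (model, AF):
best weights, iterations, T1/S0 nRMSE and SSIM.

There is also a thin CLI (`qmricsr trajgen / simulate / recon / fit /
evaluate / experiment`); run `qmricsr --help`.

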