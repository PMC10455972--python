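# Methods

This note documents the models, algorithms and numerical choices behind
`qmricsr`, and what the synthetic study does and does not demonstrate.

## Measurement model

A variable-flip-angle (VFA) acquisition produces `Nc` complex 3D images
`u_n` (contrasts), each measured on its own 3D radial k-space trajectory:

    m_n = A_n u_n + e_n,

where `A_n` is the non-uniform Fourier (NUFFT) operator for contrast `n`
and `e_n` is complex Gaussian noise.  Conventions, fixed package-wide:
image voxels are centered integers with the origin at index `floor(N/2)`;
the forward transform is the unnormalized sum
`s(k) = Σ_x u(x) exp(-2πi k·x)` with `k` in cycles/FOV inside `[-0.5, 0.5)`;
the adjoint is the exact conjugate transpose.

Two operator implementations share this contract:

* **exact NUDFT** — the direct sum, used as oracle and by default up to
  16³ voxels (dense-cached for small instances);
* **Kaiser–Bessel gridding** — interpolation on an oversampled FFT grid.
  The deapodizer is the DFT of the integer-sampled kernel rather than the
  kernel's continuous Fourier transform; this makes on-grid coordinates
  reproduce the centered FFT to machine precision, and with the default
  oversampling 2.0 and (even) kernel width 8 the relative error against the
  exact transform is ~1e-7 (~1.5e-5 at width 6).  The β shape parameter
  follows the standard aliasing-optimal formula.  Forward and adjoint are
  exact transposes of one another regardless of the approximation error,
  which the solver's convergence theory relies on.

## Trajectories and undersampling

Each contrast uses `n_subsets` complementary subsets of center-out spokes.
Spoke directions are a spherical-Fibonacci lattice over the union of all
subsets, dealt round-robin so every subset alone covers the sphere
quasi-uniformly; a per-contrast random rotation (deterministic in
`(seed, contrast)`) decorrelates the sampling between contrasts so that
undersampling artifacts are incoherent along the contrast dimension.
Radial samples are linearly spaced from 0 to `0.5·(1 − 1/S)`.
Retrospective acceleration keeps the first `round(n_subsets/AF)` whole
subsets — the granularity at which a genuinely shorter scan would be run —
and the realized AF (`n_subsets/kept`) is reported, since requested
non-divisor AFs cannot be realized exactly.

## Reconstruction models

All models minimize a data-consistency term plus regularization over the
4D complex series `u` (voxels × contrasts):

| model   | objective |
|---------|-----------|
| LS      | `Σ_n ‖A_n u_n − m_n‖²` |
| sTV+cTV | `… + α‖∇_s u‖₁ + β‖∇_c u‖₁` |
| sH+cH   | `… + α H_γ1(∇_s u) + β H_γ2(∇_c u)` |
| LLR     | `… + α Σ_b ‖C_b u‖_*` |
| sTV+LLR | `… + α‖∇_s u‖₁ + β Σ_b ‖C_b u‖_*` |

Spatial TV is isotropic: the three forward differences (Neumann boundary)
are coupled under one pointwise 2-norm per voxel and contrast; contrast TV
is a separate scalar penalty on forward differences along the flip-angle
axis.  Magnitudes are complex moduli and ball projections scale complex
entries radially — the images are complex and the penalties must be
phase-equivariant.  The Huber function `H_γ` is quadratic below the knee
`γ` and linear above, trading TV's staircasing for controlled smoothness;
separate knees γ1 (spatial) and γ2 (contrast) keep contrast-dimension
smoothing mild.  `C_b` extracts non-overlapping `b×b×b` blocks (cyclic
padding when a dimension is not divisible) and reshapes each to a
`b³ × Nc` Casorati matrix; `‖·‖_*` is the nuclear norm, whose prox is
singular-value soft-thresholding (SVT).  Translation invariance of the
blocking is approximated by drawing a fresh uniform cyclic shift in
`[0, b)³` at every iteration from a counter-based stream (seed, iteration),
so runs are bit-reproducible and restartable.  Block size defaults to
b = 8; the blocks hold complex values.

## Solver

All five problems are solved by one primal-dual proximal-splitting loop
(`min F(Ku) + G(u)`).  The dualization layout:

* data blocks `A_n` — dualized; the resolvent of `‖·−m‖²` with a diagonal
  k-space preconditioner `P` is `p ← (p + Pσ(Aū − m))/(1 + Pσ/2)`;
* gradient blocks — dualized; TV duals are projections onto the
  `weight`-ball, Huber duals shrink by `1/(1 + σγ/weight)` before
  projecting (the conjugate adds a quadratic inside the ball indicator);
* the nuclear-norm term stays in `G` on the primal side: after the primal
  gradient step, blockwise SVT at threshold `τ·weight` under the current
  random shift.

The primal update is `u ← u − τ Kᵀ(dual)`, over-relaxation θ = 1, zero
initialization for all variables.  Keeping the LLR term in `G` avoids
dualizing the nuclear norm and is verified by oracle equivalence on small
instances (any valid splitting shares the minimizer).  By linearity,
`A ū = 2 A u_k − A u_{k−1}`, so one forward transform per contrast per
iteration serves both the over-relaxed dual step and the objective.

**Step sizes.**  σ = 1 and τ = 0.99/‖KᵀPK‖₂, with the norm estimated by
the power method.  Because the power iteration approaches the norm from
below (slowly when the top eigenvalues cluster), the estimate is inflated
by 5% before use — without this the strict inequality στ < 1/‖KᵀPK‖₂ can
silently fail and the iteration stalls.  The unpreconditioned reference
variant uses σ = τ = 1/‖K‖₂.

**Preconditioner.**  `build_preconditioner` exposes two strategies.
`row_sum` is the classical diagonal rule `P_i = 1/Σ_j |A_ij|`; for a
unit-modulus Fourier kernel every row sum equals the voxel count, so the
rule reduces to a uniform rescaling and measurably does not accelerate
convergence (it matches the unpreconditioned variant to within one
iteration on radial test instances).  The default `gram` strategy builds
the diagonal approximate inverse of the sample Gram matrix `G = AAᴴ`:
`P_i = G_ii / Σ_j |G_ij|²`, the row-wise least-squares solution of
`PG ≈ I`.  Since `G_ij` depends only on `k_i − k_j`, the row norms are
computed matrix-free with two transforms on a doubled grid (the grid
autocorrelation weights `Π_a (N_a − |d_a|)` supply the `Σ_x` inner
structure).  Center-out radial sampling concentrates samples near k = 0,
so these weights grow toward the k-space edge and flatten the spectrum of
`AᴴPA` — the measured effect on a radial least-squares instance is
convergence to the stop criterion while the unpreconditioned variant
exhausts its iteration budget at an objective two orders of magnitude
higher.  On *uniform* random sampling the gram weights are nearly flat and
the benefit disappears (the dense-oracle equivalence test therefore uses
`row_sum`).

**Stopping.**  The objective (evaluated every iteration; LLR terms at zero
shift for determinism) stops the loop when all successive relative
differences across the last 20 values fall below `stop_tol` (1e-3 for
simulated data; 1e-2 is the suggested setting for measured data, where
k-coordinate inaccuracies and noise keep the floor higher), or at
`max_iters` = 500.  Slight objective oscillations are expected under θ = 1
and the tests deliberately assert only windowed decrease, never strict
monotonicity.  Note the relative-difference rule fires on *flatness*: a
badly conditioned unpreconditioned run can trigger it while still far from
the minimum, which is why convergence comparisons should always report the
attained objective alongside the iteration count.

## Phantom and simulation

The synthetic phantom supplies separate S0, T1 and phase volumes on a
cubic grid: an outer spherical shell, a background compartment, four
embedded spheres with distinct (S0, T1) pairs, and thin high-contrast rods
that expose blur and staircasing.  The T1 palette {300, 600, 1000, 1500,
2500} ms spans a realistic relaxometry range (>8× ratio); S0 is order 1.
The phase is a linear ramp along the first axis from zero back to zero
with a single wrap at the midplane, wrapped into (−π, π].  The VFA series
follows the steady-state spoiled signal equation

    S_n = S0 (1 − E) sin(FA_n) / (1 − E cos(FA_n)),  E = exp(−TR/T1),

times `exp(i·phase)`, with the 12-angle schedule 1–8, 10, 12, 14, 20° and
TR = 5 ms (a typical short-TR steady-state value; TR and T1 share
milliseconds).  k-space is simulated with the exact NUDFT up to 16³ and
with high-accuracy gridding (oversampling 2, width 8, ~1e-7) above — the
reconstruction operator is a *different*, coarser discretization
(oversampling 1.5, width 4, single precision), so the inverse crime of
reconstructing with the identical forward model is avoided.

**Noise.**  "2% complex Gaussian noise" is implemented so that the complex
noise standard deviation `sqrt(var(Re) + var(Im))` equals 2% of the mean
absolute noiseless sample over the dataset, i.e. per-component std
`0.02·mean|m|/√2`.  The percentage reading is ambiguous between
per-component and complex-modulus conventions; the modulus convention is
the natural reading of "standard deviation of complex noise" and is the
documented, configurable choice.  Streams are independent across contrasts
(seed-derived child sequences).

## T1/S0 fitting

Magnitude images are fitted (the signal model describes magnitudes; the
phase is a separate component).  The linearized route regresses
`S/sin(FA)` on `S/tan(FA)`; the slope is `E` and T1 = −TR/ln(slope), with
slopes outside (0, 1) mapped to the sentinel 0 and excluded from metrics.
The non-linear route solves per-voxel bounded least squares on the signal
equation (T1 ∈ [1, 10⁵] ms, S0 ≥ 0, analytic Jacobian, tolerances 1e-10),
initialized from the linear fit.  The grid search scores candidates with
the fast linear fit; only the winning reconstruction is refit with NLLS —
on noiseless signals both routes invert the model exactly, while under
noise the NLLS estimate has visibly lower error and bias.

## Metrics

nRMSE(x) = ‖x − ref‖₂/‖ref‖₂ over the ROI (support voxels with valid,
non-sentinel fits in both maps).  SSIM uses a 3D Gaussian window (σ = 1.5,
width 11) with K1 = 0.01, K2 = 0.03; the local SSIM map is computed over
the full volume and then averaged over the ROI, avoiding window-edge bias
from masking before filtering.  The dynamic range comes from the reference
map on the ROI (the reference is the fixed comparator, so the score is
deliberately not symmetric in its arguments).

## Experiment design and desk-scale defaults

The default study: 32³ phantom, 12 contrasts, 32 subsets × 64 spokes × 48
samples per contrast (98,304 samples at AF 1), 2% noise, AF ∈ {4, 8} for
all models plus AF 20 for the two LLR variants (with 32 subsets a
requested AF 20 realizes as 16 and is reported as such).  The reference
for simulated data is the phantom ground truth; for data without ground
truth the reference policy reconstructs the full data with the smallest
grid weights ("slight regularization") and NLLS-fits it.  Regularization
weights come from a per-model grid search minimizing linear-fit T1 nRMSE
against the reference, ties broken toward smaller total weight; default
grids are two-point brackets around the optima observed for the default
conditions (spatial-TV weights ~0.01–0.06, nuclear weights ~0.1–0.3,
Huber knees 0.005 — absolute values tied to the phantom's order-1 S0
scale).  Desk-scale solver settings — iteration cap 100, single-precision
gridding at oversampling 1.5 / width 4, 25 power iterations, preconditioner
and operator-norm estimates cached across grid points — keep the full
model × AF sweep around ten minutes on one CPU; the publication-scale 256³
problem is a configuration change, not a code change.

## What the synthetic study shows — and does not

With these defaults the package reproduces the qualitative findings of
radial VFA compressed sensing: every regularized model clearly beats
unregularized LS (T1 nRMSE ~0.12–0.24 vs ~0.30–0.33); errors grow with
acceleration; spatial-TV-containing models lead; the Huber variant trades
slightly higher noise for less staircasing; plain LLR shows residual noise
and block artifacts that adding spatial TV removes (sTV+LLR < LLR at every
AF).  The phantom is piecewise-structured and therefore favorable to
TV-type priors; real tissue with smooth T1 gradients, B1+ inhomogeneity,
k-coordinate errors, motion, or multi-coil data may reorder the
middle of the ranking, as no noise-free ground truth exists there.  The
simulation uses single-coil, ideal-trajectory, white-noise data by design.

## Known limitations

* Non-overlapping LLR blocks only (overlap multiplies cost); block
  boundary artifacts are mitigated by random shifts and by the sTV+LLR
  combination rather than by overlap.
* No TGV model, no B1+ correction, no multi-coil sensitivity model.
* The gridding kernel width must be even (the offset scheme assumes it).
* The relative-difference stop rule can fire on flat-but-unconverged
  traces (see Solver); iteration-count comparisons need the objective
  value for context.
* CPU implementation; the per-iteration cost is dominated by the
  gather/scatter interpolation and the oversampled FFTs.
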