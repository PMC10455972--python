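"""Digital relaxometry phantom, steady-state VFA signal model and k-space simulation.

The phantom provides separate S0 (proton-density-weighted amplitude), T1
(longitudinal relaxation, milliseconds) and phase volumes.  The complex
variable-flip-angle image series follows the steady-state spoiled signal
equation

    S_n = S0 * (1 - E) * sin(FA_n) / (1 - E * cos(FA_n)),   E = exp(-TR/T1),

multiplied by exp(i * phase).  Simulated radial k-space is the non-uniform
discrete Fourier transform of the series plus complex circular Gaussian
noise at a stated percentage of the mean absolute noiseless sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import RadialTrajectory
from .forward_model import NufftOperator

__all__ = [
    "PhantomVolumes",
    "AcqParams",
    "KSpaceData",
    "DEFAULT_FLIP_ANGLES_DEG",
    "make_phantom",
    "vfa_signal",
    "simulate_kspace",
]

#: flip-angle schedule of the reference VFA protocol (degrees)
DEFAULT_FLIP_ANGLES_DEG = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0, 12.0, 14.0, 20.0)

#: default T1 palette, milliseconds — spans a realistic relaxometry range
DEFAULT_T1_PALETTE_MS = (300.0, 600.0, 1000.0, 1500.0, 2500.0)


@dataclass(frozen=True)
class PhantomVolumes:
    """Ground-truth S0 / T1 / phase volumes with a support mask.

    ``t1`` is in milliseconds and strictly positive inside ``support_mask``
    (sentinel 0 outside); ``s0`` is 0 outside the support; ``phase`` is a
    linear ramp along the first axis running from zero back to zero with a
    single wrap at the midplane, wrapped into (-pi, pi].
    """

    s0: np.ndarray
    t1: np.ndarray
    phase: np.ndarray
    support_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.s0.shape == self.t1.shape == self.phase.shape == self.support_mask.shape):
            raise ValueError("phantom volumes must share one shape")
        if np.any(self.t1[self.support_mask] <= 0):
            raise ValueError("t1 must be positive inside the support")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.s0.shape


@dataclass(frozen=True)
class AcqParams:
    """Acquisition parameters shared by all contrasts: TR (ms), flip angles (deg)."""

    tr: float
    flip_angles: tuple[float, ...] = DEFAULT_FLIP_ANGLES_DEG
    fov: float = 30.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        fas = tuple(float(a) for a in self.flip_angles)
        if any(a <= 0 or a > 90 for a in fas):
            raise ValueError("flip angles must be in (0, 90] degrees")
        if any(b <= a for a, b in zip(fas, fas[1:])):
            raise ValueError("flip angles must be strictly increasing")
        object.__setattr__(self, "flip_angles", fas)

    @property
    def n_contrasts(self) -> int:
        return len(self.flip_angles)

    @property
    def flip_angles_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.flip_angles))


@dataclass(frozen=True)
class KSpaceData:
    """Complex radial samples per contrast, aligned with their trajectories.

    ``samples`` has shape ``(Nc, n_samples)``; ``trajectories`` holds the
    matching :class:`RadialTrajectory` per contrast.
    """

    samples: np.ndarray
    trajectories: tuple[RadialTrajectory, ...]
    noise_pct: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or len(self.trajectories) != self.samples.shape[0]:
            raise ValueError("samples must be (Nc, n_samples) matching trajectories")
        for n, t in enumerate(self.trajectories):
            if t.n_samples != self.samples.shape[1]:
                raise ValueError(f"trajectory {n} does not match sample count")

    @property
    def n_contrasts(self) -> int:
        return self.samples.shape[0]


def _ball(grid: tuple[np.ndarray, ...], center: tuple[float, ...], radius: float) -> np.ndarray:
    d2 = sum((g - c) ** 2 for g, c in zip(grid, center))
    return d2 <= radius**2


def make_phantom(
    shape: tuple[int, int, int],
    seed: int,
    t1_palette: tuple[float, ...] = DEFAULT_T1_PALETTE_MS,
) -> PhantomVolumes:
    """Procedural phantom: outer shell, inner compartments, fine detail rods.

    The layout is an outer spherical shell enclosing a background compartment,
    four embedded spheres with distinct (S0, T1) pairs spanning more than a
    factor of five in T1, and a cluster of small high-contrast rods that
    exercise blur and staircasing behavior.  Deterministic in ``seed`` (the
    seed only jitters compartment centers by a fraction of a voxel pitch).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError("each phantom dimension must be >= 8")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(7,)))

    # normalized coordinates in [-1, 1] per axis
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    grid = np.meshgrid(*axes, indexing="ij", sparse=True)

    s0 = np.zeros(shape)
    t1 = np.zeros(shape)
    r = np.sqrt(sum(g**2 for g in grid))

    interior = r <= 0.80
    shell = (r <= 0.92) & ~interior
    s0[shell], t1[shell] = 1.0, t1_palette[0]
    s0[interior], t1[interior] = 0.8, t1_palette[2]

    # four inner compartments with distinct (S0, T1)
    comp = [
        ((-0.38, -0.30, -0.25), 0.30, 0.95, t1_palette[1]),
        ((0.40, -0.32, 0.20), 0.26, 0.70, t1_palette[3]),
        ((-0.30, 0.40, 0.22), 0.24, 1.10, t1_palette[4]),
        ((0.28, 0.34, -0.30), 0.20, 0.55, t1_palette[0]),
    ]
    for center, radius, amp, tval in comp:
        center = tuple(c + rng.uniform(-0.02, 0.02) for c in center)
        m = _ball(grid, center, radius) & interior
        s0[m], t1[m] = amp, tval

    # small high-contrast detail rods near the center (few-voxel scale)
    rod_w = max(2.0 / min(shape), 0.06)
    for j, off in enumerate((-0.12, 0.0, 0.12)):
        m = (
            (np.abs(grid[0] - off) <= rod_w)
            & (np.abs(grid[1] - 0.02 * j) <= rod_w)
            & (np.abs(grid[2]) <= 0.35)
        )
        m &= interior
        s0[m] = 1.2
        t1[m] = t1_palette[0] if j % 2 == 0 else t1_palette[4]

    support = s0 > 0

    # linear phase ramp along axis 0: 0 -> 2*pi across the volume, wrapped
    # into (-pi, pi]; starts and ends at zero with one wrap at the midplane.
    n0 = shape[0]
    ramp = 2.0 * np.pi * np.arange(n0) / (n0 - 1)
    wrapped = np.angle(np.exp(1j * ramp))
    phase = np.broadcast_to(wrapped[:, None, None], shape).copy()

    return PhantomVolumes(s0=s0, t1=t1, phase=phase, support_mask=support)


def vfa_signal(phantom: PhantomVolumes, acq: AcqParams) -> np.ndarray:
    """Complex VFA image series ``(Nx, Ny, Nz, Nc)`` from the steady-state model.

    Voxels outside the support are exactly zero.
    """
    if np.any(phantom.t1[phantom.support_mask] <= 0):
        raise ValueError("t1 must be positive inside the support")
    mask = phantom.support_mask
    shape = phantom.shape + (acq.n_contrasts,)
    series = np.zeros(shape, dtype=np.complex128)
    t1 = phantom.t1[mask]
    e = np.exp(-acq.tr / t1)[:, None]
    fa = acq.flip_angles_rad[None, :]
    mag = phantom.s0[mask][:, None] * (1.0 - e) * np.sin(fa) / (1.0 - e * np.cos(fa))
    series[mask] = mag * np.exp(1j * phantom.phase[mask])[:, None]
    return series


def simulate_kspace(
    series: np.ndarray,
    trajectories: "tuple[RadialTrajectory, ...] | list[RadialTrajectory]",
    noise_pct: float,
    seed: int,
    engine: str = "auto",
) -> KSpaceData:
    """Simulate noisy radial k-space: NUDFT of the series plus complex noise.

    The complex noise standard deviation, sqrt(var(Re) + var(Im)), equals
    ``noise_pct`` percent of the mean absolute noiseless sample over the whole
    dataset (per-component std is that value / sqrt(2)); noise streams are
    independent across contrasts, derived from ``seed``.

    ``engine`` selects the transform: ``"exact"`` (direct NUDFT),
    ``"gridding"`` (high-accuracy Kaiser-Bessel gridding) or ``"auto"``
    (exact up to 16^3 voxels, gridding above).
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    nc = series.shape[-1]
    if len(trajectories) != nc:
        raise ValueError("one trajectory per contrast is required")
    shape = series.shape[:-1]
    if engine == "auto":
        engine = "exact" if np.prod(shape) <= 4096 else "gridding"
    mode = "exact_nudft" if engine == "exact" else "gridding"

    clean = []
    for n in range(nc):
        op = NufftOperator(
            trajectories[n].all_coords(),
            shape,
            mode=mode,
            oversampling=2.0,
            kernel_width=8,
        )
        clean.append(op.forward(np.ascontiguousarray(series[..., n])))
    clean = np.stack(clean)

    samples = clean
    if noise_pct > 0:
        level = (noise_pct / 100.0) * np.mean(np.abs(clean))
        streams = np.random.SeedSequence(entropy=int(seed), spawn_key=(11,)).spawn(nc)
        noise = np.empty_like(clean)
        for n, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            noise[n] = (level / np.sqrt(2.0)) * (
                rng.standard_normal(clean.shape[1]) + 1j * rng.standard_normal(clean.shape[1])
            )
        samples = clean + noise

    return KSpaceData(
        samples=samples,
        trajectories=tuple(trajectories),
        noise_pct=float(noise_pct),
        seed=int(seed),
    )
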