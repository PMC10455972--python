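"""3D center-out radial trajectories and retrospective undersampling.

A full acquisition consists of ``n_subsets`` complementary trajectory
subsets per contrast, each holding ``spokes_per_subset`` center-out spokes.
The union of all subsets covers the k-space sphere quasi-uniformly, no two
spokes are identical, and each subset alone is also quasi-uniform, so that
retrospective undersampling can keep whole subsets and remain directly
transferable to a practical sparse acquisition.  Different contrasts use
differently rotated direction sets so that undersampling artifacts are
incoherent along the contrast dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RadialTrajectory",
    "SamplingPlan",
    "generate_trajectory",
    "downsample",
]


@dataclass(frozen=True)
class RadialTrajectory:
    """k-space sample coordinates for one contrast.

    ``coords`` has shape ``(n_subsets, spokes_per_subset, samples_per_spoke, 3)``
    in units of cycles/FOV, every component inside ``[-0.5, 0.5)``.  Spokes
    start at the k-space origin and run outward along a fixed direction.
    """

    coords: np.ndarray
    contrast_index: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64)
        if c.ndim != 4 or c.shape[-1] != 3:
            raise ValueError("coords must have shape (subsets, spokes, samples, 3)")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords must be finite")
        if c.min() < -0.5 or c.max() >= 0.5:
            raise ValueError("coords must lie in [-0.5, 0.5)")
        object.__setattr__(self, "coords", c)

    @property
    def n_subsets(self) -> int:
        return self.coords.shape[0]

    @property
    def spokes_per_subset(self) -> int:
        return self.coords.shape[1]

    @property
    def samples_per_spoke(self) -> int:
        return self.coords.shape[2]

    @property
    def n_samples(self) -> int:
        return int(np.prod(self.coords.shape[:3]))

    def all_coords(self) -> np.ndarray:
        """All samples flattened to ``(n_samples, 3)``, subset-major order."""
        return self.coords.reshape(-1, 3)


@dataclass(frozen=True)
class SamplingPlan:
    """Record of which trajectory subsets a reconstruction used.

    The acceleration factor AF is (#full data) / (#data used), recomputed
    from the actually kept subset count, so a requested non-divisor AF is
    reported as realized.
    """

    acceleration_factor: float
    subsets_used: tuple[int, ...]
    full_subset_count: int

    def __post_init__(self) -> None:
        if self.acceleration_factor < 1.0:
            raise ValueError("acceleration_factor must be >= 1")
        used = tuple(int(i) for i in self.subsets_used)
        if any(i < 0 or i >= self.full_subset_count for i in used):
            raise ValueError("subsets_used out of range")
        object.__setattr__(self, "subsets_used", used)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - 2.0 * (i + 0.5) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random 3x3 rotation matrix (normalized random quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_trajectory(
    n_subsets: int,
    spokes_per_subset: int,
    samples_per_spoke: int,
    contrast_index: int = 0,
    seed: int | None = None,
) -> RadialTrajectory:
    """Generate complementary uniform center-out radial subsets for one contrast.

    Spoke directions are a spherical-Fibonacci lattice over the union of all
    subsets, rotated by a deterministic random rotation derived from
    ``(seed, contrast_index)`` so that different contrasts sample k-space
    incoherently.  Directions are dealt round-robin into subsets, which makes
    every subset on its own a (coarser) quasi-uniform cover.  Radial sample
    positions are linearly spaced from 0 to ``0.5 * (1 - 1/samples_per_spoke)``.
    """
    if seed is None:
        raise ValueError("seed is required (trajectory generation is deterministic)")
    if n_subsets < 1 or spokes_per_subset < 1:
        raise ValueError("n_subsets and spokes_per_subset must be >= 1")
    if samples_per_spoke < 2:
        raise ValueError("samples_per_spoke must be >= 2")

    total = n_subsets * spokes_per_subset
    directions = _fibonacci_sphere(total)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(contrast_index),))
    )
    directions = directions @ _random_rotation(rng).T

    kmax = 0.5 * (1.0 - 1.0 / samples_per_spoke)
    radii = np.linspace(0.0, kmax, samples_per_spoke)

    # round-robin deal: direction i goes to subset i % n_subsets
    order = np.arange(total).reshape(spokes_per_subset, n_subsets).T
    dirs = directions[order]  # (n_subsets, spokes_per_subset, 3)
    coords = dirs[:, :, None, :] * radii[None, None, :, None]
    # guard against boundary round-off after rotation
    np.clip(coords, -0.5, np.nextafter(0.5, 0.0), out=coords)
    return RadialTrajectory(coords=coords, contrast_index=int(contrast_index))


def downsample(traj: RadialTrajectory, af: float) -> tuple[RadialTrajectory, SamplingPlan]:
    """Retrospectively undersample by keeping the first ``round(n_subsets/af)`` subsets.

    Whole-subset granularity mirrors how a shorter acquisition would actually
    be run.  The returned plan reports the realized acceleration factor
    ``n_subsets / kept``, which differs from the request at non-divisor AFs.
    """
    if af < 1.0:
        raise ValueError("af must be >= 1")
    if af > traj.n_subsets:
        raise ValueError(f"af={af} exceeds the number of subsets ({traj.n_subsets})")
    kept = int(np.floor(traj.n_subsets / float(af) + 0.5))
    kept = max(kept, 1)
    sub = RadialTrajectory(
        coords=traj.coords[:kept].copy(), contrast_index=traj.contrast_index
    )
    plan = SamplingPlan(
        acceleration_factor=traj.n_subsets / kept,
        subsets_used=tuple(range(kept)),
        full_subset_count=traj.n_subsets,
    )
    return sub, plan
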