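"""Sparsifying operators and proximal maps.

Covers the linear maps and proxes used by the five reconstruction models:
forward-difference spatial and contrast gradients (Neumann boundary), the
dual proxes of isotropic total variation and of the Huber-smoothed variant,
Casorati block extraction for locally low-rank (LLR) penalties, and
singular-value thresholding (the nuclear-norm prox).

Images are complex throughout: norms use complex moduli and ball projections
scale complex entries radially.  The three spatial difference components are
coupled under one pointwise 2-norm per voxel and contrast (isotropic spatial
TV); the contrast-dimension term is a separate scalar penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlockPartition",
    "grad_spatial",
    "grad_spatial_adjoint",
    "grad_contrast",
    "grad_contrast_adjoint",
    "tv_dual_prox",
    "huber_value",
    "huber_dual_prox",
    "extract_blocks",
    "assemble_blocks",
    "svt",
    "llr_prox",
    "nuclear_norm_sum",
]


# -- finite-difference gradients ------------------------------------------

def grad_spatial(u: np.ndarray) -> np.ndarray:
    """Forward differences along x, y, z for a series ``(Nx, Ny, Nz, Nc)``.

    Returns shape ``(3, Nx, Ny, Nz, Nc)``; the difference at the last index
    along each axis is 0 (Neumann boundary).
    """
    g = np.zeros((3,) + u.shape, dtype=u.dtype)
    g[0, :-1] = u[1:] - u[:-1]
    g[1, :, :-1] = u[:, 1:] - u[:, :-1]
    g[2, :, :, :-1] = u[:, :, 1:] - u[:, :, :-1]
    return g


def grad_spatial_adjoint(y: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`grad_spatial` (negative divergence)."""
    out = np.zeros(y.shape[1:], dtype=y.dtype)
    out[:-1] -= y[0, :-1]
    out[1:] += y[0, :-1]
    out[:, :-1] -= y[1, :, :-1]
    out[:, 1:] += y[1, :, :-1]
    out[:, :, :-1] -= y[2, :, :, :-1]
    out[:, :, 1:] += y[2, :, :, :-1]
    return out


def grad_contrast(u: np.ndarray) -> np.ndarray:
    """Forward differences along the contrast axis: ``(Nx, Ny, Nz, Nc-1)``."""
    return u[..., 1:] - u[..., :-1]


def grad_contrast_adjoint(y: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`grad_contrast`."""
    nc = y.shape[-1] + 1
    out = np.zeros(y.shape[:-1] + (nc,), dtype=y.dtype)
    out[..., :-1] -= y
    out[..., 1:] += y
    return out


# -- TV / Huber dual proxes ------------------------------------------------

def _project_ball(y: np.ndarray, radius: float, axis: int | None) -> np.ndarray:
    if axis is None:
        mag = np.abs(y)
    else:
        mag = np.sqrt((np.abs(y) ** 2).sum(axis=axis, keepdims=True))
    scale = radius / np.maximum(mag, radius)
    return y * scale


def tv_dual_prox(y: np.ndarray, weight: float, coupled_axis: int | None = 0) -> np.ndarray:
    """Projection onto the dual-norm ball of radius ``weight``.

    This is the prox of the conjugate of a weighted L1-type norm (an
    indicator function), hence independent of the dual step size.  With
    ``coupled_axis`` set, the components along that axis are coupled under a
    pointwise 2-norm (isotropic TV: pass the axis holding the 3 spatial
    differences); with ``coupled_axis=None`` each complex entry is projected
    on its own (contrast TV).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    return _project_ball(y, weight, coupled_axis)


def huber_value(x: np.ndarray, gamma: float) -> np.ndarray:
    """Huber penalty of ``|x|``: quadratic below ``gamma``, linear above."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a = np.abs(x)
    return np.where(a <= gamma, a**2 / (2.0 * gamma), a - gamma / 2.0)


def huber_dual_prox(
    y: np.ndarray,
    weight: float,
    gamma: float,
    sigma: float,
    coupled_axis: int | None = 0,
) -> np.ndarray:
    """Prox of the conjugate of ``weight * H_gamma``, scaled by dual step ``sigma``.

    The conjugate of the Huber-smoothed norm adds a quadratic
    ``gamma/(2*weight) * ||y||^2`` inside the ``weight``-ball indicator, so the
    prox shrinks by ``1/(1 + sigma*gamma/weight)`` and then projects.  As
    ``gamma -> 0`` this reduces to :func:`tv_dual_prox`.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return _project_ball(y / (1.0 + sigma * gamma / weight), weight, coupled_axis)


# -- locally low rank ------------------------------------------------------

@dataclass(frozen=True)
class BlockPartition:
    """Non-overlapping ``b x b x b`` tiling of a (cyclically shifted) volume."""

    block_size: int
    shifts: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        object.__setattr__(self, "shifts", tuple(int(s) for s in self.shifts))


def _padded_shape(shape: tuple[int, ...], b: int) -> tuple[int, ...]:
    return tuple(-(-s // b) * b for s in shape)


def extract_blocks(u: np.ndarray, part: BlockPartition) -> np.ndarray:
    """Casorati matrices of all blocks: shape ``(n_blocks, b^3, Nc)``.

    The volume is cyclically shifted by ``part.shifts``, padded cyclically to
    a multiple of ``b`` per spatial axis, and tiled.  Voxel ``(0,0,0)`` of the
    shifted volume lands in block 0.
    """
    b = part.block_size
    nx, ny, nz, nc = u.shape
    if b > min(nx, ny, nz):
        raise ValueError("block_size exceeds a volume dimension")
    v = np.roll(u, shift=[-s for s in part.shifts], axis=(0, 1, 2))
    px, py, pz = _padded_shape((nx, ny, nz), b)
    if (px, py, pz) != (nx, ny, nz):
        v = np.pad(v, ((0, px - nx), (0, py - ny), (0, pz - nz), (0, 0)), mode="wrap")
    v = v.reshape(px // b, b, py // b, b, pz // b, b, nc)
    v = v.transpose(0, 2, 4, 1, 3, 5, 6)
    return np.ascontiguousarray(v.reshape(-1, b**3, nc))


def assemble_blocks(
    blocks: np.ndarray, part: BlockPartition, shape: tuple[int, int, int, int]
) -> np.ndarray:
    """Inverse of :func:`extract_blocks`: ``assemble(extract(u)) == u`` exactly.

    Cyclically padded voxels (when a dimension is not a multiple of ``b``)
    are discarded; the primary copy wins.
    """
    b = part.block_size
    nx, ny, nz, nc = shape
    px, py, pz = _padded_shape((nx, ny, nz), b)
    v = blocks.reshape(px // b, py // b, pz // b, b, b, b, nc)
    v = v.transpose(0, 3, 1, 4, 2, 5, 6).reshape(px, py, pz, nc)
    v = v[:nx, :ny, :nz]
    return np.roll(v, shift=list(part.shifts), axis=(0, 1, 2))


def svt(mat: np.ndarray, threshold: float) -> np.ndarray:
    """Singular-value soft-thresholding, the exact prox of ``threshold*||.||_*``.

    Accepts a single matrix or a stack ``(..., m, n)``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite entries")
    if threshold == 0:
        return mat.copy()
    u, s, vh = np.linalg.svd(mat, full_matrices=False)
    s = np.maximum(s - threshold, 0.0)
    return (u * s[..., None, :]) @ vh


def llr_prox(
    u: np.ndarray, threshold: float, block_size: int, shifts: tuple[int, int, int]
) -> np.ndarray:
    """Prox of the shifted blockwise nuclear-norm sum (SVT per Casorati block)."""
    part = BlockPartition(block_size=block_size, shifts=shifts)
    blocks = extract_blocks(u, part)
    return assemble_blocks(svt(blocks, threshold), part, u.shape)


def nuclear_norm_sum(u: np.ndarray, block_size: int, shifts=(0, 0, 0)) -> float:
    """Sum of nuclear norms of the Casorati blocks at the given shift."""
    blocks = extract_blocks(u, BlockPartition(block_size=block_size, shifts=shifts))
    return float(np.linalg.svd(blocks, compute_uv=False).sum())
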