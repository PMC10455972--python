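"""HDF5 / NIfTI containers for trajectories, k-space bundles, reconstructions, maps."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acquisition import RadialTrajectory
from .phantom import AcqParams, KSpaceData

__all__ = [
    "save_phantom",
    "save_trajectories",
    "load_trajectories",
    "save_kspace_bundle",
    "load_kspace_bundle",
    "save_recon",
    "load_recon",
    "save_maps",
]


def save_phantom(outdir, phantom, voxel_size_mm: float = 1.0) -> None:
    """Write s0/t1/phase/support as NIfTI volumes (one file per map)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    for name, vol in (
        ("s0", phantom.s0),
        ("t1", phantom.t1),
        ("phase", phantom.phase),
        ("support", phantom.support_mask.astype(np.uint8)),
    ):
        nib.save(
            nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine),
            outdir / f"{name}.nii.gz",
        )


def save_trajectories(path, trajectories, fov_mm: float = 30.0) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fov_mm"] = float(fov_mm)
        for traj in trajectories:
            g = f.create_group(f"contrast_{traj.contrast_index:03d}")
            g.create_dataset("coords", data=traj.coords)
            g.create_dataset(
                "subset_index",
                data=np.repeat(
                    np.arange(traj.n_subsets),
                    traj.spokes_per_subset * traj.samples_per_spoke,
                ),
            )
            g.attrs["contrast_index"] = traj.contrast_index


def load_trajectories(path) -> list[RadialTrajectory]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(k for k in f if k.startswith("contrast_")):
            g = f[name]
            out.append(
                RadialTrajectory(
                    coords=g["coords"][()], contrast_index=int(g.attrs["contrast_index"])
                )
            )
    return out


def save_kspace_bundle(path, kspace: KSpaceData, acq: AcqParams) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=kspace.samples)
        f.attrs["flip_angle_deg"] = np.asarray(acq.flip_angles)
        f.attrs["tr_ms"] = acq.tr
        f.attrs["fov_mm"] = acq.fov
        f.attrs["noise_pct"] = kspace.noise_pct
        if kspace.seed is not None:
            f.attrs["seed"] = kspace.seed
        for n, traj in enumerate(kspace.trajectories):
            g = f.create_group(f"traj_{n:03d}")
            g.create_dataset("coords", data=traj.coords)
            g.attrs["contrast_index"] = traj.contrast_index


def load_kspace_bundle(path) -> tuple[KSpaceData, AcqParams]:
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        trajs = []
        for n in range(samples.shape[0]):
            g = f[f"traj_{n:03d}"]
            trajs.append(
                RadialTrajectory(
                    coords=g["coords"][()], contrast_index=int(g.attrs["contrast_index"])
                )
            )
        acq = AcqParams(
            tr=float(f.attrs["tr_ms"]),
            flip_angles=tuple(float(a) for a in f.attrs["flip_angle_deg"]),
            fov=float(f.attrs.get("fov_mm", 30.0)),
        )
        ks = KSpaceData(
            samples=samples,
            trajectories=tuple(trajs),
            noise_pct=float(f.attrs.get("noise_pct", 0.0)),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
    return ks, acq


def save_recon(path, image: np.ndarray, objective_trace: np.ndarray, config: dict) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=image)
        f.create_dataset("objective_trace", data=np.asarray(objective_trace))
        f.attrs["config_json"] = json.dumps(config, sort_keys=True)


def load_recon(path) -> tuple[np.ndarray, np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        return (
            f["image"][()],
            f["objective_trace"][()],
            json.loads(f.attrs["config_json"]),
        )


def save_maps(outdir, qmaps, voxel_size_mm: float = 1.0) -> None:
    """Write t1.nii.gz / s0.nii.gz / roi.nii.gz into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(qmaps.t1.astype(np.float32), affine), outdir / "t1.nii.gz")
    nib.save(nib.Nifti1Image(qmaps.s0.astype(np.float32), affine), outdir / "s0.nii.gz")
    nib.save(
        nib.Nifti1Image(qmaps.roi_mask.astype(np.uint8), affine), outdir / "roi.nii.gz"
    )
    with h5py.File(outdir / "maps.h5", "w") as f:
        f.create_dataset("t1_ms", data=qmaps.t1)
        f.create_dataset("s0", data=qmaps.s0)
        f.create_dataset("roi_mask", data=qmaps.roi_mask.astype(np.uint8))
        f.create_dataset("fit_residual", data=qmaps.fit_residual)
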