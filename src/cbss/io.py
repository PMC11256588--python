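"""NIfTI / bval-bvec / table I/O and the phantom cohort disk layout."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import GmAtlas
from .grid import AcquisitionScheme, DiffusionSeries, VoxelGrid
from .phantom import PhantomSpec, PhantomSubject, generate_cohort

__all__ = [
    "write_volume", "read_volume", "write_series", "read_series",
    "write_bvals_bvecs", "read_bvals_bvecs",
    "write_subject", "read_subject", "write_cohort",
    "resample_labels_nearest",
]


def _affine(spacing) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    return aff


def write_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a 3-D map; integer arrays round-trip exactly as labels."""
    path = Path(path)
    data = grid.data
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    nib.save(nib.Nifti1Image(data, _affine(grid.spacing)), str(path))
    return path


def read_volume(path: str | Path, allow_nan: bool = False) -> VoxelGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if not allow_nan and not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(data, spacing)


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    # FSL layout: bvals on one line; bvecs as three rows (x, y, z)
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    rows = ["\t".join(f"{v:.6f}" for v in scheme.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path, b_max: float = 200.0) -> AcquisitionScheme:
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape == (3, bvals.size):
        bvecs = bvecs.T
    return AcquisitionScheme(bvals, bvecs, b_max=b_max)


def write_series(series: DiffusionSeries, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(series.data.astype(np.float64), _affine(series.spacing)), str(path))
    stem = path.name.replace(".nii.gz", "").replace(".nii", "")
    write_bvals_bvecs(series.scheme, path.parent / f"{stem}.bval", path.parent / f"{stem}.bvec")
    return path


def read_series(path: str | Path, b_max: float = 200.0) -> DiffusionSeries:
    path = Path(path)
    stem = path.name.replace(".nii.gz", "").replace(".nii", "")
    bval = path.parent / f"{stem}.bval"
    bvec = path.parent / f"{stem}.bvec"
    if not bval.exists() or not bvec.exists():
        raise FileNotFoundError(f"missing bval/bvec sidecars for {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: series contains non-finite voxels")
    scheme = read_bvals_bvecs(bval, bvec, b_max=b_max)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DiffusionSeries(data, scheme, spacing)


def write_subject(subject: PhantomSubject, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(subject.anat, out / "anat.nii.gz")
    write_volume(subject.atlas.labels, out / "gm_atlas.nii.gz")
    subject.atlas.to_json(out / "gm_atlas.json")
    write_volume(subject.free_water, out / "free_water.nii.gz")
    write_volume(subject.cfa, out / "cfa.nii.gz")
    write_volume(subject.cbf, out / "cbf.nii.gz")
    write_series(subject.series, out / "lowb.nii.gz")
    return out


def read_subject(subject_dir: str | Path, b_max: float = 200.0) -> dict:
    """Load one subject's input maps as a dict of grids and series."""
    d = Path(subject_dir)
    atlas = GmAtlas(read_volume(d / "gm_atlas.nii.gz"), GmAtlas.regions_from_json(d / "gm_atlas.json"))
    return {
        "subject_id": d.name,
        "anat": read_volume(d / "anat.nii.gz"),
        "atlas": atlas,
        "free_water": read_volume(d / "free_water.nii.gz"),
        "cfa": read_volume(d / "cfa.nii.gz"),
        "cbf": read_volume(d / "cbf.nii.gz"),
        "series": read_series(d / "lowb.nii.gz", b_max=b_max),
    }


def write_cohort(spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Generate and write a full phantom cohort under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, table = generate_cohort(spec)
    for s in subjects:
        write_subject(s, out / s.subject_id)
    table.to_csv(out / "covariates.csv")
    spec.to_json(out / "phantom_spec.json")
    return out


def resample_labels_nearest(labels: VoxelGrid, transform: np.ndarray, out_shape=None) -> VoxelGrid:
    """Nearest-neighbor label resampling under a user-supplied rigid
    transform (4x4, world mm coordinates, output-to-input convention).

    Hook for aligning a parcellation with a series acquired in another
    space; inputs generated on a common grid do not need it (identity).
    """
    transform = np.asarray(transform, float)
    if transform.shape != (4, 4):
        raise ValueError("transform must be a 4x4 matrix")
    out_shape = labels.shape if out_shape is None else tuple(out_shape)
    sp = np.asarray(labels.spacing)
    idx = np.indices(out_shape, dtype=float).reshape(3, -1)
    world = idx * sp[:, None]
    src = transform[:3, :3] @ world + transform[:3, 3:4]
    src_idx = src / sp[:, None]
    out = ndimage.map_coordinates(labels.data.astype(np.int32), src_idx, order=0, mode="constant", cval=0)
    return VoxelGrid(out.reshape(out_shape), labels.spacing)
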