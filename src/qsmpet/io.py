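"""File I/O: NIfTI-1 volumes (float32 on disk, float64 in memory), cohort
CSV tables with typed validation, TAC CSVs, and JSON sidecar metadata
recording seed and parameters for every written artifact."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .patlak import Tac
from .volumes import LabeledVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_cohort",
    "write_cohort",
    "read_tac",
    "write_tac",
    "write_sidecar",
]

_SMOKING_LEVELS = {"current", "past", "never"}
_GROUP_LEVELS = {"control", "patient"}
_SEX_LEVELS = {"male", "female"}


def _check_affine(affine, path):
    off_diag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    if np.abs(off_diag).max() > 1e-4:
        warnings.warn(
            f"{path}: affine has rotation/shear terms; only scaling+translation is "
            "interpreted (lattice treated as axis-aligned)"
        )


def read_volume(path) -> LabeledVolume:
    """Read a NIfTI-1 volume; geometry from the (scaling+translation) affine."""
    img = nib.load(str(path))
    aff = img.affine
    _check_affine(aff, path)
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D or 4D NIfTI, got shape {data.shape}")
    voxel_size = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    if data.ndim == 4:  # subject-stacked file: subject axis last on disk
        data3 = data[..., 0]
        vol = LabeledVolume(data3, voxel_size, origin)
        vol.stack_data = np.moveaxis(data, -1, 0)
        return vol
    return LabeledVolume(data, voxel_size, origin)


def write_volume(volume, path, overwrite: bool = False, sidecar: dict | None = None,
                 affine=None):
    """Write a LabeledVolume (or bare 3D/4D array) as float32 NIfTI-1.

    Refuses to overwrite existing files unless ``overwrite`` is set; an
    optional JSON sidecar records seed/parameters next to the image.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if isinstance(volume, LabeledVolume):
        data = volume.data
        affine = volume.affine if affine is None else affine
    else:
        data = np.asarray(volume)
        affine = np.eye(4) if affine is None else np.asarray(affine)
    if data.ndim == 4:  # (subject, x, y, z) in memory -> subject axis last on disk
        data = np.moveaxis(data, 0, -1)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    if sidecar is not None:
        write_sidecar(path, sidecar)
    return path


def write_sidecar(path, meta: dict):
    side = Path(str(path).replace(".nii.gz", "").replace(".nii", "")).with_suffix(".json")
    side.write_text(json.dumps(meta, indent=2, default=str))
    return side


def check_geometry_match(a: LabeledVolume, b: LabeledVolume, name_a="map", name_b="mask"):
    if a.data.shape != b.data.shape or not np.allclose(a.voxel_size, b.voxel_size):
        raise ValueError(
            f"geometry mismatch: {name_a} shape={a.data.shape} voxels={a.voxel_size} vs "
            f"{name_b} shape={b.data.shape} voxels={b.voxel_size}"
        )


def write_cohort(subjects: pd.DataFrame, roi_measures: pd.DataFrame, path,
                 overwrite: bool = False):
    """One row per subject: covariates joined with ROI measures."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    df = subjects.merge(roi_measures, on="subject_id", validate="one_to_one")
    df.to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (typed columns, enum levels checked)."""
    df = pd.read_csv(path)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dup}")
    for col, levels in (("group", _GROUP_LEVELS), ("sex", _SEX_LEVELS),
                        ("smoking", _SMOKING_LEVELS)):
        bad = df.index[~df[col].isin(levels)].tolist()
        if bad:
            raise ValueError(
                f"unknown {col} level(s) {sorted(df.loc[bad, col].unique())} at rows {bad}"
            )
    if (df["age"] < 18).any() or (df["age"] > 45).any():
        raise ValueError("ages outside the admissible 18-45 range")
    df["thc_positive"] = df["thc_positive"].astype(bool)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        import logging

        logging.getLogger(__name__).info("cohort: %d missing cells (expected for controls'"
                                         " clinical fields)", n_missing)
    return df


def write_tac(tac: Tac, path, overwrite: bool = False):
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    start = tac.frame_mid_times - tac.frame_durations / 2
    pd.DataFrame(
        {
            "frame_start_min": start,
            "frame_end_min": start + tac.frame_durations,
            "target_kbq_ml": tac.target_activity,
            "reference_kbq_ml": tac.reference_activity,
        }
    ).to_csv(path, index=False)
    return path


def read_tac(path) -> Tac:
    df = pd.read_csv(path)
    dur = (df["frame_end_min"] - df["frame_start_min"]).to_numpy(float)
    mid = df["frame_start_min"].to_numpy(float) + dur / 2
    return Tac(mid, dur, df["target_kbq_ml"].to_numpy(float),
               df["reference_kbq_ml"].to_numpy(float))
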