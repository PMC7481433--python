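"""Volume readers/writers and cohort manifests.

Supported on-disk forms:

* NIfTI (``.nii`` / ``.nii.gz``) via nibabel — slices are the third axis,
  reordered if necessary so index 0 is the inferior-most slice.
* DICOM series directories via pydicom (read-only) — slices ordered by
  ``ImagePositionPatient`` projected on the slice normal, falling back to
  ``InstanceNumber`` when position tags are missing.
* NPZ fixtures written by this package (lossless, keeps tumor flags and
  lesion masks alongside the intensities).

The canonical in-memory object is :class:`~ggnav.phantom.VolumeStack`,
always ordered inferior-to-superior with 0-based slice indices.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import VolumeStack

__all__ = [
    "read_volume", "write_nifti", "write_npz",
    "read_manifest", "load_cohort",
]

MANIFEST_COLUMNS = ["patient_id", "path", "gg_rp", "gg_nb", "split"]


# ---------------------------------------------------------------- writers

def write_nifti(stack: VolumeStack, path) -> Path:
    """Write slices as a float32 ``.nii``/``.nii.gz`` volume, (H, W, n)."""
    path = Path(path)
    data = np.moveaxis(stack.slices.astype(np.float32), 0, -1)
    affine = np.diag([stack.voxel_spacing[0], stack.voxel_spacing[1],
                      stack.voxel_spacing[2], 1.0])
    img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))
    return path


def write_npz(stack: VolumeStack, path) -> Path:
    path = Path(path)
    payload = {
        "slices": stack.slices.astype(np.float32),
        "tumor_flags": stack.tumor_flags,
        "voxel_spacing": np.asarray(stack.voxel_spacing, dtype=np.float64),
    }
    if stack.gg_rp is not None:
        payload["gg_rp"] = np.array(stack.gg_rp)
    if stack.gg_nb is not None:
        payload["gg_nb"] = np.array(stack.gg_nb)
    if stack.lesion_masks:
        for idx, mask in stack.lesion_masks.items():
            payload[f"mask_{idx}"] = mask
    np.savez_compressed(path, **payload)
    return path


# ---------------------------------------------------------------- readers

def _read_npz(path: Path) -> VolumeStack:
    with np.load(path) as z:
        slices = z["slices"]
        flags = z["tumor_flags"]
        spacing = tuple(z["voxel_spacing"]) if "voxel_spacing" in z \
            else (0.5, 0.5, 3.0)
        gg_rp = int(z["gg_rp"]) if "gg_rp" in z else None
        gg_nb = int(z["gg_nb"]) if "gg_nb" in z else None
        masks = {int(k.split("_")[1]): z[k]
                 for k in z.files if k.startswith("mask_")} or None
    return VolumeStack(patient_id=path.stem, slices=slices, tumor_flags=flags,
                       gg_rp=gg_rp, gg_nb=gg_nb, lesion_masks=masks,
                       voxel_spacing=spacing)


def _read_nifti(path: Path) -> VolumeStack:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    # third-axis direction from the affine: flip so index 0 is inferior
    z_step = img.affine[2, 2]
    if z_step < 0:
        data = data[:, :, ::-1]
    slices = np.moveaxis(data, -1, 0)
    spacing = tuple(float(abs(s)) for s in
                    (img.affine[0, 0], img.affine[1, 1], img.affine[2, 2]))
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return VolumeStack(patient_id=name, slices=np.ascontiguousarray(slices),
                       tumor_flags=np.zeros(len(slices), dtype=bool),
                       voxel_spacing=spacing)


def _read_dicom_dir(path: Path) -> VolumeStack:
    import pydicom

    files = sorted(p for p in path.iterdir()
                   if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise ValueError(f"{path}: no DICOM instances found")
    datasets = [pydicom.dcmread(str(p)) for p in files]
    series_uids = {getattr(d, "SeriesInstanceUID", None) for d in datasets}
    if len(series_uids) > 1:
        offender = next(
            p for p, d in zip(files, datasets)
            if getattr(d, "SeriesInstanceUID", None) != datasets[0].SeriesInstanceUID)
        raise ValueError(
            f"{path}: mixed series in directory (offending instance: "
            f"{offender.name})")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        orient = getattr(ds, "ImageOrientationPatient", None)
        if pos is not None and orient is not None:
            row = np.array(orient[:3], dtype=float)
            col = np.array(orient[3:], dtype=float)
            normal = np.cross(row, col)
            return float(np.dot(np.array(pos, dtype=float), normal))
        return None

    keys = [sort_key(d) for d in datasets]
    if any(k is None for k in keys):
        warnings.warn(f"{path}: missing position tags; ordering by "
                      "InstanceNumber", stacklevel=2)
        order = np.argsort([int(getattr(d, "InstanceNumber", i))
                            for i, d in enumerate(datasets)])
    else:
        order = np.argsort(keys)          # ascending projection = inf->sup
    slices = np.stack([datasets[i].pixel_array.astype(np.float32)
                       for i in order])
    ds0 = datasets[order[0]]
    px = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(ds0, "SliceThickness", 1.0))
    return VolumeStack(patient_id=path.name, slices=slices,
                       tumor_flags=np.zeros(len(slices), dtype=bool),
                       voxel_spacing=(float(px[0]), float(px[1]), dz))


def read_volume(path) -> VolumeStack:
    """Read a volume from NPZ, NIfTI or a DICOM series directory.

    Slices come back ordered inferior-to-superior; tumor flags and grade
    labels are only populated for NPZ fixtures (other formats carry them in
    the cohort manifest).
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path)
    if path.suffix == ".npz":
        return _read_npz(path)
    if path.name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    raise ValueError(f"unrecognized volume format: {path}")


# -------------------------------------------------------------- manifests

def read_manifest(path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "tumor_flags": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"{path}: duplicate patient_id {dup!r}")
    for col in ("gg_rp", "gg_nb"):
        vals = df[col].dropna()
        if not vals.isin([1, 2, 3, 4, 5]).all():
            raise ValueError(f"{path}: {col} values must be in 1..5")
    bad = set(df["split"].dropna()) - {"train", "val", "test"}
    if bad:
        raise ValueError(f"{path}: unknown split values {sorted(bad)}")
    return df


def load_cohort(manifest_path, split: str | None = None) -> list[VolumeStack]:
    """Load the volumes of a manifest, attaching labels and tumor flags."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    if split is not None:
        df = df[df["split"] == split]
    stacks = []
    for _, row in df.iterrows():
        stack = read_volume(manifest_path.parent / row["path"])
        stack.patient_id = row["patient_id"]
        stack.gg_rp = int(row["gg_rp"])
        stack.gg_nb = int(row["gg_nb"])
        if "tumor_flags" in row and isinstance(row["tumor_flags"], str):
            stack.tumor_flags = np.array([c == "1"
                                          for c in row["tumor_flags"]])
        stacks.append(stack)
    return stacks
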