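"""Image/mask readers and writers plus dataset manifests.

Two interchange formats are supported:

* PNG — 8-bit grayscale.  Images in [0, 1] are scaled to 0..255 on write
  and rescaled on read (quantized to 1/255); masks are written with their
  raw label values (0, 1, 255) so they round-trip exactly.
* NIfTI (``.nii`` / ``.nii.gz``) — float32 images, uint8 masks, lossless
  within float32 precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .phantom import PhantomDataset

_PNG_EXT = {".png"}
_NIFTI_EXT = {".nii", ".gz"}  # .nii.gz resolves through .gz


def _kind(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in _PNG_EXT:
        return "png"
    if suffix in _NIFTI_EXT and (suffix == ".nii" or path.suffixes[-2:] == [".nii", ".gz"]):
        return "nifti"
    raise FormatError(
        f"unsupported image format {path.name!r}; supported: .png, .nii, .nii.gz"
    )


def read_image(path) -> np.ndarray:
    """Read a 2-D intensity image; PNG returns values scaled to [0, 1]."""
    path = Path(path)
    kind = _kind(path)
    try:
        if kind == "png":
            arr = np.asarray(iio.imread(path))
            if arr.ndim == 3:  # RGB(A) PNG: keep first three channels
                arr = arr[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
            return arr.astype(np.float64) / 255.0
        img = nib.load(str(path))
        return np.asarray(img.dataobj, dtype=np.float64)
    except FormatError:
        raise
    except Exception as exc:  # corrupt file
        raise FormatError(f"cannot read image {path}: {exc}") from exc


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(image, dtype=np.float64)
    if _kind(path) == "png":
        iio.imwrite(path, np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8))
    else:
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4)), str(path))


def read_mask(path) -> np.ndarray:
    """Read an integer label mask exactly (no intensity rescaling)."""
    path = Path(path)
    try:
        if _kind(path) == "png":
            arr = np.asarray(iio.imread(path))
            if arr.ndim == 3:
                arr = arr[..., 0]
            return arr.astype(np.uint8)
        img = nib.load(str(path))
        return np.asarray(img.dataobj).astype(np.uint8)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read mask {path}: {exc}") from exc


def write_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(mask).astype(np.uint8)
    if _kind(path) == "png":
        iio.imwrite(path, arr)
    else:
        nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def save_dataset(dataset: PhantomDataset, out_dir, fmt: str = "png") -> Path:
    """Write image/mask pairs plus a manifest CSV; returns the manifest path.

    Manifest columns: image_path, mask_path, label, subject_id, modality, seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"png": ".png", "nifti": ".nii.gz"}.get(fmt)
    if ext is None:
        raise FormatError(f"unsupported dataset format {fmt!r}; use png or nifti")
    rows = []
    for i in range(len(dataset)):
        image_path = out_dir / f"img_{i:04d}{ext}"
        mask_path = out_dir / f"mask_{i:04d}{ext}"
        write_image(image_path, dataset.images[i])
        write_mask(mask_path, dataset.masks[i])
        seed = dataset.specs[i].seed if dataset.specs else ""
        rows.append(
            {
                "image_path": image_path.name,
                "mask_path": mask_path.name,
                "label": dataset.labels[i],
                "subject_id": dataset.subject_ids[i],
                "modality": dataset.modality_tags[i],
                "seed": seed,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path) -> PhantomDataset:
    manifest_path = Path(manifest_path)
    frame = pd.read_csv(manifest_path)
    root = manifest_path.parent
    images = [read_image(root / p) for p in frame["image_path"]]
    masks = [read_mask(root / p) for p in frame["mask_path"]]
    return PhantomDataset(
        images=images,
        masks=masks,
        labels=list(frame["label"]),
        subject_ids=list(frame["subject_id"]),
        modality_tags=list(frame["modality"]),
    )


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
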