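"""Format plumbing: NIfTI/PNG image-mask pairs and cohort CSV files.

Conventions: row-major 0-based pixel indices, isotropic spacing in
mm/pixel, masks strictly {0,1} with 1 = lesion.  PNG images are 8-bit and
need a JSON sidecar (``<stem>.spacing.json``) carrying the pixel spacing;
NIfTI files carry spacing in the affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import CLINICAL_FIELDS

__all__ = [
    "write_image_mask_pair",
    "read_image_mask_pair",
    "write_cohort_csv",
    "read_cohort_csv",
]


def _coerce_mask(mask: np.ndarray) -> np.ndarray:
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must contain only 0/1, found {vals[:5]}")
    return mask.astype(np.uint8)


def write_image_mask_pair(image, mask, spacing, image_path, mask_path) -> None:
    """Write an image/mask pair as NIfTI (.nii/.nii.gz) or PNG."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    mask = _coerce_mask(np.asarray(mask))
    image = np.asarray(image, dtype=np.float64)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if image_path.suffix == ".png":
        import imageio.v3 as iio

        lo, hi = image.min(), image.max()
        scaled = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
        iio.imwrite(image_path, (scaled * 255).round().astype(np.uint8))
        iio.imwrite(mask_path, (mask * 255).astype(np.uint8))
        sidecar = image_path.with_suffix("").with_suffix(".spacing.json")
        sidecar.write_text(json.dumps({"pixel_spacing_mm": float(spacing),
                                       "intensity_range": [float(lo), float(hi)]}))
    else:
        affine = np.diag([spacing, spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(image[..., None], affine), image_path)
        nib.save(nib.Nifti1Image(mask[..., None].astype(np.uint8), affine), mask_path)


def read_image_mask_pair(image_path, mask_path):
    """Read a pair; returns (image, mask, spacing_mm).

    PNG pairs require the spacing sidecar written alongside the image.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    if not image_path.exists() or not mask_path.exists():
        raise FileNotFoundError(f"missing {image_path} or {mask_path}")
    if image_path.suffix == ".png":
        import imageio.v3 as iio

        sidecar = image_path.with_suffix("").with_suffix(".spacing.json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing spacing sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        image = iio.imread(image_path).astype(np.float64)
        lo, hi = meta.get("intensity_range", [0.0, 255.0])
        image = image / 255.0 * (hi - lo) + lo
        mask = (iio.imread(mask_path) > 127).astype(np.uint8)
        spacing = float(meta["pixel_spacing_mm"])
    else:
        img = nib.load(image_path)
        image = np.asarray(img.dataobj, dtype=np.float64)[..., 0]
        mask_raw = np.asarray(nib.load(mask_path).dataobj)[..., 0]
        mask = _coerce_mask(mask_raw)
        spacing = float(abs(img.affine[0, 0]))
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    return image, mask, spacing


def cohort_dataframe(cohort) -> pd.DataFrame:
    """One row per phantom: id, 8 clinical fields, 3 label bits, category."""
    rows = []
    for i, ph in enumerate(cohort):
        row = {"id": f"subj{i:04d}"}
        row.update(ph.clinical.as_dict())
        row.update(
            cell_size=ph.label.cell_size,
            keratinization=ph.label.keratinization,
            histology=ph.label.histology,
            category=ph.label.category,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(cohort, path) -> None:
    cohort_dataframe(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", *CLINICAL_FIELDS, "cell_size", "keratinization", "histology", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")
    return df
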