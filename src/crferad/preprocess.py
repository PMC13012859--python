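"""Slice preprocessing: resampling, z-score standardization, stochastic
augmentation and cohort splitting.

Augmentation draws one geometric transform (rotation within +/- a limit,
optional horizontal/vertical flips, isotropic scaling) applied identically
to image and mask, plus additive Gaussian noise applied to the image only.
Images are padded by reflection, masks by zeros, so no lesion pixels are
fabricated at borders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import transform as sktransform

from .phantom import Phantom

__all__ = [
    "AugmentationConfig",
    "SplitSpec",
    "resample",
    "zscore",
    "augment",
    "split_cohort",
]


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_limit: float = 15.0  # degrees
    flip_horizontal: bool = True
    flip_vertical: bool = True
    scale_range: tuple = (0.9, 1.1)
    gaussian_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_limit < 0:
            raise ValueError("rotation_limit must be >= 0")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must be positive and ordered")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be >= 0")


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions) or len(self.fractions) != 3:
            raise ValueError("fractions must be three non-negative numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def resample(
    image: np.ndarray,
    source_spacing: float,
    target_spacing: float,
    is_mask: bool = False,
) -> np.ndarray:
    """Resample a 2-D grid from one isotropic pixel spacing to another.

    Linear interpolation for images, nearest-neighbor for masks; the output
    extent is round(source_extent * source_spacing / target_spacing).
    """
    if source_spacing <= 0 or target_spacing <= 0:
        raise ValueError("spacings must be positive")
    image = np.asarray(image)
    if source_spacing == target_spacing:
        return image.copy()
    out_shape = tuple(
        int(round(s * source_spacing / target_spacing)) for s in image.shape
    )
    order = 0 if is_mask else 1
    out = sktransform.resize(
        image.astype(float),
        out_shape,
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out.astype(image.dtype) if is_mask else out


def zscore(image: np.ndarray) -> np.ndarray:
    """Standardize a slice to zero mean, unit standard deviation."""
    image = np.asarray(image, dtype=float)
    sd = image.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant image (zero variance)")
    return (image - image.mean()) / sd


def _draw_transform(rng: np.random.Generator, config: AugmentationConfig):
    return {
        "angle": float(rng.uniform(-config.rotation_limit, config.rotation_limit)),
        "flip_h": bool(config.flip_horizontal and rng.random() < 0.5),
        "flip_v": bool(config.flip_vertical and rng.random() < 0.5),
        "scale": float(rng.uniform(*config.scale_range)),
    }


def _apply_geometric(grid: np.ndarray, draw: dict, is_mask: bool) -> np.ndarray:
    out = grid.astype(float)
    order = 0 if is_mask else 1
    mode = "constant" if is_mask else "reflect"
    if draw["flip_h"]:
        out = out[:, ::-1]
    if draw["flip_v"]:
        out = out[::-1, :]
    if draw["angle"] != 0.0:
        out = sktransform.rotate(out, draw["angle"], order=order, mode=mode,
                                 cval=0.0, preserve_range=True)
    if draw["scale"] != 1.0:
        h, w = out.shape
        scaled = sktransform.rescale(out, draw["scale"], order=order, mode=mode,
                                     cval=0.0, preserve_range=True)
        sh, sw = scaled.shape
        if draw["scale"] >= 1.0:  # center crop back to original extent
            y0, x0 = (sh - h) // 2, (sw - w) // 2
            out = scaled[y0:y0 + h, x0:x0 + w]
        else:  # pad back to original extent
            py, px = h - sh, w - sw
            pad = ((py // 2, py - py // 2), (px // 2, px - px // 2))
            pmode = "constant" if is_mask else "reflect"
            out = np.pad(scaled, pad, mode=pmode)
    return out


def augment(phantom: Phantom, config: AugmentationConfig, draw: dict | None = None) -> Phantom:
    """Apply one random augmentation draw to a phantom.

    The same geometric transform hits image and mask; Gaussian noise is
    added to the image only and the mask stays strictly binary.  An explicit
    ``draw`` (as produced internally) may be passed for reproducibility.
    """
    rng = np.random.default_rng(config.seed)
    if draw is None:
        draw = _draw_transform(rng, config)
    image = _apply_geometric(phantom.image, draw, is_mask=False)
    mask = _apply_geometric(phantom.mask, draw, is_mask=True)
    if config.gaussian_noise_sd > 0:
        image = image + rng.normal(0.0, config.gaussian_noise_sd, size=image.shape)
    mask = (mask > 0.5).astype(np.uint8)
    return replace(phantom, image=image, mask=mask)


def split_cohort(ids, spec: SplitSpec):
    """Partition subject ids into train/validation/test.

    Validation and test receive floor(fraction * n) subjects each; the
    remainder goes to train (141 subjects at 0.70/0.15/0.15 -> 99/21/21).
    Shuffling is seeded; the partition is disjoint and exhaustive.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    n = len(ids)
    n_val = int(np.floor(spec.fractions[1] * n))
    n_test = int(np.floor(spec.fractions[2] * n))
    rng = np.random.default_rng(spec.seed)
    order = list(rng.permutation(n))
    shuffled = [ids[i] for i in order]
    val = shuffled[:n_val]
    test = shuffled[n_val:n_val + n_test]
    train = shuffled[n_val + n_test:]
    return train, val, test
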