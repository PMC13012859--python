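"""Derived-image filter bank feeding texture analysis.

Nine image types are produced per slice: the original, Laplacian-of-
Gaussian responses at sigma = 1.0 and 2.0 mm (sigma converted to pixels
through the pixel spacing), the single-level wavelet approximation (L)
and the aggregated detail reconstruction (H), and four intensity
transforms (exponential, logarithm, square, square root).  Transforms
with restricted domains shift the image to non-negative support first;
the logarithm additionally shifts by one so the argument is >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["DerivedImage", "DERIVED_KINDS", "derive_images"]

DERIVED_KINDS = (
    "original",
    "log-sigma-1.0mm",
    "log-sigma-2.0mm",
    "wavelet-L",
    "wavelet-H",
    "exponential",
    "logarithm",
    "square",
    "square-root",
)


@dataclass(frozen=True)
class DerivedImage:
    kind: str
    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in DERIVED_KINDS:
            raise ValueError(f"unknown derived-image kind {self.kind!r}")


def _shift_nonneg(image: np.ndarray) -> np.ndarray:
    mn = image.min()
    return image - mn if mn < 0 else image


def _wavelet_pair(image: np.ndarray, wavelet: str):
    """Approximation (L) and summed-detail (H) reconstructions at level 1,
    cropped back to the original extent."""
    h, w = image.shape
    ca, (ch, cv, cd) = pywt.dwt2(image, wavelet, mode="symmetric")
    zeros = np.zeros_like(ca)
    low = pywt.idwt2((ca, (zeros, zeros, zeros)), wavelet, mode="symmetric")
    high = pywt.idwt2((zeros * 0, (ch, cv, cd)), wavelet, mode="symmetric")
    return low[:h, :w], high[:h, :w]


def derive_images(
    image: np.ndarray,
    spacing: float,
    wavelet: str = "db2",
    provenance: str = "",
) -> list:
    """Return the 9 derived images for one slice."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if spacing <= 0:
        raise ValueError("spacing must be positive")

    out = [DerivedImage("original", image.copy(), provenance)]
    for sigma_mm in (1.0, 2.0):
        sigma_px = sigma_mm / spacing
        # negated Laplacian-of-Gaussian: bright blobs give positive response
        # wide truncation keeps the discrete kernel's response to a
        # constant image at float-precision zero
        log = -(sigma_px**2) * ndimage.gaussian_laplace(image, sigma_px, truncate=8.0)
        out.append(DerivedImage(f"log-sigma-{sigma_mm:.1f}mm", log, provenance))
    low, high = _wavelet_pair(image, wavelet)
    out.append(DerivedImage("wavelet-L", low, provenance))
    out.append(DerivedImage("wavelet-H", high, provenance))

    nn = _shift_nonneg(image)
    scale = nn.max() if nn.max() > 0 else 1.0
    out.append(DerivedImage("exponential", np.exp(nn / scale), provenance))
    out.append(DerivedImage("logarithm", np.log1p(nn), provenance))
    out.append(DerivedImage("square", image**2, provenance))
    out.append(DerivedImage("square-root", np.sqrt(nn), provenance))
    return out
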