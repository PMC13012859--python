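"""Radiomics feature extraction: the 868-entry feature catalogue.

Per lesion, the catalogue concatenates
8 clinical covariates, 14 morphological (shape) features, 9 histogram
features of the original masked intensities (median first), and — for
each of the 9 derived image types — 18 first-order statistics plus the
24/16/16/14/5 features of the GLCM/GLRLM/GLSZM/GLDM/NGTDM texture
families: 8 + 14 + 9 + 9*(18+24+16+16+14+5) = 868.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from skimage import measure as skmeasure

from .filters import DERIVED_KINDS, DerivedImage, derive_images
from .phantom import CLINICAL_FIELDS, Phantom
from .texture import TEXTURE_FEATURE_NAMES, texture_features, texture_matrices

__all__ = [
    "FeatureConfig",
    "FeatureCatalogue",
    "build_catalogue",
    "clinical_features",
    "histogram_features",
    "shape_features",
    "first_order_features",
    "extract_all",
    "HISTOGRAM_FEATURE_NAMES",
    "SHAPE_FEATURE_NAMES",
    "FIRST_ORDER_FEATURE_NAMES",
]

HISTOGRAM_FEATURE_NAMES = (
    "Median", "Mean", "Mode", "Variance", "Skewness", "Kurtosis",
    "Energy", "Entropy", "InterquartileRange",
)

SHAPE_FEATURE_NAMES = (
    "Volume", "SurfaceArea", "SurfaceVolumeRatio", "Sphericity",
    "EquivalentDiameter", "MaximumDiameter", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
    "Eccentricity", "Extent", "Solidity",
)

FIRST_ORDER_FEATURE_NAMES = (
    "Energy", "Entropy", "Minimum", "10Percentile", "90Percentile",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    "StandardDeviation",
)

_FAMILY_ORDER = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


@dataclass(frozen=True)
class FeatureConfig:
    n_gray_levels: int = 32
    pixel_spacing: float = 0.5
    wavelet: str = "db2"
    include_clinical: bool = True


@dataclass(frozen=True)
class FeatureCatalogue:
    """Ordered feature names with (family, derived-image kind) provenance."""

    entries: tuple  # of (name, family, kind-or-None)

    @property
    def names(self):
        return [e[0] for e in self.entries]

    def __len__(self):
        return len(self.entries)

    def family_counts(self) -> dict:
        counts: dict = {}
        for _, family, _ in self.entries:
            counts[family] = counts.get(family, 0) + 1
        return counts


def build_catalogue(config: FeatureConfig | None = None) -> FeatureCatalogue:
    config = config or FeatureConfig()
    entries = []
    if config.include_clinical:
        for f in CLINICAL_FIELDS:
            entries.append((f"clinical_{f}", "clinical", None))
    for f in SHAPE_FEATURE_NAMES:
        entries.append((f"shape_{f}", "shape", None))
    for f in HISTOGRAM_FEATURE_NAMES:
        entries.append((f"histogram_{f}", "histogram", None))
    for kind in DERIVED_KINDS:
        for f in FIRST_ORDER_FEATURE_NAMES:
            entries.append((f"{kind}_firstorder_{f}", "firstorder", kind))
        for family in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
            for f in TEXTURE_FEATURE_NAMES[family]:
                entries.append((f"{kind}_{family}_{f}", family, kind))
    return FeatureCatalogue(entries=tuple(entries))


# ---------------------------------------------------------------------------
# per-family extractors
# ---------------------------------------------------------------------------

_HPV_CODE = {"negative": 0.0, "positive": 1.0, "unknown": -1.0}
_FIGO_CODE = {"I": 1.0, "II": 2.0, "III-IV": 3.0, "unknown": 0.0}


def clinical_features(record) -> dict:
    """Numeric encoding of the 8 clinical covariates."""
    d = record.as_dict()
    d["hpv_status"] = _HPV_CODE[d["hpv_status"]]
    d["figo_stage"] = _FIGO_CODE[d["figo_stage"]]
    return {f"clinical_{k}": float(v) for k, v in d.items()}


def histogram_features(intensities: np.ndarray, n_bins: int = 32) -> dict:
    """Nine histogram descriptors of the masked intensities, median first."""
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no masked pixels")
    hist, edges = np.histogram(x, bins=n_bins)
    p = hist / hist.sum()
    pe = p[p > 0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    constant = x.max() == x.min()
    return {
        "histogram_Median": float(np.median(x)),
        "histogram_Mean": float(x.mean()),
        "histogram_Mode": float(centers[np.argmax(hist)]),
        "histogram_Variance": float(x.var()),
        "histogram_Skewness": 0.0 if constant else float(sstats.skew(x)),
        "histogram_Kurtosis": 0.0 if constant else float(sstats.kurtosis(x, fisher=False)),
        "histogram_Energy": float((p**2).sum()),
        "histogram_Entropy": 0.0 if constant else float(-(pe * np.log2(pe)).sum()),
        "histogram_InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
    }


def shape_features(mask: np.ndarray, spacing: float) -> dict:
    """Fourteen 2-D morphological descriptors of the lesion mask (mm units).

    2-D analogues of the usual volumetric set: area stands in for volume,
    perimeter (Crofton estimate) for surface area; elongation and flatness
    follow the sqrt-eigenvalue-ratio convention, which for an ellipse
    equals the minor/major axis ratio.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    area = props.area * spacing**2
    perimeter = max(skmeasure.perimeter_crofton(mask, directions=4) * spacing, 1e-12)
    major = props.axis_major_length * spacing
    minor = props.axis_minor_length * spacing
    elong = minor / major if major > 0 else 1.0

    coords = np.argwhere(mask)
    if len(coords) > 500:  # pairwise diameter only needs the convex hull
        from scipy.spatial import ConvexHull

        coords = coords[ConvexHull(coords).vertices]
    from scipy.spatial.distance import pdist

    max_diam = float(pdist(coords).max()) * spacing if len(coords) > 1 else spacing

    return {
        "shape_Volume": float(area),
        "shape_SurfaceArea": float(perimeter),
        "shape_SurfaceVolumeRatio": float(perimeter / area),
        "shape_Sphericity": float(2.0 * np.sqrt(np.pi * area) / perimeter),
        "shape_EquivalentDiameter": float(2.0 * np.sqrt(area / np.pi)),
        "shape_MaximumDiameter": max_diam,
        "shape_MajorAxisLength": float(major),
        "shape_MinorAxisLength": float(minor),
        "shape_LeastAxisLength": float(minor),
        "shape_Elongation": float(elong),
        "shape_Flatness": float(elong),
        "shape_Eccentricity": float(props.eccentricity),
        "shape_Extent": float(props.extent),
        "shape_Solidity": float(props.solidity),
    }


def first_order_features(derived: DerivedImage, mask: np.ndarray,
                         n_bins: int = 32) -> dict:
    """Eighteen intensity statistics of one derived image inside the mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = derived.data[mask].astype(float)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    hist, _ = np.histogram(x, bins=n_bins)
    p = hist / hist.sum()
    pe = p[p > 0]
    constant = x.max() == x.min()
    prefix = f"{derived.kind}_firstorder_"
    return {
        prefix + "Energy": float((x**2).sum()),
        prefix + "Entropy": 0.0 if constant else float(-(pe * np.log2(pe)).sum()),
        prefix + "Minimum": float(x.min()),
        prefix + "10Percentile": float(p10),
        prefix + "90Percentile": float(p90),
        prefix + "Maximum": float(x.max()),
        prefix + "Mean": float(x.mean()),
        prefix + "Median": float(p50),
        prefix + "InterquartileRange": float(p75 - p25),
        prefix + "Range": float(x.max() - x.min()),
        prefix + "MeanAbsoluteDeviation": float(np.abs(x - x.mean()).mean()),
        prefix + "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        prefix + "RootMeanSquared": float(np.sqrt((x**2).mean())),
        prefix + "Skewness": 0.0 if constant else float(sstats.skew(x)),
        prefix + "Kurtosis": 0.0 if constant else float(sstats.kurtosis(x, fisher=False)),
        prefix + "Variance": float(x.var()),
        prefix + "Uniformity": float((p**2).sum()),
        prefix + "StandardDeviation": float(x.std()),
    }


def extract_all(phantom: Phantom, config: FeatureConfig | None = None) -> dict:
    """Full feature vector for one phantom, ordered by the catalogue."""
    config = config or FeatureConfig()
    catalogue = build_catalogue(config)
    mask = phantom.mask.astype(bool)
    n_pixels = int(mask.sum())

    values: dict = {}
    if config.include_clinical:
        values.update(clinical_features(phantom.clinical))
    values.update(shape_features(mask, config.pixel_spacing))
    values.update(histogram_features(phantom.image[mask], config.n_gray_levels))
    for derived in derive_images(phantom.image, config.pixel_spacing, config.wavelet):
        try:
            values.update(first_order_features(derived, mask, config.n_gray_levels))
            mats = texture_matrices(derived.data, mask, config.n_gray_levels)
            for family, feats in texture_features(mats, n_pixels).items():
                for name, v in feats.items():
                    values[f"{derived.kind}_{family}_{name}"] = float(v)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"feature extraction failed on {derived.kind}: {exc}") from exc

    ordered = {name: values[name] for name in catalogue.names}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad[:5]}")
    return ordered
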