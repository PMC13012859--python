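"""Synthetic MRI-like phantoms with quasi-elliptical lesions.

Every downstream stage of the package (segmentation, radiomics, feature
selection, pathological typing) is exercised on phantoms produced here: a
single-channel slice containing one simply-connected lesion of clinically
plausible size (1-4 cm equivalent diameter at the configured pixel
spacing), a matching binary mask, a small clinical record and a 3-bit
pathology label.

Lesions are random ellipses deformed by low-frequency radial noise.  The
lesion interior receives a subtype-dependent mean shift and spatially
correlated texture (Gaussian-smoothed white noise at a subtype-specific
correlation length), so that intensity and texture statistics carry the
pathology label and the selection/classification stages have real signal
to recover.  Clinical covariates are drawn independently of the image by
default; an optional coupling can tie invasion depth to lesion size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "PathologyLabel",
    "ClinicalRecord",
    "SubtypeEffect",
    "PhantomConfig",
    "Phantom",
    "generate_phantom",
    "generate_cohort",
    "scaled_phantom_config",
    "equivalent_diameter_mm",
    "CATEGORY_NAMES",
]

#: Table of category names keyed by the 3-bit encoding
#: category = 4*cell_size + 2*keratinization + histology.
CATEGORY_NAMES = {
    0: "Small-cell keratinizing squamous cell carcinoma",
    1: "Small-cell keratinizing adenocarcinoma",
    2: "Small-cell non-keratinizing squamous cell carcinoma",
    3: "Small-cell non-keratinizing adenocarcinoma",
    4: "Large-cell keratinizing squamous cell carcinoma",
    5: "Large-cell keratinizing adenocarcinoma",
    6: "Large-cell non-keratinizing squamous cell carcinoma",
    7: "Large-cell non-keratinizing adenocarcinoma",
}

CLINICAL_FIELDS = (
    "age",
    "hpv_status",
    "figo_stage",
    "lymph_node_metastasis",
    "lymphovascular_invasion",
    "invasion_depth",
    "chemotherapy",
    "radiotherapy",
)


@dataclass(frozen=True)
class PathologyLabel:
    """3-bit pathological type: cell size / keratinization / histology."""

    cell_size: int  # 0 = small, 1 = large
    keratinization: int  # 0 = keratinizing, 1 = non-keratinizing
    histology: int  # 0 = squamous, 1 = adenocarcinoma

    def __post_init__(self) -> None:
        for name in ("cell_size", "keratinization", "histology"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be binary, got {v!r}")

    @property
    def category(self) -> int:
        return 4 * self.cell_size + 2 * self.keratinization + self.histology

    @property
    def name(self) -> str:
        return CATEGORY_NAMES[self.category]

    @classmethod
    def from_category(cls, category: int) -> "PathologyLabel":
        if not 0 <= int(category) <= 7:
            raise ValueError(f"category must be in 0-7, got {category}")
        c = int(category)
        return cls(cell_size=(c >> 2) & 1, keratinization=(c >> 1) & 1, histology=c & 1)


@dataclass(frozen=True)
class ClinicalRecord:
    """Eight clinical covariates recorded per subject."""

    age: float
    hpv_status: str  # positive / negative / unknown
    figo_stage: str  # I / II / III-IV / unknown
    lymph_node_metastasis: int
    lymphovascular_invasion: int
    invasion_depth: float  # cm, in [0, 2]
    chemotherapy: int
    radiotherapy: int

    def __post_init__(self) -> None:
        if self.hpv_status not in ("positive", "negative", "unknown"):
            raise ValueError(f"bad hpv_status {self.hpv_status!r}")
        if self.figo_stage not in ("I", "II", "III-IV", "unknown"):
            raise ValueError(f"bad figo_stage {self.figo_stage!r}")
        if not 0.0 <= self.invasion_depth <= 2.0:
            raise ValueError("invasion_depth must lie in [0, 2] cm")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in CLINICAL_FIELDS}


@dataclass(frozen=True)
class SubtypeEffect:
    """Image-level signature of one pathological subtype.

    mean_shift
        additive intensity offset inside the lesion, in units of the
        background noise scale.
    correlation_length_px
        Gaussian smoothing sigma of the lesion texture field; larger values
        give coarser, more 'zonal' texture (drives GLSZM/GLRLM contrasts).
    low_gray_fraction
        fraction of lesion pixels pulled toward low intensities, emulating
        hypo-intense (e.g. necrotic/keratin pearl) subregions.
    """

    mean_shift: float
    correlation_length_px: float
    low_gray_fraction: float


def _default_subtype_effects() -> dict:
    # Effect sizes spread the 8 categories along three texture axes:
    # cell size -> correlation length, keratinization -> low-gray zones,
    # histology -> mean shift.  Values are free parameters of the phantom
    # model, chosen to give a strong but not degenerate class signal.
    effects = {}
    for cat in range(8):
        lab = PathologyLabel.from_category(cat)
        effects[cat] = SubtypeEffect(
            mean_shift=1.5 + 2.0 * lab.histology + 0.5 * lab.cell_size,
            correlation_length_px=1.0 + 2.5 * lab.cell_size,
            low_gray_fraction=0.05 + 0.25 * (1 - lab.keratinization),
        )
    return effects


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 256
    pixel_spacing: float = 0.5  # mm / pixel
    lesion_diameter_range: tuple = (10.0, 40.0)  # mm
    noise_sd: float = 0.2
    subtype_effects: dict = field(default_factory=_default_subtype_effects)
    couple_clinical_to_size: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_diameter_range must be positive and ordered")
        if hi >= self.image_size * self.pixel_spacing:
            raise ValueError("lesion cannot fit in the image at this spacing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")


def strong_subtype_effects() -> dict:
    """Subtype effects with amplified contrasts between the 8 categories.

    Used for recovery studies where the phantom classes must be clearly
    separable in texture/intensity space; the default effects are milder.
    """
    effects = {}
    for cat in range(8):
        lab = PathologyLabel.from_category(cat)
        effects[cat] = SubtypeEffect(
            mean_shift=1.5 + 3.0 * lab.histology + 1.0 * lab.cell_size
            + 1.0 * lab.keratinization,
            correlation_length_px=1.0 + 3.5 * lab.cell_size,
            low_gray_fraction=0.05 + 0.45 * (1 - lab.keratinization),
        )
    return effects


def scaled_phantom_config(image_size: int, seed: int = 0, noise_sd: float = 0.2,
                          **kwargs) -> "PhantomConfig":
    """Phantom configuration for a scaled-down field of view.

    Full-scale slices are 256 px at 0.5 mm; smaller studies use 1 mm
    pixels, and the lesion-diameter interval keeps its 10 mm floor but is
    capped so the largest lesion still fits the field of view.
    """
    if image_size >= 256:
        return PhantomConfig(image_size=image_size, seed=seed,
                             noise_sd=noise_sd, **kwargs)
    spacing = 1.0
    cap = min(40.0, 0.42 * image_size * spacing)
    return PhantomConfig(
        image_size=image_size, pixel_spacing=spacing,
        lesion_diameter_range=(10.0, cap), noise_sd=noise_sd, seed=seed,
        **kwargs,
    )


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray
    mask: np.ndarray
    clinical: ClinicalRecord
    label: PathologyLabel


def equivalent_diameter_mm(mask: np.ndarray, pixel_spacing: float) -> float:
    """Diameter (mm) of the disk with the same area as the mask."""
    area = float(np.count_nonzero(mask)) * pixel_spacing**2
    return 2.0 * math.sqrt(area / math.pi)


def _lesion_mask(rng: np.random.Generator, config: PhantomConfig) -> np.ndarray:
    """Rasterize one quasi-elliptical lesion whose equivalent diameter lies
    inside the configured range.  Rejection-samples the radial deformation
    until the diameter constraint and single-component constraint hold."""
    n = config.image_size
    lo, hi = config.lesion_diameter_range
    for _ in range(200):
        target_d = rng.uniform(lo, hi)  # mm
        r_mean = target_d / 2.0 / config.pixel_spacing  # px
        ecc = rng.uniform(0.6, 1.0)  # minor/major ratio
        a, b = r_mean / math.sqrt(ecc), r_mean * math.sqrt(ecc)
        theta0 = rng.uniform(0, math.pi)
        margin = a * 1.45 + 2
        if margin >= n - margin:  # this draw cannot fit; try another
            continue
        cy = rng.uniform(margin, n - margin)
        cx = rng.uniform(margin, n - margin)

        # low-frequency radial deformation: 3 random harmonics, <=18% amplitude
        k = np.array([2, 3, 4])
        amp = rng.uniform(0, 0.06, size=3)
        phase = rng.uniform(0, 2 * math.pi, size=3)

        yy, xx = np.mgrid[0:n, 0:n]
        dy, dx = yy - cy, xx - cx
        ct, st = math.cos(theta0), math.sin(theta0)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        phi = np.arctan2(v / b, u / a)
        deform = 1.0 + sum(
            amp[i] * np.cos(k[i] * phi + phase[i]) for i in range(3)
        )
        mask = ((u / a) ** 2 + (v / b) ** 2) <= deform**2

        d = equivalent_diameter_mm(mask, config.pixel_spacing)
        if not (lo <= d <= hi):
            continue
        labelled, ncomp = ndimage.label(mask, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        if ncomp != 1:
            continue
        return mask.astype(np.uint8)
    raise RuntimeError("failed to draw a lesion satisfying the size constraint")


def _clinical_record(
    rng: np.random.Generator, config: PhantomConfig, lesion_d_mm: float
) -> ClinicalRecord:
    # Marginals loosely follow a gynecologic-oncology cohort; independent of
    # the image unless coupling is enabled.
    hpv = rng.choice(["positive", "negative", "unknown"], p=[0.68, 0.08, 0.24])
    figo = rng.choice(["I", "II", "III-IV", "unknown"], p=[0.42, 0.45, 0.10, 0.03])
    if config.couple_clinical_to_size:
        depth = float(np.clip(lesion_d_mm / 40.0 + rng.normal(0, 0.1), 0.0, 2.0))
    else:
        depth = float(np.clip(rng.normal(0.54, 0.28), 0.0, 2.0))
    return ClinicalRecord(
        age=float(np.clip(rng.normal(51.0, 9.0), 28, 80)),
        hpv_status=str(hpv),
        figo_stage=str(figo),
        lymph_node_metastasis=int(rng.random() < 0.17),
        lymphovascular_invasion=int(rng.random() < 0.11),
        invasion_depth=depth,
        chemotherapy=int(rng.random() < 0.77),
        radiotherapy=int(rng.random() < 0.51),
    )


def generate_phantom(config: PhantomConfig, label: PathologyLabel) -> Phantom:
    """Generate one slice/mask/record triple for the given pathology label.

    Deterministic given ``config.seed`` (and label).  The background is
    baseline + white Gaussian noise; the lesion adds the subtype's mean
    shift plus correlated texture and an optional low-gray zone field.
    """
    if label.category not in config.subtype_effects:
        raise ValueError(f"no subtype effect configured for category {label.category}")
    rng = np.random.default_rng([config.seed, label.category])
    n = config.image_size
    effect: SubtypeEffect = config.subtype_effects[label.category]

    mask = _lesion_mask(rng, config)
    image = rng.normal(0.0, config.noise_sd or 0.0, size=(n, n)) if config.noise_sd > 0 else np.zeros((n, n))

    # correlated texture field inside the lesion
    texture = rng.normal(0.0, 1.0, size=(n, n))
    texture = ndimage.gaussian_filter(texture, effect.correlation_length_px)
    texture *= 0.25 / max(texture[mask > 0].std(), 1e-9) if config.noise_sd > 0 else 0.0

    # hypo-intense zones: threshold a second smoothed field
    zones = ndimage.gaussian_filter(rng.normal(size=(n, n)), 3.0)
    thr = np.quantile(zones[mask > 0], effect.low_gray_fraction)
    low = (zones < thr) & (mask > 0)

    lesion_signal = effect.mean_shift * (config.noise_sd if config.noise_sd > 0 else 1.0)
    image = image + mask * (lesion_signal + texture)
    image[low] -= 0.8 * lesion_signal

    d_mm = equivalent_diameter_mm(mask, config.pixel_spacing)
    clinical = _clinical_record(rng, config, d_mm)
    return Phantom(image=image.astype(np.float64), mask=mask, clinical=clinical, label=label)


def generate_cohort(
    config: PhantomConfig,
    n: int,
    class_probabilities=None,
) -> list:
    """Draw ``n`` phantoms with labels sampled from ``class_probabilities``
    (a length-8 simplex vector over categories; uniform by default).
    Zero-probability classes are supported, emulating cohorts in which some
    pathological categories are absent."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if class_probabilities is None:
        p = np.full(8, 1.0 / 8.0)
    else:
        p = np.asarray(class_probabilities, dtype=float)
    if p.shape != (8,):
        raise ValueError("class_probabilities must have length 8")
    if np.any(p < 0):
        raise ValueError("class probabilities must be non-negative")
    if not math.isclose(p.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("class probabilities must sum to 1")

    rng = np.random.default_rng([config.seed, 0xC0])
    categories = rng.choice(8, size=n, p=p)
    cohort = []
    for i, cat in enumerate(categories):
        sub = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        cohort.append(generate_phantom(sub, PathologyLabel.from_category(int(cat))))
    return cohort
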