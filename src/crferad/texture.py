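"""Gray-level texture matrices and their named features.

All five classical families are computed from scratch on the masked,
quantized slice: co-occurrence (GLCM), run length (GLRLM), size zone
(GLSZM), dependence (GLDM) and neighborhood gray-tone difference (NGTDM).
Conventions: masked intensities are quantized into a fixed number of
equal-width bins (levels 1..n); the GLCM uses distance 1, is symmetrized
and averaged over the four 2-D directions; the GLRLM sums runs over the
same four directions; GLSZM zones are 8-connected; GLDM uses distance 1
with similarity tolerance alpha = 0 and dependence size = dependent
neighbors + 1; NGTDM uses the distance-1 (8-pixel) neighborhood mean.

Degenerate inputs (a single occupied gray level) yield defined finite
values: entropies are 0 and correlation-type features are 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TextureMatrixSet",
    "quantize",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_matrix",
    "texture_matrices",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "texture_features",
    "TEXTURE_FEATURE_NAMES",
]

_EPS = np.spacing(1.0)

# direction offsets (dr, dc): 0, 45, 90, 135 degrees
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_EIGHT = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


def quantize(image: np.ndarray, mask: np.ndarray, n_gray_levels: int = 32) -> np.ndarray:
    """Quantize masked intensities into equal-width bins, levels 1..n.

    Pixels outside the mask are set to 0.  A constant region maps to a
    single occupied level (1).
    """
    if n_gray_levels < 2:
        raise ValueError("n_gray_levels must be >= 2")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    image = np.asarray(image, dtype=float)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(image.shape, dtype=np.int64)
    if hi == lo:
        q[mask] = 1
        return q
    edges = np.linspace(lo, hi, n_gray_levels + 1)
    q[mask] = np.clip(np.digitize(image[mask], edges[1:-1]) + 1, 1, n_gray_levels)
    return q


@dataclass(frozen=True)
class TextureMatrixSet:
    glcm: np.ndarray  # (Ng, Ng), symmetric, direction-averaged counts
    glrlm: np.ndarray  # (Ng, Nr), summed over directions
    glszm: np.ndarray  # (Ng, Ns)
    gldm: np.ndarray  # (Ng, Nd)
    ngtdm_s: np.ndarray  # per-level summed gray-tone differences
    ngtdm_n: np.ndarray  # per-level pixel counts
    n_gray_levels: int


def glcm_matrix(quantized: np.ndarray, mask: np.ndarray, n_levels: int,
                directions=_DIRECTIONS) -> np.ndarray:
    """Symmetrized co-occurrence counts averaged over the directions."""
    mask = np.asarray(mask).astype(bool)
    acc = np.zeros((n_levels, n_levels))
    h, w = quantized.shape
    for dr, dc in directions:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = quantized[r0:r1, c0:c1]
        b = quantized[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        m = np.zeros((n_levels, n_levels))
        np.add.at(m, (a[valid] - 1, b[valid] - 1), 1.0)
        acc += m + m.T  # symmetrize
    return acc / len(directions)


def _lines(quantized, mask, dr, dc):
    """Yield (levels, inmask) 1-D arrays for every scan line in direction."""
    h, w = quantized.shape
    if (dr, dc) == (0, 1):
        for r in range(h):
            yield quantized[r], mask[r]
    elif (dr, dc) == (-1, 0) or (dr, dc) == (1, 0):
        for c in range(w):
            yield quantized[:, c], mask[:, c]
    elif (dr, dc) in ((-1, 1), (1, -1)):  # anti-diagonals
        fq, fm = quantized[::-1], mask[::-1]
        for o in range(-(h - 1), w):
            yield fq.diagonal(o), fm.diagonal(o)
    else:  # main diagonals
        for o in range(-(h - 1), w):
            yield quantized.diagonal(o), mask.diagonal(o)


def glrlm_matrix(quantized: np.ndarray, mask: np.ndarray, n_levels: int,
                 directions=_DIRECTIONS) -> np.ndarray:
    """Run-length counts summed over the four directions.

    A run is a maximal collinear segment of equal gray level entirely
    inside the mask; runs partition each masked scan line.
    """
    mask = np.asarray(mask).astype(bool)
    max_run = max(quantized.shape)
    acc = np.zeros((n_levels, max_run))
    for dr, dc in directions:
        for levels, inmask in _lines(quantized, mask, dr, dc):
            run_level, run_len = 0, 0
            for lev, ok in zip(levels, inmask):
                lev = lev if ok else 0
                if lev == run_level:
                    run_len += 1
                else:
                    if run_level > 0:
                        acc[run_level - 1, run_len - 1] += 1
                    run_level, run_len = lev, 1
            if run_level > 0:
                acc[run_level - 1, run_len - 1] += 1
    # trim trailing all-zero run-length columns (keep at least one)
    nz = np.nonzero(acc.sum(axis=0))[0]
    return acc[:, : (nz[-1] + 1 if nz.size else 1)]


def glszm_matrix(quantized: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts: 8-connected components of constant gray level."""
    mask = np.asarray(mask).astype(bool)
    structure = np.ones((3, 3))
    zones = []  # (level, size)
    for lev in range(1, n_levels + 1):
        lab, ncomp = ndimage.label((quantized == lev) & mask, structure=structure)
        if ncomp:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((lev, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    acc = np.zeros((n_levels, max_size))
    for lev, s in zones:
        acc[lev - 1, s - 1] += 1
    return acc


def gldm_matrix(quantized: np.ndarray, mask: np.ndarray, n_levels: int,
                alpha: int = 0) -> np.ndarray:
    """Dependence counts: for each masked pixel, the number of 8-neighbors
    (inside the mask) whose level differs by at most ``alpha``; dependence
    size = that count + 1 (so sizes start at 1)."""
    mask = np.asarray(mask).astype(bool)
    h, w = quantized.shape
    dep = np.zeros((h, w), dtype=np.int64)
    for dr, dc in _EIGHT:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        nb_ok = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        close = np.abs(quantized[r0:r1, c0:c1]
                       - quantized[r0 + dr:r1 + dr, c0 + dc:c1 + dc]) <= alpha
        dep[r0:r1, c0:c1] += (nb_ok & close).astype(np.int64)
    sizes = dep[mask] + 1
    levels = quantized[mask]
    acc = np.zeros((n_levels, int(sizes.max())))
    np.add.at(acc, (levels - 1, sizes - 1), 1.0)
    return acc


def ngtdm_matrix(quantized: np.ndarray, mask: np.ndarray, n_levels: int):
    """Neighborhood gray-tone differences.

    Returns (s, n): per-level summed absolute differences from the mean of
    the masked 8-neighborhood, and per-level pixel counts (over pixels with
    at least one masked neighbor).
    """
    mask = np.asarray(mask).astype(bool)
    h, w = quantized.shape
    nb_sum = np.zeros((h, w))
    nb_cnt = np.zeros((h, w))
    for dr, dc in _EIGHT:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        nb_ok = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        nb_sum[r0:r1, c0:c1] += np.where(nb_ok, quantized[r0 + dr:r1 + dr, c0 + dc:c1 + dc], 0)
        nb_cnt[r0:r1, c0:c1] += nb_ok
    valid = mask & (nb_cnt > 0)
    diffs = np.zeros((h, w))
    diffs[valid] = np.abs(quantized[valid] - nb_sum[valid] / nb_cnt[valid])
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    np.add.at(s, quantized[valid] - 1, diffs[valid])
    np.add.at(n, quantized[valid] - 1, 1.0)
    return s, n


def texture_matrices(image: np.ndarray, mask: np.ndarray,
                     n_gray_levels: int = 32) -> TextureMatrixSet:
    """Quantize and compute all five matrix families for one slice."""
    mask = np.asarray(mask).astype(bool)
    if np.count_nonzero(mask) < 1:
        raise ValueError("mask must contain at least one pixel")
    q = quantize(image, mask, n_gray_levels)
    s, n = ngtdm_matrix(q, mask, n_gray_levels)
    return TextureMatrixSet(
        glcm=glcm_matrix(q, mask, n_gray_levels),
        glrlm=glrlm_matrix(q, mask, n_gray_levels),
        glszm=glszm_matrix(q, mask, n_gray_levels),
        gldm=gldm_matrix(q, mask, n_gray_levels),
        ngtdm_s=s,
        ngtdm_n=n,
        n_gray_levels=n_gray_levels,
    )


# ---------------------------------------------------------------------------
# feature formulas
# ---------------------------------------------------------------------------


def glcm_features(counts: np.ndarray) -> dict:
    ng = counts.shape[0]
    total = counts.sum()
    p = counts / total if total > 0 else counts
    i = np.arange(1, ng + 1)[:, None] * np.ones((1, ng))
    j = np.ones((ng, 1)) * np.arange(1, ng + 1)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = (np.arange(1, ng + 1) * px).sum()
    uy = (np.arange(1, ng + 1) * py).sum()
    sx = np.sqrt(((np.arange(1, ng + 1) - ux) ** 2 * px).sum())
    sy = np.sqrt(((np.arange(1, ng + 1) - uy) ** 2 * py).sum())

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(i + j) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(i - j) == k].sum() for k in k_diff])

    def ent(v):
        v = v[v > 0]
        return float(-(v * np.log2(v)).sum())

    hx, hy, hxy = ent(px), ent(py), ent(p.ravel())
    outer = px[:, None] * py[None, :]
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log2(outer[nz])).sum())
    onz = outer > 0
    hxy2 = float(-(outer[onz] * np.log2(outer[onz])).sum())

    corr = 0.0
    if sx > _EPS and sy > _EPS:
        corr = float(((i * j * p).sum() - ux * uy) / (sx * sy))

    imc1 = 0.0 if max(hx, hy) <= _EPS else (hxy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # maximal correlation coefficient: second-largest eigenvalue of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    mcc = 1.0
    occupied = (px > 0).sum()
    if occupied > 1:
        a = p / np.where(px[:, None] > 0, px[:, None], 1.0)
        b = p / np.where(py[None, :] > 0, py[None, :], 1.0)
        q_mat = a @ b.T
        ev = np.sort(np.abs(np.linalg.eigvals(q_mat)))
        mcc = float(np.sqrt(max(0.0, ev[-2].real)))

    da = float((k_diff * p_diff).sum())
    feats = {
        "Autocorrelation": float((i * j * p).sum()),
        "JointAverage": float((i * p).sum()),
        "ClusterProminence": float((((i + j) - ux - uy) ** 4 * p).sum()),
        "ClusterShade": float((((i + j) - ux - uy) ** 3 * p).sum()),
        "ClusterTendency": float((((i + j) - ux - uy) ** 2 * p).sum()),
        "Contrast": float(((i - j) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(i - j))).sum()),
        "Idm": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (i - j) ** 2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(i - j) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p[i != j] / (i - j)[i != j] ** 2).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "MCC": mcc,
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((i - ux) ** 2 * p).sum()),
    }
    return feats


def _run_zone_family(counts: np.ndarray, n_pixels: int, prefix_small: str,
                     prefix_large: str, axis_name: str) -> dict:
    """Shared formulas of the GLRLM/GLSZM families.

    ``counts``: (Ng, Nsize) matrix; size index j weights runs/zones.
    """
    nz = counts.sum()
    ng, ns = counts.shape
    iv = np.arange(1, ng + 1)[:, None]
    jv = np.arange(1, ns + 1)[None, :]
    p = counts / nz if nz > 0 else counts
    mu_i = float((iv * p).sum())
    mu_j = float((jv * p).sum())
    pe = p[p > 0]
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    return {
        prefix_small: float((counts / jv**2).sum() / nz),
        prefix_large: float((counts * jv**2).sum() / nz),
        "GrayLevelNonUniformity": float((row**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((row**2).sum() / nz**2),
        f"{axis_name}NonUniformity": float((col**2).sum() / nz),
        f"{axis_name}NonUniformityNormalized": float((col**2).sum() / nz**2),
        f"{axis_name[0]}P" if axis_name == "RunLength" else "ZonePercentage":
            float(nz / n_pixels),
        "GrayLevelVariance": float(((iv - mu_i) ** 2 * p).sum()),
        f"{'Run' if axis_name == 'RunLength' else 'Zone'}Variance":
            float(((jv - mu_j) ** 2 * p).sum()),
        f"{'Run' if axis_name == 'RunLength' else 'Zone'}Entropy":
            float(-(pe * np.log2(pe)).sum()),
        "LowGrayLevelEmphasis": float((counts / iv**2).sum() / nz),
        "HighGrayLevelEmphasis": float((counts * iv**2).sum() / nz),
    }


def glrlm_features(counts: np.ndarray, n_pixels: int) -> dict:
    base = _run_zone_family(counts, n_pixels, "ShortRunEmphasis",
                            "LongRunEmphasis", "RunLength")
    base["RunPercentage"] = base.pop("RP")
    nz = counts.sum()
    ng, ns = counts.shape
    iv = np.arange(1, ng + 1)[:, None]
    jv = np.arange(1, ns + 1)[None, :]
    base["LowGrayLevelRunEmphasis"] = base.pop("LowGrayLevelEmphasis")
    base["HighGrayLevelRunEmphasis"] = base.pop("HighGrayLevelEmphasis")
    base["ShortRunLowGrayLevelEmphasis"] = float((counts / (iv**2 * jv**2)).sum() / nz)
    base["ShortRunHighGrayLevelEmphasis"] = float((counts * iv**2 / jv**2).sum() / nz)
    base["LongRunLowGrayLevelEmphasis"] = float((counts * jv**2 / iv**2).sum() / nz)
    base["LongRunHighGrayLevelEmphasis"] = float((counts * iv**2 * jv**2).sum() / nz)
    return base


def glszm_features(counts: np.ndarray, n_pixels: int) -> dict:
    base = _run_zone_family(counts, n_pixels, "SmallAreaEmphasis",
                            "LargeAreaEmphasis", "SizeZone")
    nz = counts.sum()
    ng, ns = counts.shape
    iv = np.arange(1, ng + 1)[:, None]
    jv = np.arange(1, ns + 1)[None, :]
    base["LowGrayLevelZoneEmphasis"] = base.pop("LowGrayLevelEmphasis")
    base["HighGrayLevelZoneEmphasis"] = base.pop("HighGrayLevelEmphasis")
    base["SmallAreaLowGrayLevelEmphasis"] = float((counts / (iv**2 * jv**2)).sum() / nz)
    base["SmallAreaHighGrayLevelEmphasis"] = float((counts * iv**2 / jv**2).sum() / nz)
    base["LargeAreaLowGrayLevelEmphasis"] = float((counts * jv**2 / iv**2).sum() / nz)
    base["LargeAreaHighGrayLevelEmphasis"] = float((counts * iv**2 * jv**2).sum() / nz)
    return base


def gldm_features(counts: np.ndarray) -> dict:
    nz = counts.sum()
    ng, nd = counts.shape
    iv = np.arange(1, ng + 1)[:, None]
    jv = np.arange(1, nd + 1)[None, :]
    p = counts / nz if nz > 0 else counts
    mu_i = float((iv * p).sum())
    mu_j = float((jv * p).sum())
    pe = p[p > 0]
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    return {
        "SmallDependenceEmphasis": float((counts / jv**2).sum() / nz),
        "LargeDependenceEmphasis": float((counts * jv**2).sum() / nz),
        "GrayLevelNonUniformity": float((row**2).sum() / nz),
        "DependenceNonUniformity": float((col**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((col**2).sum() / nz**2),
        "GrayLevelVariance": float(((iv - mu_i) ** 2 * p).sum()),
        "DependenceVariance": float(((jv - mu_j) ** 2 * p).sum()),
        "DependenceEntropy": float(-(pe * np.log2(pe)).sum()),
        "LowGrayLevelEmphasis": float((counts / iv**2).sum() / nz),
        "HighGrayLevelEmphasis": float((counts * iv**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((counts / (iv**2 * jv**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((counts * iv**2 / jv**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((counts * jv**2 / iv**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((counts * iv**2 * jv**2).sum() / nz),
    }


def ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict:
    n_total = n.sum()
    p = n / n_total if n_total > 0 else n
    ivals = np.arange(1, len(n) + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ip = ivals[present]
    pp = p[present]
    sp = s[present]

    coarseness = float(1.0 / (p * s).sum()) if (p * s).sum() > 0 else 1e6

    contrast = 0.0
    if ngp > 1:
        pair = (pp[:, None] * pp[None, :] * (ip[:, None] - ip[None, :]) ** 2).sum()
        contrast = float(pair / (ngp * (ngp - 1)) * s.sum() / n_total)

    busy_den = np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum()
    busyness = float((pp * sp).sum() / busy_den) if busy_den > 0 else 0.0

    complexity = 0.0
    strength = 0.0
    if ngp > 0:
        psum = pp[:, None] + pp[None, :]
        num_c = (np.abs(ip[:, None] - ip[None, :])
                 * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / psum).sum()
        complexity = float(num_c / n_total)
        if s.sum() > 0:
            strength = float((psum * (ip[:, None] - ip[None, :]) ** 2).sum() / s.sum())

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


TEXTURE_FEATURE_NAMES = {
    "glcm": tuple(glcm_features(np.ones((2, 2))).keys()),
    "glrlm": tuple(glrlm_features(np.ones((2, 2)), 4).keys()),
    "glszm": tuple(glszm_features(np.ones((2, 2)), 4).keys()),
    "gldm": tuple(gldm_features(np.ones((2, 2))).keys()),
    "ngtdm": tuple(ngtdm_features(np.ones(2), np.ones(2)).keys()),
}


def texture_features(matrices: TextureMatrixSet, n_pixels: int) -> dict:
    """All named features of the five families, keyed family -> {name: value}."""
    return {
        "glcm": glcm_features(matrices.glcm),
        "glrlm": glrlm_features(matrices.glrlm, n_pixels),
        "glszm": glszm_features(matrices.glszm, n_pixels),
        "gldm": gldm_features(matrices.gldm),
        "ngtdm": ngtdm_features(matrices.ngtdm_s, matrices.ngtdm_n),
    }
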