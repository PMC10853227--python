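"""Compact IBSI-style radiomics features on discretized parametric images.

Implements the subset the pipeline needs end-to-end: first-order and
intensity-histogram statistics, grey-level co-occurrence (GLCM) features —
including Information Correlation 2 and Cluster Prominence — basic
morphology, and the local intensity peak. Feature tables are the pipeline
contract, so any external extractor can substitute a richer catalogue.

Discretization uses a fixed bin width anchored at the in-mask minimum
(0.1 for TBR images, 1 min for TTP images), which makes every
discretized-domain feature invariant to adding a constant to the image.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .imaging import ParametricImage

__all__ = [
    "discretize",
    "glcm_matrix",
    "glcm_features",
    "first_order_features",
    "morphology_features",
    "local_intensity_peak",
    "extract_features",
    "radiomics_vector",
    "TBR_BIN_WIDTH",
    "TTP_BIN_WIDTH",
]

TBR_BIN_WIDTH = 0.1
TTP_BIN_WIDTH = 1.0

#: the 13 unique 3D direction pairs at Chebyshev distance 1
GLCM_DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width grey levels, anchored at the minimum (levels start at 1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty region")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    return np.floor((values - values.min()) / bin_width).astype(np.int64) + 1


def _level_image(image: np.ndarray, mask: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    levels = np.zeros(mask.shape, dtype=np.int64)
    levels[mask] = discretize(image[mask], bin_width)
    return levels, int(levels.max())


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, direction,
                n_levels: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one direction.

    Returns the all-zero matrix if the direction yields no in-mask pairs.
    """
    d = np.asarray(direction, int)
    src = [slice(max(0, -o), levels.shape[a] - max(0, o)) for a, o in enumerate(d)]
    dst = [slice(max(0, o), levels.shape[a] - max(0, -o)) for a, o in enumerate(d)]
    a = levels[tuple(src)]
    b = levels[tuple(dst)]
    valid = mask[tuple(src)] & mask[tuple(dst)]
    i, j = a[valid] - 1, b[valid] - 1
    mat = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(mat, (i, j), 1.0)
    mat = mat + mat.T
    total = mat.sum()
    return mat / total if total > 0 else mat


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sd_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    nz = p > 0

    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float((((ii - mu_x) * (jj - mu_y) * p).sum()) / (sd_x * sd_y))
    else:
        correlation = 0.0  # degenerate: a single grey level
    joint_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    joint_energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    autocorrelation = float((ii * jj * p).sum())

    # information measures of correlation (natural log internally)
    hxy = float(-(p[nz] * np.log(p[nz])).sum())
    pxy = np.outer(px, py)
    nz2 = pxy > 0
    hxy1 = float(-(p[nz2] * np.log(pxy[nz2])).sum())
    hxy2 = float(-(pxy[nz2] * np.log(pxy[nz2])).sum())
    hx = float(-(px[px > 0] * np.log(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log(py[py > 0])).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, 1.0)))

    cdev = ii + jj - mu_x - mu_y
    cluster_shade = float((cdev**3 * p).sum())
    cluster_prominence = float((cdev**4 * p).sum())
    cluster_tendency = float((cdev**2 * p).sum())
    return {
        "Contrast": contrast,
        "Correlation": correlation,
        "JointEntropy": joint_entropy,
        "JointEnergy": joint_energy,
        "Homogeneity": homogeneity,
        "Autocorrelation": autocorrelation,
        "Imc1": imc1,
        "InformationCorrelation2": imc2,
        "ClusterShade": cluster_shade,
        "ClusterProminence": cluster_prominence,
        "ClusterTendency": cluster_tendency,
    }


def glcm_features(image: np.ndarray, mask: np.ndarray, bin_width: float) -> dict[str, float]:
    """GLCM features averaged over the 13 distance-1 directions (IBSI 'averaged').

    A single-level region is degenerate: all dispersion-type features are 0.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("GLCM needs at least two in-mask voxels")
    levels, n_levels = _level_image(image, mask, bin_width)
    per_direction = []
    for d in GLCM_DIRECTIONS:
        p = glcm_matrix(levels, mask, d, n_levels)
        if p.sum() > 0:
            per_direction.append(_glcm_features_single(p))
    if not per_direction:
        raise ValueError("no co-occurring voxel pairs in any direction")
    keys = per_direction[0].keys()
    return {f"glcm_{k}": float(np.mean([f[k] for f in per_direction])) for k in keys}


def first_order_features(image: np.ndarray, mask: np.ndarray,
                         bin_width: float) -> dict[str, float]:
    """First-order statistics plus the intensity-histogram entropy.

    Regions with fewer than 3 voxels have undefined higher moments, which
    are reported as NaN.
    """
    vals = np.asarray(image, dtype=float)[np.asarray(mask, bool)]
    if vals.size == 0:
        raise ValueError("mask is empty")
    levels = discretize(vals, bin_width)
    counts = np.bincount(levels)[1:]
    freq = counts[counts > 0] / vals.size
    out = {
        "firstorder_Mean": float(vals.mean()),
        "firstorder_Minimum": float(vals.min()),
        "firstorder_Maximum": float(vals.max()),
        "firstorder_Range": float(vals.max() - vals.min()),
        "firstorder_Energy": float((vals**2).sum()),
        "firstorder_Entropy": float(-(freq * np.log2(freq)).sum()),
    }
    if vals.size >= 2:
        out["firstorder_StdDev"] = float(vals.std(ddof=1))
    else:
        out["firstorder_StdDev"] = float("nan")
    if vals.size >= 3 and vals.std() > 0:
        out["firstorder_Skewness"] = float(stats.skew(vals))
        out["firstorder_Kurtosis"] = float(stats.kurtosis(vals))
    elif vals.std() == 0:
        out["firstorder_Skewness"] = 0.0
        out["firstorder_Kurtosis"] = 0.0
    else:
        out["firstorder_Skewness"] = float("nan")
        out["firstorder_Kurtosis"] = float("nan")
    return out


def morphology_features(image: np.ndarray, mask: np.ndarray, spacing) -> dict[str, float]:
    """Volume (mL), a surface-to-volume proxy, and the centre-of-mass shift (mm)."""
    mask = np.asarray(mask, dtype=bool)
    image = np.asarray(image, dtype=float)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing, dtype=float)
    voxel_vol = float(np.prod(spacing))
    volume_mm3 = mask.sum() * voxel_vol

    # exposed-face surface area by counting mask/background face transitions
    surface = 0.0
    padded = np.pad(mask, 1)
    for axis in range(3):
        diff = np.diff(padded.astype(np.int8), axis=axis) != 0
        face_area = voxel_vol / spacing[axis]
        surface += diff.sum() * face_area

    coords = np.argwhere(mask) * spacing
    geom_com = coords.mean(axis=0)
    weights = image[mask]
    wsum = weights.sum()
    if wsum > 0:
        weighted_com = (coords * weights[:, None]).sum(axis=0) / wsum
        shift = float(np.linalg.norm(weighted_com - geom_com))
    else:
        shift = 0.0
    return {
        "morph_VolumeML": volume_mm3 / 1000.0,
        "morph_SurfaceToVolume": float(surface / volume_mm3),
        "morph_CoMShift": shift,
    }


def local_intensity_peak(image: np.ndarray, mask: np.ndarray, spacing,
                         volume_ml: float = 1.0) -> float:
    """Mean intensity in a 1 cm^3 sphere centred at the in-mask maximum voxel.

    The sphere is clipped to the image grid (not to the mask).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    center = np.unravel_index(np.nanargmax(np.where(mask, image, -np.inf)), image.shape)
    radius = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = [int(np.floor(radius / s)) for s in spacing]
    total, count = 0.0, 0
    for dx in range(-half[0], half[0] + 1):
        for dy in range(-half[1], half[1] + 1):
            for dz in range(-half[2], half[2] + 1):
                if (dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dz * spacing[2]) ** 2 > radius**2:
                    continue
                x, y, z = center[0] + dx, center[1] + dy, center[2] + dz
                if 0 <= x < image.shape[0] and 0 <= y < image.shape[1] and 0 <= z < image.shape[2]:
                    total += image[x, y, z]
                    count += 1
    return total / count


def extract_features(image: np.ndarray, mask: np.ndarray, spacing,
                     bin_width: float, suffix: str = "") -> dict[str, float]:
    """Intensity-domain features of one parametric image over one mask."""
    mask = np.asarray(mask, dtype=bool) & np.isfinite(np.asarray(image, float))
    feats = {}
    feats.update(first_order_features(image, mask, bin_width))
    if mask.sum() >= 2:
        feats.update(glcm_features(image, mask, bin_width))
    feats["local_IntensityPeak"] = local_intensity_peak(np.nan_to_num(image), mask, spacing)
    if suffix:
        feats = {f"{k}{suffix}": v for k, v in feats.items()}
    return feats


def radiomics_vector(tbr: ParametricImage, ttp: ParametricImage,
                     tumor_mask: np.ndarray) -> dict[str, float]:
    """One patient's radiomics row: TBR features, TTP features (`_TTP`), morphology.

    Deterministic key ordering (insertion order of the families).
    """
    feats = {}
    feats.update(extract_features(tbr.values, tumor_mask, tbr.spacing, TBR_BIN_WIDTH))
    feats.update(extract_features(ttp.values, tumor_mask, ttp.spacing, TTP_BIN_WIDTH, suffix="_TTP"))
    feats.update(morphology_features(tbr.values, tumor_mask, tbr.spacing))
    return feats
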