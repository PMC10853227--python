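"""Static TBR and dynamic TTP parametric images, VOIs, conventional features.

The static scan is normalized to the mean uptake of a healthy-brain
reference region, giving a tumor-to-background-ratio (TBR) image; the
tumor VOI is everything above 1.6x the brain mean inside a search region,
and the striatum VOI everything above 70% of the local maximum. Dynamic
30-frame series are turned into time-to-peak (TTP) images by smoothing
each voxel's time-activity curve (TAC) with a cubic smoothing spline,
dividing by the smoothed brain-mean TAC, and taking the frame time of the
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import convolve, map_coordinates

__all__ = [
    "ParametricImage",
    "compute_tbr_image",
    "segment_tumor",
    "segment_striatum",
    "compute_ttp_image",
    "region_ttp",
    "compute_slope",
    "sphere_peak",
    "conventional_features",
    "resample_isotropic",
    "resample_mask_isotropic",
]

TUMOR_TBR_THRESHOLD = 1.6
STRIATUM_MAX_FRACTION = 0.7
#: default smoothing-spline regularization for TAC fitting
TAC_SPLINE_LAM = 1.0


@dataclass
class ParametricImage:
    """A 3D parametric map with voxel spacing in mm.

    ``modality`` is ``"TBR"`` (unitless ratio) or ``"TTP"`` (minutes).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "TBR"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("parametric images are 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


def compute_tbr_image(static: np.ndarray, brain_mask: np.ndarray,
                      spacing=(1.0, 1.0, 1.0)) -> ParametricImage:
    """Normalize a static image to the healthy-brain mean uptake.

    After normalization the TBR mean over the brain mask is exactly 1.
    """
    static = np.asarray(static, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty; TBR normalization undefined")
    ref = static[brain_mask].mean()
    if ref <= 0:
        raise ValueError("brain mean uptake must be positive")
    return ParametricImage(static / ref, tuple(spacing), modality="TBR")


def segment_tumor(tbr: ParametricImage, search_mask: np.ndarray,
                  threshold: float = TUMOR_TBR_THRESHOLD) -> tuple[np.ndarray, float]:
    """Threshold the TBR image inside a search region; return (mask, MTV in mL).

    An empty result is legal (no voxel reaches the threshold) and yields
    MTV = 0.
    """
    search_mask = np.asarray(search_mask, dtype=bool)
    mask = (tbr.values >= threshold) & search_mask
    mtv_ml = float(mask.sum()) * tbr.voxel_volume_ml
    return mask, mtv_ml


def segment_striatum(static: np.ndarray, search_mask: np.ndarray,
                     fraction: float = STRIATUM_MAX_FRACTION) -> np.ndarray:
    """Voxels at or above ``fraction`` of the maximum uptake in the search region."""
    static = np.asarray(static, dtype=float)
    search_mask = np.asarray(search_mask, dtype=bool)
    if not search_mask.any():
        raise ValueError("striatum search mask is empty")
    peak = static[search_mask].max()
    return (static >= fraction * peak) & search_mask


def _smoother_matrix(times: np.ndarray, lam: float) -> np.ndarray:
    """Linear operator of the cubic smoothing spline evaluated on the frame grid.

    The smoothing spline with fixed ``lam`` is linear in the data, so the
    whole fit reduces to one (n_frames x n_frames) matrix applied to every
    TAC at once.
    """
    n = len(times)
    s = np.empty((n, n))
    eye = np.eye(n)
    for j in range(n):
        s[:, j] = make_smoothing_spline(times, eye[:, j], lam=lam)(times)
    return s


def compute_ttp_image(dynamic: np.ndarray, frame_times: np.ndarray,
                      brain_mask: np.ndarray, spacing=(1.0, 1.0, 1.0),
                      lam: float = TAC_SPLINE_LAM) -> ParametricImage:
    """Per-voxel time-to-peak of the fitted, brain-normalized TAC (minutes).

    Voxels with an all-zero TAC have no defined peak and are returned as
    NaN; downstream feature extraction excludes them.
    """
    dynamic = np.asarray(dynamic, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if dynamic.shape[-1] != len(frame_times):
        raise ValueError("last axis of the dynamic series must match frame_times")
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")

    smoother = _smoother_matrix(frame_times, lam)
    brain_tac = smoother @ dynamic[brain_mask].mean(axis=0)
    brain_tac = np.clip(brain_tac, 1e-12, None)

    flat = dynamic.reshape(-1, len(frame_times))
    fitted = flat @ smoother.T
    normalized = fitted / brain_tac[None, :]
    idx = np.argmax(normalized, axis=1)
    ttp = frame_times[idx].astype(float)
    ttp[np.all(flat == 0.0, axis=1)] = np.nan
    return ParametricImage(ttp.reshape(dynamic.shape[:-1]), tuple(spacing), modality="TTP")


def region_ttp(dynamic: np.ndarray, frame_times: np.ndarray,
               region_mask: np.ndarray, brain_mask: np.ndarray,
               lam: float = TAC_SPLINE_LAM) -> float:
    """TTP of the region-mean TAC, fitted and brain-normalized the same way."""
    dynamic = np.asarray(dynamic, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    smoother = _smoother_matrix(frame_times, lam)
    brain_tac = np.clip(smoother @ dynamic[np.asarray(brain_mask, bool)].mean(axis=0), 1e-12, None)
    tac = smoother @ dynamic[region_mask].mean(axis=0)
    return float(frame_times[np.argmax(tac / brain_tac)])


def compute_slope(tac: np.ndarray, frame_times: np.ndarray,
                  window: tuple[float, float] = (10.0, 30.0)) -> float:
    """OLS slope of a (normalized) TAC over the 10–30 min acquisition window."""
    tac = np.asarray(tac, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    sel = (frame_times >= window[0]) & (frame_times <= window[1])
    if sel.sum() < 2:
        raise ValueError("need at least two frames inside the slope window")
    slope, _ = np.polyfit(frame_times[sel], tac[sel], 1)
    return float(slope)


def sphere_peak(values: np.ndarray, mask: np.ndarray, spacing,
                volume_ml: float = 1.0) -> float:
    """Maximum, over mask voxels, of the mean inside a 1 cm^3 world-space sphere.

    The sphere is intersected with the image grid (common SUVpeak practice),
    so border voxels average over the in-grid part only.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    radius = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    half = [int(np.floor(radius / s)) for s in spacing]
    grids = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    dist2 = sum(((g * s) ** 2) for g, s in zip(grids, spacing))
    kernel = (dist2 <= radius**2).astype(float)
    sums = convolve(values, kernel, mode="constant", cval=0.0)
    counts = convolve(np.ones_like(values), kernel, mode="constant", cval=0.0)
    means = sums / counts
    return float(means[mask].max())


def conventional_features(static: np.ndarray, dynamic: np.ndarray,
                          frame_times: np.ndarray, brain_mask: np.ndarray,
                          tumor_mask: np.ndarray, striatum_mask: np.ndarray,
                          spacing=(1.0, 1.0, 1.0),
                          lam: float = TAC_SPLINE_LAM) -> dict[str, float]:
    """The nine region-level features of a scan.

    TBR statistics (mean/max/peak) over the tumor VOI, tumor-to-striatum
    ratios of the same three statistics, MTV (mL), the region TTP, and the
    10–30 min slope of the brain-normalized tumor TAC. An empty striatum
    yields NaN for the three TSR entries.
    """
    static = np.asarray(static, dtype=float)
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    striatum_mask = np.asarray(striatum_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    brain_mean = static[brain_mask].mean()
    tbr = static / brain_mean
    tumor_vals = tbr[tumor_mask]
    voxel_ml = float(np.prod(spacing)) / 1000.0

    feats = {
        "conv_TBR_mean": float(tumor_vals.mean()),
        "conv_TBR_max": float(tumor_vals.max()),
        "conv_TBR_peak": sphere_peak(tbr, tumor_mask, spacing),
    }
    if striatum_mask.any():
        stri_mean = static[striatum_mask].mean()
        feats["conv_TSR_mean"] = float(static[tumor_mask].mean() / stri_mean)
        feats["conv_TSR_max"] = float(static[tumor_mask].max() / stri_mean)
        feats["conv_TSR_peak"] = sphere_peak(static, tumor_mask, spacing) / stri_mean
    else:
        feats["conv_TSR_mean"] = feats["conv_TSR_max"] = feats["conv_TSR_peak"] = float("nan")
    feats["conv_MTV"] = float(tumor_mask.sum()) * voxel_ml
    feats["conv_TTP"] = region_ttp(dynamic, frame_times, tumor_mask, brain_mask, lam=lam)

    smoother = _smoother_matrix(np.asarray(frame_times, float), lam)
    brain_tac = np.clip(smoother @ np.asarray(dynamic, float)[brain_mask].mean(axis=0), 1e-12, None)
    tumor_tac = smoother @ np.asarray(dynamic, float)[tumor_mask].mean(axis=0)
    feats["conv_slope"] = compute_slope(tumor_tac / brain_tac, frame_times)
    return feats


def _resample(values: np.ndarray, spacing, target: float, order: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    new_shape = [max(1, int(np.floor((s - 1) * sp / target)) + 1)
                 for s, sp in zip(values.shape, spacing)]
    coords = np.meshgrid(
        *[np.arange(ns) * target / sp for ns, sp in zip(new_shape, spacing)],
        indexing="ij",
    )
    return map_coordinates(values, np.stack(coords), order=order, mode="nearest")


def resample_isotropic(image: ParametricImage, target: float = 1.0) -> ParametricImage:
    """Trilinear resampling onto an isotropic grid sharing the input origin."""
    if all(abs(s - target) < 1e-12 for s in image.spacing):
        return ParametricImage(image.values.copy(), image.spacing, image.modality)
    out = _resample(image.values, image.spacing, target, order=1)
    return ParametricImage(out, (target,) * 3, image.modality)


def resample_mask_isotropic(mask: np.ndarray, spacing, target: float = 1.0) -> np.ndarray:
    """Nearest-neighbour resampling for boolean masks."""
    if all(abs(s - target) < 1e-12 for s in spacing):
        return np.asarray(mask, bool).copy()
    return _resample(np.asarray(mask, float), spacing, target, order=0) > 0.5
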