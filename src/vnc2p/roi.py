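"""Sparse-neuron ROI detection, tracking, and ratiometric signal extraction.

Candidate ROIs are found on a reference activity-channel frame by Gaussian
smoothing, Otsu thresholding, and morphological erosion; the caller picks
among the candidates (a programmatic stand-in for clicking on contours).
ROIs are then tracked through the movie by integer-shift cross-correlation
against the structural channel, and mean mask fluorescence is reported as
%ΔR/R — the GCaMP/tdTomato ratio relative to its minimum 2.5 s-bin mean —
which cancels shared-intensity (motion) artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure
from skimage.feature import match_template
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk, erosion

from .io import TwoChannelMovie

__all__ = [
    "RoiMask",
    "RatioTrace",
    "detect_candidate_rois",
    "track_roi",
    "elliptical_roi",
    "extract_ratio_trace",
    "left_right_covariance",
]


@dataclass
class RoiMask:
    mask: np.ndarray  # bool (H, W)
    label: str = "other"  # 'left' | 'right' | 'other'
    frame_index: int = 0
    score: float = 1.0  # tracking QC score (NCC), 1.0 for hand-placed masks
    flagged: bool = False  # low-score frames for manual review

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass
class RatioTrace:
    """Per-ROI %ΔR/R time series with its raw ratio and baseline."""

    t: np.ndarray
    percent_dRR: np.ndarray
    roi_label: str
    ratio: np.ndarray | None = None
    baseline: float | None = None


def detect_candidate_rois(
    frame: np.ndarray,
    smoothing_sigma: float = 2.0,
    erosion_radius: int = 1,
    min_area: int = 3,
) -> list[RoiMask]:
    """Candidate neuron masks from one activity-channel frame.

    Gaussian smoothing → Otsu binarization → erosion → connected components
    with area ≥ ``min_area``, returned sorted by area (largest first). A
    blank frame, or an erosion radius that annihilates every blob, yields an
    empty list; callers then fall back to :func:`elliptical_roi`.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    smoothed = gaussian(frame, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return []
    binary = smoothed > threshold_otsu(smoothed)
    if erosion_radius > 0:
        binary = erosion(binary, disk(erosion_radius))
    labels = measure.label(binary)
    candidates = []
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            candidates.append(RoiMask(mask=labels == region.label))
    candidates.sort(key=lambda r: r.mask.sum(), reverse=True)
    return candidates


def track_roi(
    reference_mask: RoiMask,
    reference_frame: np.ndarray,
    movie: np.ndarray,
    search_radius: int = 10,
    patch_pad: int = 3,
    score_floor: float = 0.5,
) -> list[RoiMask]:
    """Track a reference ROI across frames by integer-shift cross-correlation.

    The reference patch (bounding box of the mask, padded) is correlated
    against each frame of the structural channel within ``search_radius`` of
    its reference position; the mask is emitted translated by the best shift.
    Frames scoring below ``score_floor`` are flagged for review.
    """
    rr, cc = np.nonzero(reference_mask.mask)
    h, w = reference_frame.shape
    r0 = max(0, rr.min() - patch_pad)
    r1 = min(h, rr.max() + 1 + patch_pad)
    c0 = max(0, cc.min() - patch_pad)
    c1 = min(w, cc.max() + 1 + patch_pad)
    patch = np.asarray(reference_frame, dtype=float)[r0:r1, c0:c1]
    out: list[RoiMask] = []
    for idx in range(movie.shape[0]):
        frame = np.asarray(movie[idx], dtype=float)
        s0 = r0 - search_radius
        s1 = r1 + search_radius
        t0 = c0 - search_radius
        t1 = c1 + search_radius
        if s0 < 0 or t0 < 0 or s1 > h or t1 > w:
            warnings.warn("search window clipped at image boundary")
            s0, t0 = max(0, s0), max(0, t0)
            s1, t1 = min(h, s1), min(w, t1)
        region = frame[s0:s1, t0:t1]
        if region.std() == 0 or patch.std() == 0:
            shift, score = (0, 0), 0.0
        else:
            ncc = match_template(region, patch)
            ij = np.unravel_index(np.argmax(ncc), ncc.shape)
            score = float(ncc[ij])
            shift = (s0 + ij[0] - r0, t0 + ij[1] - c0)
        mask = np.zeros_like(reference_mask.mask)
        nr = np.clip(rr + shift[0], 0, h - 1)
        nc = np.clip(cc + shift[1], 0, w - 1)
        mask[nr, nc] = True
        out.append(
            RoiMask(
                mask=mask,
                label=reference_mask.label,
                frame_index=idx,
                score=score,
                flagged=score < score_floor,
            )
        )
    return out


def elliptical_roi(
    center: tuple[float, float],
    axes: tuple[float, float],
    angle_deg: float,
    frame_shape: tuple[int, int],
) -> RoiMask:
    """Rasterized filled ellipse mask of arbitrary orientation."""
    if axes[0] <= 0 or axes[1] <= 0:
        raise ValueError("ellipse axes must be positive")
    a, b = float(axes[0]), float(axes[1])
    theta = np.deg2rad(angle_deg)
    rr, cc = np.mgrid[0 : frame_shape[0], 0 : frame_shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    # rotate into the ellipse frame; boundary pixels included (<= 1)
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    ext_r = np.hypot(a * np.cos(theta), b * np.sin(theta))
    ext_c = np.hypot(a * np.sin(theta), b * np.cos(theta))
    if (
        center[0] - ext_r < 0
        or center[0] + ext_r > frame_shape[0] - 1
        or center[1] - ext_c < 0
        or center[1] + ext_c > frame_shape[1] - 1
    ):
        raise ValueError("ellipse extends outside the frame")
    return RoiMask(mask=mask)


def extract_ratio_trace(
    movie: TwoChannelMovie,
    masks: list[RoiMask],
    baseline_bin_s: float = 2.5,
    roi_label: str | None = None,
) -> RatioTrace:
    """%ΔR/R over per-frame masks.

    R_t is the mean activity-channel intensity over the frame's mask divided
    by the mean structural-channel intensity. The ratio trace is averaged in
    non-overlapping ``baseline_bin_s`` bins; the minimum bin mean is the
    baseline R0, and %ΔR/R_t = 100 (R_t − R0)/R0. Frames whose structural
    mean is non-positive are masked (NaN) with a warning.
    """
    if len(masks) != movie.n_frames:
        raise ValueError("need one mask per frame")
    ratio = np.empty(movie.n_frames)
    for i, m in enumerate(masks):
        act = movie.activity[i][m.mask].mean()
        struct = movie.structural[i][m.mask].mean()
        if struct <= 0:
            warnings.warn(f"non-positive structural mean at frame {i}; sample masked")
            ratio[i] = np.nan
        else:
            ratio[i] = act / struct
    bin_frames = max(1, int(round(baseline_bin_s * movie.frame_rate)))
    n_bins = int(np.ceil(movie.n_frames / bin_frames))
    bin_means = [
        np.nanmean(ratio[b * bin_frames : (b + 1) * bin_frames]) for b in range(n_bins)
    ]
    r0 = float(np.nanmin(bin_means))
    if r0 <= 0:
        raise ValueError("non-positive baseline ratio")
    percent = 100.0 * (ratio - r0) / r0
    return RatioTrace(
        t=movie.timestamps,
        percent_dRR=percent,
        roi_label=roi_label or masks[0].label,
        ratio=ratio,
        baseline=r0,
    )


def left_right_covariance(trace_l: np.ndarray, trace_r: np.ndarray) -> float:
    """Pearson correlation between left- and right-neuron %ΔR/R traces."""
    trace_l = np.asarray(trace_l, dtype=float)
    trace_r = np.asarray(trace_r, dtype=float)
    if trace_l.shape != trace_r.shape or len(trace_l) < 3:
        raise ValueError("traces must have equal length >= 3")
    if trace_l.std() == 0 or trace_r.std() == 0:
        raise ValueError("correlation undefined for zero-variance trace")
    return float(stats.pearsonr(trace_l, trace_r)[0])
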