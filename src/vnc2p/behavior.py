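"""Behavior quantification from spherical-treadmill optic flow and video.

Raw ball rotations (rot s⁻¹ about the anterior-posterior, medial-lateral, and
yaw axes) are smoothed with a 200 ms running average and calibrated to
physical units: 1 rot s⁻¹ corresponds to 31.42 mm s⁻¹ of translation (ball
circumference) and to 360 ° s⁻¹ of yaw. Locomotor bouts are segmented with
fixed thresholds (±0.31 mm s⁻¹ for forward/backward or sideways walking,
±10.8 ° s⁻¹ for turning). Walking and grooming are annotated from behavior
video by frame differencing inside two regions of interest, with grooming
subservient to walking and a minimum-run-length (hysteresis) filter removing
implausibly brief state switches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "MM_PER_ROT",
    "DEG_PER_ROT",
    "OpticFlowTrace",
    "VelocityTrace",
    "BoutSegmentation",
    "AnnotationParams",
    "resample_to_common_timebase",
    "running_average",
    "convert_optic_flow",
    "segment_bouts",
    "suppress_short_runs",
    "annotate_video",
]

#: ball calibration: 1 rotation per second in millimetres per second
MM_PER_ROT = 31.42
#: yaw calibration: 1 rotation per second in degrees per second
DEG_PER_ROT = 360.0


@dataclass
class OpticFlowTrace:
    """Timestamped raw ball rotations in rot s⁻¹."""

    t: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    yaw: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        n = len(self.t)
        if not (len(self.ap) == len(self.ml) == len(self.yaw) == n):
            raise ValueError("all channels must share the timestamp length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def sample_rate(self) -> float:
        return (len(self.t) - 1) / (self.t[-1] - self.t[0])


@dataclass
class VelocityTrace:
    """Calibrated velocities: v_forward/v_side in mm s⁻¹, v_rotation in ° s⁻¹."""

    t: np.ndarray
    v_forward: np.ndarray
    v_side: np.ndarray
    v_rotation: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v_forward = np.asarray(self.v_forward, dtype=float)
        self.v_side = np.asarray(self.v_side, dtype=float)
        self.v_rotation = np.asarray(self.v_rotation, dtype=float)
        if not np.isfinite(self.v_forward).all():
            raise ValueError("velocities must be finite")

    @property
    def sample_rate(self) -> float:
        return (len(self.t) - 1) / (self.t[-1] - self.t[0])


@dataclass
class BoutSegmentation:
    walk_labels: np.ndarray  # per sample: 'forward' | 'backward' | 'still'
    turn_labels: np.ndarray  # per sample: 'cw' | 'ccw' | 'none'
    bouts: list[tuple[str, float, float]]
    percent_time_walking: float
    t: np.ndarray


@dataclass
class AnnotationParams:
    """Video-annotation parameters; rectangles are ``(r0, r1, c0, c1)``."""

    roi_walk: tuple[int, int, int, int]
    roi_groom: tuple[int, int, int, int]
    blur_radius: int = 5
    threshold_walk: int = 400
    threshold_groom: int = 5
    hysteresis_walk: int = 8
    hysteresis_groom: int = 10

    def __post_init__(self) -> None:
        if self.threshold_walk < 0 or self.threshold_groom < 0:
            raise ValueError("thresholds must be >= 0")
        for name, roi in (("roi_walk", self.roi_walk), ("roi_groom", self.roi_groom)):
            r0, r1, c0, c1 = roi
            if r0 >= r1 or c0 >= c1:
                raise ValueError(f"{name} is empty or inverted")
        wr, gr = self.roi_walk, self.roi_groom
        if not (wr[1] <= gr[0] or gr[1] <= wr[0] or wr[3] <= gr[2] or gr[3] <= wr[2]):
            raise ValueError("walk and groom ROIs may not overlap")


# ---------------------------------------------------------------------------

def resample_to_common_timebase(signals):
    """Linearly interpolate all signals onto the grid of the highest-rate one.

    ``signals`` is a list of ``(timestamps, values)`` pairs where ``values``
    may be 1-D or ``(n, k)``. The output grid is the highest-rate signal's
    timestamps restricted to the overlap of all supports. Disjoint supports
    raise ``ValueError``.
    """
    if not signals:
        raise ValueError("need at least one signal")
    parsed = []
    for t, v in signals:
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if len(t) < 2:
            raise ValueError("each signal needs >= 2 samples")
        parsed.append((t, v))
    t_lo = max(t[0] for t, _ in parsed)
    t_hi = min(t[-1] for t, _ in parsed)
    if t_lo >= t_hi:
        raise ValueError("signals have disjoint time support")
    rates = [(len(t) - 1) / (t[-1] - t[0]) for t, _ in parsed]
    ref_t = parsed[int(np.argmax(rates))][0]
    grid = ref_t[(ref_t >= t_lo) & (ref_t <= t_hi)]
    out = []
    for t, v in parsed:
        if v.ndim == 1:
            out.append((grid, np.interp(grid, t, v)))
        else:
            cols = [np.interp(grid, t, v[:, j]) for j in range(v.shape[1])]
            out.append((grid, np.stack(cols, axis=1)))
    return out


def running_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered running average with truncation at the trace edges."""
    if window_samples <= 1:
        return np.asarray(x, dtype=float).copy()
    kernel = np.ones(window_samples)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def convert_optic_flow(
    raw: OpticFlowTrace, smoothing_window: float = 0.2
) -> VelocityTrace:
    """Smooth (200 ms running average) and calibrate optic flow to velocities."""
    dt = np.median(np.diff(raw.t)) if len(raw.t) > 1 else np.inf
    n_win = int(round(smoothing_window / dt)) if np.isfinite(dt) else 0
    if n_win < 1:
        warnings.warn("smoothing window shorter than one sample; no smoothing")
        n_win = 1
    ap = running_average(raw.ap, n_win)
    ml = running_average(raw.ml, n_win)
    yaw = running_average(raw.yaw, n_win)
    return VelocityTrace(
        t=raw.t.copy(),
        v_forward=MM_PER_ROT * ap,
        v_side=MM_PER_ROT * ml,
        v_rotation=DEG_PER_ROT * yaw,
    )


def _runs(labels: np.ndarray):
    """Yield (label, start_idx, stop_idx) maximal runs (stop exclusive)."""
    if len(labels) == 0:
        return
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            yield labels[start], start, i
            start = i


def segment_bouts(
    vel: VelocityTrace,
    walk_threshold: float = 0.31,
    turn_threshold: float = 10.8,
    downsample_rate: float = 1500.0,
    smooth_s: float = 0.2,
    use_side: bool = False,
) -> BoutSegmentation:
    """Classify each sample and collect maximal bouts.

    The velocity trace is resampled to ``downsample_rate`` and smoothed with a
    ``smooth_s`` running average. A sample walks forward when its velocity
    exceeds +0.31 mm s⁻¹, backward below −0.31 mm s⁻¹, and stands still in
    between (strict inequalities); turning uses ±10.8 ° s⁻¹ the same way.
    ``use_side=True`` applies the walking thresholds to v_side (rightward /
    leftward) instead of v_forward.
    """
    if len(vel.t) == 0:
        raise ValueError("empty velocity trace")
    grid = np.arange(vel.t[0], vel.t[-1], 1.0 / downsample_rate)
    if len(grid) < 2:
        grid = vel.t.copy()
    v_lin = np.interp(grid, vel.t, vel.v_side if use_side else vel.v_forward)
    v_rot = np.interp(grid, vel.t, vel.v_rotation)
    n_win = max(1, int(round(smooth_s * downsample_rate)))
    v_lin = running_average(v_lin, n_win)
    v_rot = running_average(v_rot, n_win)

    walk = np.full(len(grid), "still", dtype=object)
    walk[v_lin > walk_threshold] = "forward"
    walk[v_lin < -walk_threshold] = "backward"
    turn = np.full(len(grid), "none", dtype=object)
    turn[v_rot > turn_threshold] = "cw"
    turn[v_rot < -turn_threshold] = "ccw"

    bouts: list[tuple[str, float, float]] = []
    for labels, null in ((walk, "still"), (turn, "none")):
        for lab, i0, i1 in _runs(labels):
            if lab != null:
                bouts.append((str(lab), float(grid[i0]), float(grid[i1 - 1])))
    pct = 100.0 * float(np.count_nonzero(walk != "still")) / len(walk)
    return BoutSegmentation(
        walk_labels=walk.astype(str),
        turn_labels=turn.astype(str),
        bouts=sorted(bouts, key=lambda b: b[1]),
        percent_time_walking=pct,
        t=grid,
    )


def suppress_short_runs(x: np.ndarray, min_len: int) -> np.ndarray:
    """Minimum-run-length (hysteresis) filter on a binary sequence.

    Any run shorter than ``min_len`` is absorbed into its surrounding state,
    shortest runs first; applying the filter twice equals applying it once.
    """
    x = np.asarray(x).astype(int).copy()
    if min_len <= 1 or len(x) == 0:
        return x
    while True:
        runs = list(_runs(x))
        if len(runs) <= 1:
            return x
        short = [(i1 - i0, idx) for idx, (_, i0, i1) in enumerate(runs) if i1 - i0 < min_len]
        if not short:
            return x
        _, idx = min(short)
        lab, i0, i1 = runs[idx]
        neighbor = runs[idx - 1][0] if idx > 0 else runs[idx + 1][0]
        x[i0:i1] = neighbor


def annotate_video(frames: np.ndarray, params: AnnotationParams):
    """Binary walking and grooming sequences from a grayscale video.

    Consecutive frames are subtracted; the absolute differential image is
    median blurred (radius ``blur_radius``); the number of non-zero pixels in
    each ROI is thresholded (≥). Grooming is subservient to walking. A
    minimum-run-length filter is applied to walking first, then grooming is
    recomputed under subservience and filtered. Output length is
    ``n_frames − 1``; returns ``(S_w, S_g)``.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need >= 2 grayscale frames")
    h, w = frames.shape[1:]
    for name, roi in (("roi_walk", params.roi_walk), ("roi_groom", params.roi_groom)):
        r0, r1, c0, c1 = roi
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(f"{name} outside the frame bounds")
    footprint = disk(params.blur_radius)
    is_int = np.issubdtype(frames.dtype, np.integer)
    zero_tol = 0 if is_int else 1e-9
    n = frames.shape[0] - 1
    count_w = np.zeros(n, dtype=int)
    count_g = np.zeros(n, dtype=int)
    wr = params.roi_walk
    gr = params.roi_groom
    for i in range(n):
        diff = np.abs(frames[i + 1].astype(np.int64) - frames[i].astype(np.int64)) \
            if is_int else np.abs(frames[i + 1].astype(float) - frames[i].astype(float))
        blurred = ndimage.median_filter(diff, footprint=footprint)
        count_w[i] = int((blurred[wr[0]:wr[1], wr[2]:wr[3]] > zero_tol).sum())
        count_g[i] = int((blurred[gr[0]:gr[1], gr[2]:gr[3]] > zero_tol).sum())
    raw_w = (count_w >= params.threshold_walk).astype(int)
    raw_g = (count_g >= params.threshold_groom).astype(int)
    s_w = suppress_short_runs(raw_w, params.hysteresis_walk)
    s_g = suppress_short_runs(raw_g & (1 - s_w), params.hysteresis_groom)
    s_g = s_g & (1 - s_w)  # subservience is a hard mask
    return s_w, s_g
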