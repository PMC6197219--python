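"""Pixel-wise behavior-regression maps.

Binary behavior sequences (walking, grooming) are convolved with a calcium
signal impulse response — a peak-normalized causal exponential whose
half-life matches GCaMP6s decay (t1/2 = 1.1448 s) — to form regressors
X = S ⊗ CIR. Per-pixel ΔF/F traces are regressed against each regressor with
no-intercept least squares, w = (XᵀX)⁻¹Xᵀy, and the resulting weight images,
normalized to their maxima, map which pixels covary with which behavior.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CalciumImpulseResponse",
    "DffMovie",
    "WeightMap",
    "compute_dff",
    "suggest_quiescent_window",
    "build_regressor",
    "fit_weights",
    "normalize_map",
    "extract_map_roi_trace",
]

GCAMP6S_HALF_LIFE_S = 1.1448


class CalciumImpulseResponse:
    """Causal exponential decay kernel, peak-normalized.

    ``kernel[0] = 1``, the value a half-life after onset is 0.5 (within one
    sample of interpolation), and the kernel is non-increasing. Duration
    defaults to five half-lives, by which the kernel has decayed to ~3%.
    """

    def __init__(
        self,
        half_life: float = GCAMP6S_HALF_LIFE_S,
        sample_rate: float = 8.0,
        duration: float | None = None,
    ):
        if half_life <= 0 or sample_rate <= 0:
            raise ValueError("half_life and sample_rate must be positive")
        self.half_life = float(half_life)
        self.sample_rate = float(sample_rate)
        self.duration = float(duration) if duration is not None else 5.0 * half_life
        self.t = np.arange(0.0, self.duration, 1.0 / self.sample_rate)
        self.kernel = np.exp(-np.log(2.0) * self.t / self.half_life)

    def half_decay_time(self) -> float:
        """Time at which the kernel crosses half its initial amplitude,
        located by linear interpolation between samples."""
        below = np.nonzero(self.kernel <= 0.5)[0]
        if len(below) == 0:
            raise ValueError("kernel never decays to half amplitude")
        i = below[0]
        if i == 0:
            return float(self.t[0])
        t0, t1 = self.t[i - 1], self.t[i]
        k0, k1 = self.kernel[i - 1], self.kernel[i]
        return float(t0 + (k0 - 0.5) / (k0 - k1) * (t1 - t0))


class DffMovie:
    """Per-pixel ΔF/F with its baseline image and validity mask."""

    def __init__(self, values: np.ndarray, baseline: np.ndarray, mask: np.ndarray):
        self.values = values  # (T, H, W)
        self.baseline = baseline  # (H, W)
        self.mask = mask  # (H, W) bool; True where baseline is usable


class WeightMap:
    def __init__(self, weights: np.ndarray, normalized: bool = False, degenerate: bool = False):
        self.weights = weights
        self.normalized = normalized
        self.degenerate = degenerate


def compute_dff(
    activity: np.ndarray,
    quiescent_start_frame: int = 0,
    n_baseline_frames: int = 10,
    baseline_floor_frac: float = 0.01,
) -> DffMovie:
    """ΔF/F against the mean of ten sequential quiescent frames.

    ``F`` is the per-pixel mean of ``n_baseline_frames`` frames starting at
    ``quiescent_start_frame``; ΔF/F_t = (F_t − F) / F. Pixels whose baseline
    falls below ``baseline_floor_frac`` of the movie's dynamic range are
    masked out (weight-fitting later assigns them zero).
    """
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 3:
        raise ValueError("activity must be (n_frames, h, w)")
    t0 = int(quiescent_start_frame)
    if t0 < 0 or t0 + n_baseline_frames > activity.shape[0]:
        raise ValueError(
            f"need {n_baseline_frames} frames from frame {t0}; "
            f"movie has {activity.shape[0]}"
        )
    baseline = activity[t0 : t0 + n_baseline_frames].mean(axis=0)
    floor = baseline_floor_frac * float(np.ptp(activity))
    mask = baseline > max(floor, 1e-12)
    safe = np.where(mask, baseline, 1.0)
    values = (activity - baseline) / safe
    values[:, ~mask] = 0.0
    return DffMovie(values=values, baseline=baseline, mask=mask)


def suggest_quiescent_window(activity: np.ndarray, n_frames: int = 10) -> int:
    """Propose the start of the quietest 10-frame window (minimal total
    temporal variance), a programmatic stand-in for visually picking frames
    with minimal, unchanging fluorescence."""
    activity = np.asarray(activity, dtype=float)
    n = activity.shape[0] - n_frames + 1
    if n < 1:
        raise ValueError("movie shorter than the baseline window")
    scores = [activity[i : i + n_frames].var(axis=0).sum() for i in range(n)]
    return int(np.argmin(scores))


def build_regressor(s: np.ndarray, cir: CalciumImpulseResponse) -> np.ndarray:
    """X = S ⊗ CIR, causal convolution truncated to the length of S."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty behavior sequence")
    return np.convolve(s, cir.kernel)[: len(s)]


def fit_weights(x: np.ndarray, dff: DffMovie) -> WeightMap:
    """Per-pixel no-intercept least squares: w = (XᵀX)⁻¹ Xᵀ y.

    Masked pixels receive weight 0. A degenerate (all-zero) regressor is an
    error.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != dff.values.shape[0]:
        raise ValueError("regressor and movie lengths differ")
    # time on the contiguous last axis: numerator and denominator then share
    # the same pairwise-sum reduction, so an exact fit (y = X) gives 1.0 exactly
    xtx = (x * x).sum()
    if xtx == 0.0:
        raise ValueError("degenerate regressor: XᵀX = 0")
    t, h, w = dff.values.shape
    yt = np.ascontiguousarray(dff.values.reshape(t, h * w).T)
    weights = ((yt * x).sum(axis=1) / xtx).reshape(h, w)
    weights[~dff.mask] = 0.0
    return WeightMap(weights=weights)


def normalize_map(wmap: WeightMap) -> WeightMap:
    """Divide by the maximum weight; an all-zero map is returned unchanged
    with its ``degenerate`` flag set. Negative pixels keep their sign."""
    m = float(wmap.weights.max()) if wmap.weights.size else 0.0
    if m == 0.0:
        return WeightMap(wmap.weights.copy(), normalized=False, degenerate=True)
    return WeightMap(wmap.weights / m, normalized=True)


def extract_map_roi_trace(
    dff: DffMovie, center: tuple[int, int], radius: int = 15
) -> np.ndarray:
    """Per-frame mean ΔF/F over a disk ROI of the given radius."""
    h, w = dff.values.shape[1:]
    r0, c0 = center
    if r0 - radius < 0 or c0 - radius < 0 or r0 + radius >= h or c0 + radius >= w:
        raise ValueError("ROI disk extends outside the image")
    rr, cc = np.mgrid[0:h, 0:w]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return dff.values[:, mask].mean(axis=1)
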