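"""Synthetic two-photon imaging data with known ground truth.

Emulates the inputs of a tethered-fly VNC imaging experiment:

* a structural (tdTomato-like) template image deformed frame-to-frame by
  smooth non-rigid motion fields,
* an activity (GCaMP6s-like) channel equal to the structural image modulated
  multiplicatively by planted calcium transients on known pixel masks,
* spherical-treadmill optic-flow traces coupled to a scheduled behavior
  state sequence,
* a behavior video with a rear-leg region that moves during walking and a
  front region that moves during grooming,
* ratio (%ΔR/R-like) traces with planted transients for event-detection
  benchmarks.

Every generator is deterministic given ``SyntheticConfig.rng_seed``.
Intensities are on a photon-count-like scale (background a few hundred,
cell bodies a few thousand) typical of 12-bit two-photon acquisition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import TwoChannelMovie

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "WALKING_STATES",
    "GROOMING_STATES",
    "make_structural_template",
    "make_deformation_sequence",
    "make_ground_truth",
    "render_movie",
    "make_optic_flow",
    "make_behavior_frames",
    "default_video_rois",
    "calcium_kernel",
    "make_ratio_trace",
    "warp_image",
]

#: behavior states treated as locomotion by the video generator
WALKING_STATES = frozenset({"walk_fwd", "walk_bwd", "turn_left", "turn_right"})
GROOMING_STATES = frozenset({"groom"})
_ALL_STATES = WALKING_STATES | GROOMING_STATES | {"still", "push_down"}

#: per-state mean treadmill rotations (ap, ml, yaw) in rot s⁻¹
_STATE_FLOW = {
    "still": (0.0, 0.0, 0.0),
    "groom": (0.0, 0.0, 0.0),
    "walk_fwd": (0.5, 0.0, 0.0),
    "walk_bwd": (-0.3, 0.0, 0.0),
    "turn_left": (0.1, 0.0, -0.5),
    "turn_right": (0.1, 0.0, 0.5),
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic experiment.

    ``behavior_schedule`` lists non-overlapping ``(state, start_s, end_s)``
    intervals inside the recording; time outside every interval is ``still``.
    ``event_times`` maps neuron names (e.g. ``"left"``, ``"right"``) to lists
    of planted transient onset times in seconds.
    """

    image_height: int = 64
    image_width: int = 64
    n_frames: int = 100
    frame_rate: float = 8.0  # Hz; galvo-galvo two-photon scan rates run 6-9 Hz
    deformation_amplitude: float = 3.0  # px
    deformation_smoothness: float = 8.0  # px spatial correlation scale
    noise_sd: float = 20.0  # intensity units, additive Gaussian
    event_times: dict[str, list[float]] = field(default_factory=dict)
    cir_half_life: float = 1.1448  # s, GCaMP6s decay half-life
    behavior_schedule: list[tuple[str, float, float]] = field(default_factory=list)
    rng_seed: int = 0
    n_blobs: int = 20
    background: float = 300.0
    blob_amplitude: float = 3000.0
    gain: float = 1.0  # peak fractional fluorescence increase of a transient
    flow_rate: float = 800.0  # Hz, optic-flow sample rate
    flow_noise_sd: float = 0.02  # rot s⁻¹
    video_rate: float = 30.0  # Hz
    video_shape: tuple[int, int] = (64, 96)
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.deformation_amplitude < 0:
            raise ValueError("deformation_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        duration = self.duration
        prev_end = None
        for state, start, end in sorted(self.behavior_schedule, key=lambda s: s[1]):
            if state not in _ALL_STATES:
                raise ValueError(f"unknown behavior state {state!r}")
            if not (0.0 <= start < end <= duration + 1e-9):
                raise ValueError(
                    f"schedule interval ({state}, {start}, {end}) outside "
                    f"[0, {duration})"
                )
            if prev_end is not None and start < prev_end - 1e-9:
                raise ValueError("behavior_schedule intervals overlap")
            prev_end = end

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_height, self.image_width)


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    true_fields: np.ndarray  # (T, H, W, 2) registration fields, frame 0 zero
    true_event_onsets: dict[str, np.ndarray]  # seconds, per neuron
    active_pixel_mask: dict[str, np.ndarray]  # bool (H, W) per signal source
    behavior_states: list[str]  # per imaging frame
    activity_traces: dict[str, np.ndarray] = field(default_factory=dict)


def _rng(config: SyntheticConfig, salt: int) -> np.random.Generator:
    # independent stream per generator so adding one does not shift others
    return np.random.default_rng((int(config.rng_seed) * 1_000_003 + salt) % 2**31)


def calcium_kernel(
    half_life: float, sample_rate: float, duration: float | None = None
) -> np.ndarray:
    """Peak-normalized causal exponential decay kernel, sampled at ``sample_rate``."""
    if duration is None:
        duration = 5.0 * half_life
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    return np.exp(-np.log(2.0) * t / half_life)


def state_at(schedule: list[tuple[str, float, float]], t: float) -> str:
    for state, start, end in schedule:
        if start <= t < end:
            return state
    return "still"


# ---------------------------------------------------------------------------
# template and deformation

def make_structural_template(config: SyntheticConfig) -> np.ndarray:
    """Sparse bright blobs (cell bodies/neurites) on a dim textured background."""
    rng = _rng(config, 1)
    h, w = config.shape
    img = np.full((h, w), config.background, dtype=float)
    # low-amplitude smooth texture so even blob-free regions carry gradient
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), 2.0)
    img += 0.15 * config.background * texture / max(texture.std(), 1e-12)
    rows = rng.uniform(3, h - 3, size=config.n_blobs)
    cols = rng.uniform(3, w - 3, size=config.n_blobs)
    amps = config.blob_amplitude * rng.uniform(0.4, 1.0, size=config.n_blobs)
    sigmas = rng.uniform(1.5, 3.5, size=config.n_blobs)
    rr, cc = np.mgrid[0:h, 0:w]
    for r0, c0, a, s in zip(rows, cols, amps, sigmas):
        img += a * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s**2))
    return np.clip(img, 0.0, None)


def make_deformation_sequence(config: SyntheticConfig) -> np.ndarray:
    """Per-frame smooth non-rigid displacement fields, frame 0 identically zero.

    Independent Gaussian noise per component is low-pass filtered spatially at
    scale ``deformation_smoothness`` and temporally by a short moving average,
    re-anchored so frame 0 is zero, then rescaled so the maximum displacement
    magnitude equals ``deformation_amplitude``.
    """
    rng = _rng(config, 2)
    h, w = config.shape
    n = config.n_frames
    if config.deformation_amplitude == 0:
        return np.zeros((n, h, w, 2))
    raw = rng.standard_normal((n + 4, h, w, 2))
    smooth = ndimage.gaussian_filter(
        raw, sigma=(0, config.deformation_smoothness, config.deformation_smoothness, 0)
    )
    # temporal moving average over 5 frames
    smooth = ndimage.uniform_filter1d(smooth, size=5, axis=0)[2 : 2 + n]
    fields = smooth - smooth[0]  # anchor: reference frame carries zero motion
    mag = np.sqrt((fields**2).sum(axis=-1))
    # scale so typical displacements approach the amplitude, then hard-clip
    # the rare excess so max |w| <= amplitude exactly
    ref = np.percentile(mag[1:], 95) if n > 1 else mag.max()
    if ref > 0:
        fields *= config.deformation_amplitude / ref
        mag = np.sqrt((fields**2).sum(axis=-1))
        over = mag > config.deformation_amplitude
        if over.any():
            scale = np.ones_like(mag)
            scale[over] = config.deformation_amplitude / mag[over]
            fields *= scale[..., None]
    return fields


def warp_image(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Sample ``image`` at ``x + field(x)`` with bilinear interpolation.

    Matches the registration module's warping convention (edge clamping), so
    ground-truth fields are self-consistent with the estimator.
    """
    h, w = image.shape
    rr, cc = np.mgrid[0:h, 0:w]
    coords = np.stack([rr + field[..., 0], cc + field[..., 1]])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def invert_field(field: np.ndarray, n_iter: int = 8) -> np.ndarray:
    """Fixed-point inverse of ``x -> x + field(x)`` (valid for smooth fields)."""
    inv = -field.copy()
    for _ in range(n_iter):
        warped = np.stack(
            [warp_image(field[..., 0], inv), warp_image(field[..., 1], inv)], axis=-1
        )
        inv = -warped
    return inv


# ---------------------------------------------------------------------------
# ground truth assembly

def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _binary_state_sequence(config: SyntheticConfig, states: frozenset[str]) -> np.ndarray:
    t = np.arange(config.n_frames) / config.frame_rate
    return np.array(
        [1.0 if state_at(config.behavior_schedule, ti) in states else 0.0 for ti in t]
    )


def make_ground_truth(
    config: SyntheticConfig,
    masks: dict[str, np.ndarray] | None = None,
) -> GroundTruth:
    """Assemble deformation fields, activity traces, and pixel masks.

    One disjoint disk mask is planted per neuron in ``event_times`` and, when
    the schedule contains walking or grooming states, per behavior regressor
    (``"walking"``, ``"grooming"``). Neuron activity traces are the planted
    event trains convolved with a causal exponential calcium kernel (peak 1);
    behavior-coupled traces are the binary state sequence convolved with the
    same kernel, normalized by the kernel sum so a sustained bout saturates
    near 1.
    """
    rng = _rng(config, 3)
    fields = make_deformation_sequence(config)
    t_frames = np.arange(config.n_frames) / config.frame_rate
    states = [state_at(config.behavior_schedule, ti) for ti in t_frames]

    sources = list(config.event_times)
    scheduled = {s for s, _, _ in config.behavior_schedule}
    if scheduled & WALKING_STATES:
        sources.append("walking")
    if scheduled & GROOMING_STATES:
        sources.append("grooming")

    if masks is None:
        masks = {}
        h, w = config.shape
        radius = max(3, min(h, w) // 12)
        taken = np.zeros(config.shape, dtype=bool)
        for name in sources:
            for _ in range(200):
                center = (
                    rng.integers(radius + 1, h - radius - 1),
                    rng.integers(radius + 1, w - radius - 1),
                )
                m = _disk_mask(config.shape, center, radius)
                if not (m & taken).any():
                    break
            masks[name] = m
            taken |= m

    kernel = calcium_kernel(config.cir_half_life, config.frame_rate)
    traces: dict[str, np.ndarray] = {}
    for name in sources:
        if name in config.event_times:
            train = np.zeros(config.n_frames)
            for onset in config.event_times[name]:
                idx = int(round(onset * config.frame_rate))
                if 0 <= idx < config.n_frames:
                    train[idx] += 1.0
            traces[name] = np.convolve(train, kernel)[: config.n_frames]
        elif name == "walking":
            s = _binary_state_sequence(config, WALKING_STATES)
            traces[name] = np.convolve(s, kernel)[: config.n_frames] / kernel.sum()
        elif name == "grooming":
            s = _binary_state_sequence(config, GROOMING_STATES)
            traces[name] = np.convolve(s, kernel)[: config.n_frames] / kernel.sum()

    onsets = {k: np.asarray(sorted(v), dtype=float) for k, v in config.event_times.items()}
    return GroundTruth(
        true_fields=fields,
        true_event_onsets=onsets,
        active_pixel_mask={k: masks[k] for k in sources},
        behavior_states=states,
        activity_traces=traces,
    )


def render_movie(
    template: np.ndarray,
    fields: np.ndarray,
    ground_truth: GroundTruth,
    config: SyntheticConfig,
    gain: float | None = None,
) -> TwoChannelMovie:
    """Render both channels under shared deformation.

    The activity image in template coordinates is
    ``template * (1 + gain * sum_k mask_k * a_k(t))``; both channels are then
    deformed identically. ``fields`` are registration ground truth (they map
    reference coordinates onto frame coordinates), so each frame is rendered
    by warping with the numerical inverse of its field.
    """
    if gain is None:
        gain = config.gain
    if len(fields) != config.n_frames:
        raise ValueError("fields length must equal n_frames")
    for name, mask in ground_truth.active_pixel_mask.items():
        if mask.shape != template.shape:
            raise ValueError(f"mask {name!r} shape {mask.shape} != template shape")
    rng = _rng(config, 4)
    h, w = template.shape
    structural = np.empty((config.n_frames, h, w))
    activity = np.empty_like(structural)
    for ti in range(config.n_frames):
        if np.any(fields[ti]):
            render_field = invert_field(fields[ti])
            struct_t = warp_image(template, render_field)
        else:
            render_field = None
            struct_t = template.copy()
        modulation = np.ones((h, w))
        for name, mask in ground_truth.active_pixel_mask.items():
            a = ground_truth.activity_traces.get(name)
            if a is not None and a[ti] != 0.0:
                modulation = modulation + gain * a[ti] * mask
        act_img = template * modulation
        act_t = warp_image(act_img, render_field) if render_field is not None else act_img
        structural[ti] = struct_t
        activity[ti] = act_t
    if config.poisson_noise:
        structural = rng.poisson(np.clip(structural, 0, None)).astype(float)
        activity = rng.poisson(np.clip(activity, 0, None)).astype(float)
    if config.noise_sd > 0:
        structural = structural + rng.normal(0, config.noise_sd, structural.shape)
        activity = activity + rng.normal(0, config.noise_sd, activity.shape)
    return TwoChannelMovie(
        activity=activity,
        structural=structural,
        frame_rate=config.frame_rate,
        channel_names=("GCaMP6s-like", "tdTomato-like"),
    )


# ---------------------------------------------------------------------------
# optic flow and behavior video

def make_optic_flow(ground_truth: GroundTruth, config: SyntheticConfig):
    """Raw ball-rotation traces (rot s⁻¹) coupled to the behavior schedule.

    Backward-walking intervals carry negative anterior-posterior flow, turns
    carry signed yaw (left negative), and ``push_down`` intervals carry a
    biphasic anterior-posterior pulse (positive then negative half). Returns
    ``(t, ap, ml, yaw)`` arrays at ``config.flow_rate``.
    """
    rng = _rng(config, 5)
    t = np.arange(0.0, config.duration, 1.0 / config.flow_rate)
    ap = np.zeros_like(t)
    ml = np.zeros_like(t)
    yaw = np.zeros_like(t)
    for state, start, end in config.behavior_schedule:
        if state not in _ALL_STATES:
            raise ValueError(f"unknown behavior state {state!r}")
        sel = (t >= start) & (t < end)
        if state == "push_down":
            mid = 0.5 * (start + end)
            ap[sel & (t < mid)] += 0.6
            ap[sel & (t >= mid)] -= 0.6
            continue
        a, m, y = _STATE_FLOW[state]
        ap[sel] += a
        ml[sel] += m
        yaw[sel] += y
    if config.flow_noise_sd > 0:
        ap = ap + rng.normal(0, config.flow_noise_sd, t.shape)
        ml = ml + rng.normal(0, config.flow_noise_sd, t.shape)
        yaw = yaw + rng.normal(0, config.flow_noise_sd, t.shape)
    return t, ap, ml, yaw


def default_video_rois(config: SyntheticConfig):
    """Rectangles (r0, r1, c0, c1): rear-leg (walking) and front (grooming) ROI."""
    h, w = config.video_shape
    roi_walk = (h // 6, h - h // 6, int(w * 0.55), int(w * 0.95))
    roi_groom = (h // 6, h - h // 6, int(w * 0.06), int(w * 0.45))
    return roi_walk, roi_groom


def make_behavior_frames(
    ground_truth: GroundTruth, config: SyntheticConfig
) -> np.ndarray:
    """Grayscale uint8 behavior video at ``config.video_rate``.

    The rear-leg region is re-textured every frame during walking states and
    the front region during grooming; everything else is static.
    """
    rng = _rng(config, 6)
    h, w = config.video_shape
    n = int(round(config.duration * config.video_rate))
    base = rng.integers(40, 120, size=(h, w)).astype(np.uint8)
    roi_walk, roi_groom = default_video_rois(config)
    frames = np.repeat(base[None], n, axis=0)
    for i in range(n):
        state = state_at(config.behavior_schedule, i / config.video_rate)
        if state in WALKING_STATES:
            r0, r1, c0, c1 = roi_walk
            frames[i, r0:r1, c0:c1] = rng.integers(0, 255, size=(r1 - r0, c1 - c0))
        elif state in GROOMING_STATES:
            r0, r1, c0, c1 = roi_groom
            frames[i, r0:r1, c0:c1] = rng.integers(0, 255, size=(r1 - r0, c1 - c0))
    return frames


# ---------------------------------------------------------------------------
# ratio traces for event-detection benchmarks

def make_ratio_trace(
    event_times: np.ndarray | list[float],
    duration: float,
    sample_rate: float = 8.0,
    amplitude: float = 50.0,
    noise_sd: float = 4.0,
    noise_correlation_s: float = 0.0,
    half_life: float = 1.1448,
    rise_tau: float = 0.15,
    seed: int = 0,
):
    """Synthetic %ΔR/R trace with planted calcium transients.

    Transients rise with time constant ``rise_tau`` (indicator binding
    kinetics; the rise spans a few samples at imaging rates) and decay with
    half-life ``half_life``; the kernel is peak-normalized so ``amplitude``
    is the peak %ΔR/R of an isolated event. Noise is Gaussian with a short
    temporal correlation (boxcar-filtered white noise rescaled to
    ``noise_sd``), emulating the slow residual fluctuations of ratiometric
    traces. Returns ``(t, trace)``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    train = np.zeros(n)
    for onset in event_times:
        idx = int(round(onset * sample_rate))
        if 0 <= idx < n:
            train[idx] += 1.0
    kernel = calcium_kernel(half_life, sample_rate)
    if rise_tau > 0:
        tk = np.arange(len(kernel)) / sample_rate
        kernel = (1.0 - np.exp(-tk / rise_tau)) * kernel
        if kernel.max() > 0:
            kernel = kernel / kernel.max()
    signal = amplitude * np.convolve(train, kernel)[:n]
    k = max(1, int(round(noise_correlation_s * sample_rate)))
    white = rng.standard_normal(n + 2 * k)
    colored = ndimage.uniform_filter1d(white, size=k)[k : k + n]
    if colored.std() > 0 and noise_sd > 0:
        noise = noise_sd * colored / colored.std()
    else:
        noise = np.zeros(n)
    return t, signal + noise
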