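"""Fluorescence transient event detection and event-triggered summaries.

An event is the onset of a fluorescence rise: the detector finds upward
crossings of the %ΔR/R first derivative over a class-wide threshold (the
97.5th percentile of pooled derivative values for strongly-transienting
classes such as MDN/dMAN, the 90th for A1), then walks back to the nearest
preceding derivative zero-crossing, which is taken as the event time.
Crossings sharing a rise (no intervening zero-crossing) compress into one
event. Events in the first and last 10 s of a trace are excluded because the
presentation window spans ±10 s.

Bilateral pairs are reconciled two ways. Covarying classes (left/right MDN,
dMAN): events found on both sides within 2 s are kept; an event found on one
side only is copied to the partner. Independent classes (A1): events found on
both sides within 0.25 s are discarded from both.

Event-triggered summaries align signals to event times, downsample to
500 values s⁻¹, baseline-subtract %ΔR/R to zero at the event, and report the
pointwise mean with bootstrapped 95% confidence intervals, alongside a
control built from uniformly random surrogate event times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import VelocityTrace

__all__ = [
    "EventConfig",
    "EventSeries",
    "EventTriggeredSummary",
    "pool_derivative_threshold",
    "detect_events",
    "reconcile_bilateral",
    "event_triggered_summary",
    "shuffled_control",
    "select_exemplar_events",
]


@dataclass
class EventConfig:
    percentile: float = 97.5  # pooled-derivative percentile (90 for A1-like)
    covarying_pair: bool = True
    pair_merge_window: float = 2.0  # s
    independent_veto_window: float = 0.25  # s
    edge_exclusion: float = 10.0  # s
    summary_window: float = 10.0  # s, each side of the event
    summary_rate: float = 500.0  # samples s⁻¹
    n_bootstrap: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 100.0):
            raise ValueError("percentile must be in (0, 100)")
        for name in ("pair_merge_window", "independent_veto_window",
                     "edge_exclusion", "summary_window", "summary_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class EventSeries:
    onsets: np.ndarray  # s, strictly increasing
    source: list[str] = field(default_factory=list)  # 'detected' | 'copied_from_partner'
    vetoed: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if not self.source:
            self.source = ["detected"] * len(self.onsets)
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class EventTriggeredSummary:
    t_rel: np.ndarray  # s relative to event onset, 0 at onset
    mean: dict[str, np.ndarray]
    ci_lo: dict[str, np.ndarray]
    ci_hi: dict[str, np.ndarray]
    n_events: int


def _derivative(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """First difference scaled by the sample interval; value i describes the
    step from sample i to i+1."""
    return np.diff(x) / np.diff(t)


def pool_derivative_threshold(traces, percentile: float) -> float:
    """Class-wide derivative threshold.

    ``traces`` is a list of ``(t, values)`` pairs for every experiment of one
    neuron class; signed first-difference derivatives are pooled across all of
    them and the stated percentile (linear interpolation between order
    statistics) is returned. Pooling is order-free.
    """
    if not traces:
        raise ValueError("empty trace pool")
    pooled = np.concatenate([_derivative(np.asarray(t), np.asarray(x)) for t, x in traces])
    return float(np.percentile(pooled, percentile))


def detect_events(
    t: np.ndarray, x: np.ndarray, threshold: float, config: EventConfig | None = None
) -> EventSeries:
    """Detect transient onsets on one %ΔR/R trace.

    For each upward threshold crossing of the derivative the onset is the
    nearest preceding sample at which the derivative crossed zero (last
    non-positive derivative sample). Crossings with no intervening
    zero-crossing collapse onto the first onset, and onsets within
    ``edge_exclusion`` of either trace end are dropped.
    """
    if config is None:
        config = EventConfig()
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    d = _derivative(t, x)
    onset_idx: list[int] = []
    for i in range(1, len(d)):
        if d[i] >= threshold and d[i - 1] < threshold:
            j = i
            while j > 0 and d[j - 1] > 0:
                j -= 1
            if not onset_idx or onset_idx[-1] != j:
                onset_idx.append(j)
    onsets = t[np.array(onset_idx, dtype=int)] if onset_idx else np.array([])
    lo = t[0] + config.edge_exclusion
    hi = t[-1] - config.edge_exclusion
    onsets = np.unique(onsets[(onsets >= lo) & (onsets <= hi)])
    return EventSeries(onsets=onsets)


def reconcile_bilateral(
    left: EventSeries,
    right: EventSeries,
    config: EventConfig | None = None,
    t_range: tuple[float, float] | None = None,
) -> tuple[EventSeries, EventSeries]:
    """Reconcile a left/right event pair under the class covariance rule.

    Covarying classes: greedy time-ordered nearest pairing within
    ``pair_merge_window``; paired events are kept on both sides and unpaired
    events are copied to the partner (``source='copied_from_partner'``),
    except copies that would land inside the partner's edge-exclusion zone
    when ``t_range`` is given. Independent classes: any left/right pair
    within ``independent_veto_window`` is removed from both sides and
    recorded in ``vetoed``. Covarying mode never deletes a detected event;
    independent mode never creates one.
    """
    if config is None:
        config = EventConfig()
    lt = list(left.onsets)
    rt = list(right.onsets)
    if config.covarying_pair:
        paired_l, paired_r = _greedy_pairs(lt, rt, config.pair_merge_window)
        new_l = [(o, s) for o, s in zip(lt, left.source)]
        new_r = [(o, s) for o, s in zip(rt, right.source)]
        for i, o in enumerate(lt):
            if i not in paired_l and _copy_allowed(o, t_range, config):
                new_r.append((o, "copied_from_partner"))
        for j, o in enumerate(rt):
            if j not in paired_r and _copy_allowed(o, t_range, config):
                new_l.append((o, "copied_from_partner"))
        return _sorted_series(new_l), _sorted_series(new_r)
    # independent: veto close pairs
    paired_l, paired_r = _greedy_pairs(lt, rt, config.independent_veto_window)
    vetoed = [(lt[i], rt[paired_l[i]]) for i in paired_l]
    keep_l = [(o, s) for i, (o, s) in enumerate(zip(lt, left.source)) if i not in paired_l]
    keep_r = [(o, s) for j, (o, s) in enumerate(zip(rt, right.source)) if j not in paired_r]
    out_l = _sorted_series(keep_l)
    out_r = _sorted_series(keep_r)
    out_l.vetoed = list(vetoed)
    out_r.vetoed = list(vetoed)
    return out_l, out_r


def _copy_allowed(onset, t_range, config) -> bool:
    if t_range is None:
        return True
    return t_range[0] + config.edge_exclusion <= onset <= t_range[1] - config.edge_exclusion


def _greedy_pairs(lt, rt, window):
    """Time-ordered greedy nearest matching; returns index maps l->r and r->l."""
    paired_l: dict[int, int] = {}
    paired_r: dict[int, int] = {}
    for i, lo in enumerate(lt):
        best_j, best_d = None, None
        for j, ro in enumerate(rt):
            if j in paired_r:
                continue
            d = abs(lo - ro)
            if d <= window and (best_d is None or d < best_d):
                best_j, best_d = j, d
        if best_j is not None:
            paired_l[i] = best_j
            paired_r[best_j] = i
    return paired_l, paired_r


def _sorted_series(entries) -> EventSeries:
    entries = sorted(entries, key=lambda e: e[0])
    dedup: list[tuple[float, str]] = []
    for o, s in entries:
        if dedup and abs(o - dedup[-1][0]) < 1e-12:
            continue  # stable merge: keep the first (detected before copied)
        dedup.append((o, s))
    return EventSeries(
        onsets=np.array([o for o, _ in dedup]),
        source=[s for _, s in dedup],
    )


# ---------------------------------------------------------------------------
# event-triggered summaries

def event_triggered_summary(
    events: EventSeries,
    signals: dict[str, tuple[np.ndarray, np.ndarray]],
    config: EventConfig | None = None,
    baseline_subtract: tuple[str, ...] = ("percent_dRR",),
    rng: np.random.Generator | None = None,
) -> EventTriggeredSummary:
    """Mean ± bootstrapped 95% CI of signals aligned to event onsets.

    ``signals`` maps names to ``(t, values)``. Each signal is windowed to
    ±``summary_window`` around each onset and linearly resampled to
    ``summary_rate``; signals named in ``baseline_subtract`` are shifted so
    their value at t = 0 is exactly zero. Events lacking a full window are
    skipped; having none left is an error. The CI is a percentile bootstrap
    over events (``n_bootstrap`` replicates).
    """
    if config is None:
        config = EventConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    half = int(round(config.summary_window * config.summary_rate))
    t_rel = np.arange(-half, half + 1) / config.summary_rate  # exact 0 at center
    windows: dict[str, list[np.ndarray]] = {k: [] for k in signals}
    n_used = 0
    for onset in events.onsets:
        ok = True
        snap = {}
        for name, (ts, xs) in signals.items():
            ts = np.asarray(ts, dtype=float)
            if onset - config.summary_window < ts[0] - 1e-9 or (
                onset + config.summary_window > ts[-1] + 1e-9
            ):
                ok = False
                break
            snap[name] = np.interp(onset + t_rel, ts, np.asarray(xs, dtype=float))
        if not ok:
            continue
        n_used += 1
        for name, win in snap.items():
            if name in baseline_subtract:
                win = win - win[half]
            windows[name].append(win)
    if n_used == 0:
        raise ValueError("no event has a full ±window of data")
    mean, lo, hi = {}, {}, {}
    for name, wins in windows.items():
        arr = np.stack(wins)
        mean[name] = arr.mean(axis=0)
        if arr.shape[0] == 1 or config.n_bootstrap < 2:
            lo[name] = mean[name].copy()
            hi[name] = mean[name].copy()
        else:
            n = arr.shape[0]
            boots = np.empty((config.n_bootstrap, arr.shape[1]))
            for b in range(config.n_bootstrap):  # loop keeps memory bounded
                boots[b] = arr[rng.integers(0, n, size=n)].mean(axis=0)
            lo[name] = np.percentile(boots, 2.5, axis=0)
            hi[name] = np.percentile(boots, 97.5, axis=0)
    return EventTriggeredSummary(t_rel=t_rel, mean=mean, ci_lo=lo, ci_hi=hi, n_events=n_used)


def shuffled_control(
    signals: dict[str, tuple[np.ndarray, np.ndarray]],
    n_events: int,
    config: EventConfig | None = None,
    seed: int = 0,
) -> EventTriggeredSummary:
    """Summary over uniformly random surrogate event times (edge-respecting)."""
    if config is None:
        config = EventConfig()
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(seed)
    t0 = max(np.asarray(ts)[0] for ts, _ in signals.values())
    t1 = min(np.asarray(ts)[-1] for ts, _ in signals.values())
    lo = t0 + max(config.edge_exclusion, config.summary_window)
    hi = t1 - max(config.edge_exclusion, config.summary_window)
    if hi <= lo:
        raise ValueError("traces too short for shuffled control windows")
    onsets = np.sort(rng.uniform(lo, hi, size=n_events))
    onsets = onsets + np.arange(n_events) * 1e-9  # enforce strict ordering
    fake = EventSeries(onsets=onsets)
    return event_triggered_summary(fake, signals, config, rng=rng)


def select_exemplar_events(
    events: EventSeries,
    velocity: VelocityTrace,
    criterion: str,
) -> list[tuple[float, float]]:
    """Rank events by their behavioral signature; returns (onset, score).

    push_down: maximize mean v_forward in [0, +2 s] minus mean in [−1 s, 0]
    (bimodal push); backward: minimize mean v_forward up to +2 s; yaw_left /
    yaw_right: maximize the +2 s mean yaw, positive for left and negative for
    right. Events whose window leaves the trace are skipped with a warning.
    """
    if len(events) == 0:
        raise ValueError("no events to rank")
    scored = []
    t = velocity.t
    for onset in events.onsets:
        if onset - 1.0 < t[0] or onset + 2.0 > t[-1]:
            warnings.warn(f"event at {onset:.2f}s lacks a full ranking window; skipped")
            continue
        post = (t >= onset) & (t <= onset + 2.0)
        pre = (t >= onset - 1.0) & (t < onset)
        if criterion == "push_down":
            score = velocity.v_forward[post].mean() - velocity.v_forward[pre].mean()
        elif criterion == "backward":
            score = -velocity.v_forward[post].mean()
        elif criterion == "yaw_left":
            score = velocity.v_rotation[post].mean()
        elif criterion == "yaw_right":
            score = -velocity.v_rotation[post].mean()
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        scored.append((float(onset), float(score)))
    scored.sort(key=lambda e: e[1], reverse=True)
    return scored
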