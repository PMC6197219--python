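"""Event detection, bilateral reconciliation, and triggered summaries."""

import numpy as np
import pytest

from vnc2p.behavior import VelocityTrace
from vnc2p.events import (
    EventConfig,
    EventSeries,
    detect_events,
    event_triggered_summary,
    pool_derivative_threshold,
    reconcile_bilateral,
    select_exemplar_events,
    shuffled_control,
)
from vnc2p.synthetic import make_ratio_trace


class TestPooledThreshold:
    def test_constant_trace_zero(self):
        t = np.arange(100) * 0.1
        assert pool_derivative_threshold([(t, np.ones(100))], 97.5) == 0.0

    def test_linear_interpolation_convention(self):
        # pooled derivative values 1..100 at unit dt -> p90 = 90.1
        t = np.arange(101.0)
        x = np.concatenate([[0.0], np.cumsum(np.arange(1.0, 101.0))])
        assert pool_derivative_threshold([(t, x)], 90) == pytest.approx(90.1)

    def test_pooling_order_free(self):
        rng = np.random.default_rng(0)
        traces = [(np.arange(50.0), rng.normal(size=50)) for _ in range(3)]
        a = pool_derivative_threshold(traces, 97.5)
        b = pool_derivative_threshold(traces[::-1], 97.5)
        assert a == b

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_derivative_threshold([], 97.5)


class TestDetect:
    def test_monotone_decay_has_no_events(self):
        t = np.arange(0, 60, 0.125)
        x = 100 * np.exp(-t / 10)
        series = detect_events(t, x, threshold=1.0)
        assert len(series) == 0

    def test_single_transient_onset_located(self):
        # noiseless trace: an explicit threshold below the rise derivative
        t, x = make_ratio_trace([20.0], duration=60, noise_sd=0.0, seed=0)
        series = detect_events(t, x, threshold=10.0)
        assert len(series) == 1
        assert abs(series.onsets[0] - 20.0) <= 2 / 8.0 + 1e-9

    def test_edge_exclusion_drops_early_events(self):
        t, x = make_ratio_trace([5.0], duration=60, noise_sd=0.0, seed=0)
        series = detect_events(t, x, threshold=10.0)
        assert len(series) == 0

    def test_onset_precedes_crossing(self):
        t, x = make_ratio_trace([20.0, 35.0], duration=70, noise_sd=2.0, seed=1)
        thr = pool_derivative_threshold([(t, x)], 97.5)
        series = detect_events(t, x, thr)
        d = np.diff(x) / np.diff(t)
        for onset in series.onsets:
            i = int(np.searchsorted(t, onset))
            # some crossing at or after the onset, before the next zero dip ends
            assert np.any(d[i:i + 8] >= thr)

    def test_flat_trace_zero_threshold_empty_not_error(self):
        t = np.arange(0, 60, 0.125)
        series = detect_events(t, np.ones_like(t), threshold=0.0)
        assert len(series) == 0


class TestReconcile:
    def test_covarying_lone_event_copied(self):
        left, right = reconcile_bilateral(
            EventSeries(np.array([10.0])), EventSeries(np.array([])))
        np.testing.assert_array_equal(left.onsets, [10.0])
        np.testing.assert_array_equal(right.onsets, [10.0])
        assert right.source == ["copied_from_partner"]
        assert left.source == ["detected"]

    def test_covarying_pair_within_window_kept(self):
        left, right = reconcile_bilateral(
            EventSeries(np.array([10.0])), EventSeries(np.array([11.0])))
        np.testing.assert_array_equal(left.onsets, [10.0])
        np.testing.assert_array_equal(right.onsets, [11.0])
        assert left.source == ["detected"] and right.source == ["detected"]

    def test_independent_close_pair_vetoed(self):
        cfg = EventConfig(covarying_pair=False)
        left, right = reconcile_bilateral(
            EventSeries(np.array([10.0])), EventSeries(np.array([10.1])), cfg)
        assert len(left) == 0 and len(right) == 0
        assert left.vetoed == [(10.0, 10.1)]

    def test_covarying_never_deletes_independent_never_creates(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            l = EventSeries(np.sort(rng.uniform(0, 100, rng.integers(1, 8))))
            r = EventSeries(np.sort(rng.uniform(0, 100, rng.integers(1, 8))))
            cl, cr = reconcile_bilateral(l, r, EventConfig(covarying_pair=True))
            assert set(np.round(l.onsets, 9)) <= set(np.round(cl.onsets, 9))
            assert set(np.round(r.onsets, 9)) <= set(np.round(cr.onsets, 9))
            il, ir = reconcile_bilateral(l, r, EventConfig(covarying_pair=False))
            assert set(np.round(il.onsets, 9)) <= set(np.round(l.onsets, 9))
            assert set(np.round(ir.onsets, 9)) <= set(np.round(r.onsets, 9))

    def test_copy_respects_edge_exclusion(self):
        left, right = reconcile_bilateral(
            EventSeries(np.array([5.0])), EventSeries(np.array([])),
            t_range=(0.0, 60.0))
        assert len(right) == 0  # copy would land in the partner's edge zone


def periodic_signals(duration=300.0, rate=100.0):
    t = np.arange(0, duration, 1 / rate)
    return t, np.sin(2 * np.pi * t / 7.0)


@pytest.fixture(scope="module")
def event_locked():
    rate = 100.0
    t = np.arange(0, 120, 1 / rate)
    x = np.zeros_like(t)
    vf = np.zeros_like(t)
    onsets = np.array([20.0, 40.0, 60.0, 80.0, 100.0])
    for o in onsets:
        seg = (t >= o) & (t < o + 3)
        x[seg] += 50 * np.exp(-(t[seg] - o) / 1.65)
        vf[(t >= o + 0.2) & (t < o + 1.5)] -= 5.0
    return t, x, vf, EventSeries(onsets)


class TestSummary:
    def test_dRR_exactly_zero_at_event_time(self, event_locked):
        t, x, vf, events = event_locked
        cfg = EventConfig(n_bootstrap=200, summary_rate=50.0)
        summ = event_triggered_summary(events, {"percent_dRR": (t, x)}, cfg)
        assert summ.mean["percent_dRR"][len(summ.t_rel) // 2] == 0.0

    def test_backward_walking_signature(self, event_locked):
        t, x, vf, events = event_locked
        cfg = EventConfig(n_bootstrap=100, summary_rate=50.0)
        summ = event_triggered_summary(
            events, {"percent_dRR": (t, x), "v_forward": (t, vf)}, cfg)
        post = (summ.t_rel > 0.2) & (summ.t_rel < 1.5)
        pre = summ.t_rel < 0
        assert summ.mean["v_forward"][post].mean() < -4.0
        assert abs(summ.mean["v_forward"][pre].mean()) < 0.1
        assert summ.n_events == 5

    def test_ci_contains_mean(self, event_locked):
        t, x, vf, events = event_locked
        cfg = EventConfig(n_bootstrap=200, summary_rate=50.0)
        summ = event_triggered_summary(events, {"v_forward": (t, vf)}, cfg)
        eps = 1e-12
        assert (summ.ci_lo["v_forward"] <= summ.mean["v_forward"] + eps).all()
        assert (summ.ci_hi["v_forward"] >= summ.mean["v_forward"] - eps).all()

    def test_single_event_degenerate_ci(self):
        t = np.arange(0, 60, 0.01)
        x = np.sin(t)
        summ = event_triggered_summary(
            EventSeries(np.array([30.0])), {"v": (t, x)},
            EventConfig(n_bootstrap=100, summary_rate=50.0))
        np.testing.assert_array_equal(summ.ci_lo["v"], summ.mean["v"])
        np.testing.assert_array_equal(summ.ci_hi["v"], summ.mean["v"])

    def test_constant_signal_zero_width_ci(self):
        t = np.arange(0, 100, 0.01)
        summ = event_triggered_summary(
            EventSeries(np.array([30.0, 50.0, 70.0])), {"v": (t, np.full_like(t, 2.0))},
            EventConfig(n_bootstrap=100, summary_rate=50.0))
        np.testing.assert_allclose(summ.mean["v"], 2.0)
        np.testing.assert_allclose(summ.ci_hi["v"] - summ.ci_lo["v"], 0.0, atol=1e-12)

    def test_no_full_window_rejected(self):
        t = np.arange(0, 15, 0.01)
        with pytest.raises(ValueError):
            event_triggered_summary(EventSeries(np.array([2.0])),
                                    {"v": (t, np.zeros_like(t))})

    def test_ci_width_shrinks_with_event_count(self):
        # bootstrap CI narrows roughly as 1/sqrt(n): compare n=10 vs n=40
        rng = np.random.default_rng(8)
        rate = 50.0
        t = np.arange(0, 1200, 1 / rate)
        x = rng.normal(0, 1.0, len(t))
        cfg = EventConfig(n_bootstrap=300, summary_rate=25.0)
        widths = {}
        for n in (10, 40):
            onsets = np.linspace(30, 1170, n)
            summ = event_triggered_summary(EventSeries(onsets), {"v": (t, x)}, cfg,
                                           rng=np.random.default_rng(0))
            widths[n] = (summ.ci_hi["v"] - summ.ci_lo["v"]).mean()
        ratio = widths[40] / widths[10]
        assert 0.3 < ratio < 0.8  # ideal 0.5


class TestShuffled:
    def test_deterministic_under_seed(self):
        t, x = periodic_signals()
        cfg = EventConfig(n_bootstrap=50, summary_rate=25.0)
        a = shuffled_control({"v": (t, x)}, 30, cfg, seed=5)
        b = shuffled_control({"v": (t, x)}, 30, cfg, seed=5)
        np.testing.assert_array_equal(a.mean["v"], b.mean["v"])

    def test_flat_on_periodic_signal(self):
        t, x = periodic_signals(duration=600.0)
        cfg = EventConfig(n_bootstrap=100, summary_rate=25.0)
        summ = shuffled_control({"v": (t, x)}, 500, cfg, seed=3)
        assert np.abs(summ.mean["v"]).max() < 0.1  # < 10% of unit amplitude

    def test_zero_events_rejected(self):
        t, x = periodic_signals()
        with pytest.raises(ValueError):
            shuffled_control({"v": (t, x)}, 0)


class TestExemplars:
    def make_velocity(self):
        t = np.arange(0, 100, 0.02)
        vf = np.zeros_like(t)
        vrot = np.zeros_like(t)
        vf[(t >= 20) & (t < 22)] = -3.0   # shallow backward episode
        vf[(t >= 50) & (t < 52)] = -8.0   # deep backward episode
        vrot[(t >= 70) & (t < 72)] = 40.0
        vrot[(t >= 80) & (t < 82)] = -40.0
        return VelocityTrace(t, vf, np.zeros_like(t), vrot)

    def test_deeper_backward_ranked_first(self):
        vel = self.make_velocity()
        ranked = select_exemplar_events(
            EventSeries(np.array([20.0, 50.0])), vel, "backward")
        assert ranked[0][0] == 50.0

    def test_yaw_criteria_are_sign_symmetric(self):
        vel = self.make_velocity()
        events = EventSeries(np.array([70.0, 80.0]))
        left = select_exemplar_events(events, vel, "yaw_left")
        right = select_exemplar_events(events, vel, "yaw_right")
        assert left[0][0] == 70.0 and right[0][0] == 80.0

    def test_push_down_prefers_forward_surge(self):
        t = np.arange(0, 60, 0.02)
        vf = np.zeros_like(t)
        vf[(t >= 30) & (t < 32)] = 6.0
        vel = VelocityTrace(t, vf, np.zeros_like(t), np.zeros_like(t))
        ranked = select_exemplar_events(
            EventSeries(np.array([20.0, 30.0])), vel, "push_down")
        assert ranked[0][0] == 30.0

    def test_single_event_top_ranked(self):
        vel = self.make_velocity()
        ranked = select_exemplar_events(EventSeries(np.array([50.0])), vel, "backward")
        assert len(ranked) == 1 and ranked[0][0] == 50.0

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            select_exemplar_events(EventSeries(np.array([])), self.make_velocity(),
                                   "backward")
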