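"""Detector behaviour on constructed signals, plus batch/stream equivalence."""

import numpy as np
import pytest

from accelfall import (
    BasicParams,
    FallIndexParams,
    IFallParams,
    InvalidInputError,
    OrientationSeries,
    PerFallDParams,
    detect_basic,
    detect_fall_index,
    detect_ifall,
    detect_perfalld,
    make_stream,
    run_detector,
    stream_detect,
    stream_push,
)

from conftest import flat_orientation, make_accel

FS = 50.0


def spike_signal(duration=10.0, spikes=(), base=1.0, fs=FS):
    """1 g along -z with single-sample magnitude spikes at given (time, value)."""
    n = int(round(duration * fs))
    az = np.full(n, -base)
    for t, v in spikes:
        az[int(round(t * fs))] = -v
    return make_accel(np.zeros(n), np.zeros(n), az, fs=fs)


def assert_stream_matches(algo, accel, orient, params, events):
    streamed = stream_detect(algo, accel, orient, params)
    assert [(e.t_trigger, e.t_confirm, e.algorithm) for e in streamed] == [
        (e.t_trigger, e.t_confirm, e.algorithm) for e in events
    ]
    np.testing.assert_allclose(
        [e.score for e in streamed], [e.score for e in events], rtol=1e-9
    )


# ---------------------------------------------------------------------------
# basic
# ---------------------------------------------------------------------------

class TestBasic:
    def test_quiet_gives_nothing(self):
        assert detect_basic(spike_signal(), BasicParams()) == []

    def test_single_spike_gives_one_event(self):
        acc = spike_signal(spikes=[(3.0, 4.0)])
        events = detect_basic(acc, BasicParams(threshold=3.5))
        assert len(events) == 1
        ev = events[0]
        assert ev.t_trigger == pytest.approx(3.0)
        assert ev.t_confirm == ev.t_trigger
        assert ev.score == pytest.approx(4.0)
        assert_stream_matches("basic", acc, None, BasicParams(threshold=3.5), events)

    @pytest.mark.parametrize("gap,n_expected", [(0.5, 1), (3.0, 2)])
    def test_refractory_merging(self, gap, n_expected):
        acc = spike_signal(spikes=[(3.0, 4.0), (3.0 + gap, 4.0)])
        params = BasicParams(threshold=3.5, refractory=2.0)
        events = detect_basic(acc, params)
        assert len(events) == n_expected
        assert_stream_matches("basic", acc, None, params, events)

    def test_threshold_monotonicity_on_separated_spikes(self, rng):
        """Raising the threshold never increases the event count.

        Holds as a level-set argument for excursions separated by more than
        the refractory period (a spike train); dense overlapping noise can
        merge or split excursions either way.
        """
        times = np.arange(20) * 5.0 + 2.0  # spikes 5 s apart, refractory 2 s
        amps = rng.uniform(1.5, 6.0, 20)
        acc = spike_signal(duration=110.0, spikes=list(zip(times, amps)))
        counts = [
            len(detect_basic(acc, BasicParams(threshold=th)))
            for th in [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0]
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 20 and counts[-1] < 20

    def test_event_times_within_span_scores_positive(self, rng):
        n = 2000
        acc = make_accel(
            rng.normal(0, 1, n), rng.normal(0, 1, n), -1 + rng.normal(0, 1, n)
        )
        for ev in detect_basic(acc, BasicParams(threshold=2.0)):
            assert 0.0 <= ev.t_trigger <= acc.duration
            assert np.isfinite(ev.score) and ev.score > 0


# ---------------------------------------------------------------------------
# fall index
# ---------------------------------------------------------------------------

class TestFallIndex:
    def test_constant_gives_nothing(self):
        assert detect_fall_index(spike_signal(), FallIndexParams(threshold=2.0)) == []

    def test_sharp_jump_detected(self):
        """A 3 g consecutive-sample jump yields FI >= 3 and one event."""
        ax = np.zeros(300)
        ax[150:] = 3.0
        acc = make_accel(ax, np.zeros(300), np.full(300, -1.0))
        events = detect_fall_index(acc, FallIndexParams(threshold=2.0))
        assert len(events) == 1
        assert events[0].score >= 3.0
        assert_stream_matches("fall_index", acc, None, FallIndexParams(threshold=2.0), events)

    def test_slow_drift_ignored(self):
        """Per-sample steps of 1e-3 g keep FI below sqrt(20) * 1e-3."""
        ax = np.cumsum(np.full(2000, 1e-3))
        acc = make_accel(ax, np.zeros(2000), np.full(2000, -1.0))
        assert detect_fall_index(acc, FallIndexParams(threshold=2.0)) == []

    def test_magnitude_gated_mode(self):
        params = FallIndexParams(threshold=3.5, mode="magnitude_gated", fi_gate=1.0)
        # a 4 g spike is both a large magnitude and a large FI step: detected
        acc = spike_signal(spikes=[(3.0, 4.0)])
        assert len(detect_fall_index(acc, params)) == 1
        # a slow sustained 4 g level with no sharp step fails the FI gate
        az = np.concatenate([np.full(100, -1.0), -np.linspace(1, 4, 400), np.full(100, -4.0)])
        acc2 = make_accel(np.zeros(600), np.zeros(600), az)
        assert detect_fall_index(acc2, params) == []


# ---------------------------------------------------------------------------
# perfalld: constructed signals satisfying / violating each clause
# ---------------------------------------------------------------------------

PF = PerFallDParams(
    th_tt=1.0, th_ct=0.3, th_tv=0.5, th_cv=0.3,
    win_tt=1.0, win_ct=1.0, win_tv=1.0, win_cv=1.0,
)


def pf_signal(n=500, fs=FS):
    """Quiet upright base: mag = |A_v| = 1 at zero angles."""
    az = np.full(n, -1.0)
    return np.zeros(n), np.zeros(n), az


class TestPerFallD:
    def test_constant_gives_nothing(self):
        acc = spike_signal()
        assert detect_perfalld(acc, flat_orientation(acc.n), PF) == []

    def test_impact_then_stillness_confirms_one_event(self):
        """Both channels trigger at the spike; quiet checks confirm one window later."""
        ax, ay, az = pf_signal()
        az[100] = -3.0  # single-sample impact moves both |A_T| and |A_v|
        acc = make_accel(ax, ay, az)
        events = detect_perfalld(acc, flat_orientation(acc.n), PF)
        assert len(events) == 1
        ev = events[0]
        assert ev.t_trigger == pytest.approx(2.0)
        assert ev.t_confirm == pytest.approx(2.0 + PF.win_ct)
        assert_stream_matches("perfalld", acc, flat_orientation(acc.n), PF, events)

    def test_noisy_checking_window_rejects(self):
        """Sustained oscillation keeps every checking window dirty: no event."""
        ax, ay, az = pf_signal()
        az[100] = -3.0
        az[101:] = -1.0 + 0.4 * np.sin(np.arange(399) * 1.1)  # range > th_ct forever
        acc = make_accel(ax, ay, az)
        orient = flat_orientation(acc.n)
        assert detect_perfalld(acc, orient, PF) == []
        assert stream_detect("perfalld", acc, orient, PF) == []

    def test_total_only_trigger_expires(self):
        """An x-axis spike moves |A_T| but not |A_v| (zero angles): no event."""
        ax, ay, az = pf_signal()
        ax[100] = 3.0
        acc = make_accel(ax, ay, az)
        orient = flat_orientation(acc.n)
        assert detect_perfalld(acc, orient, PF) == []
        assert stream_detect("perfalld", acc, orient, PF) == []

    def test_late_second_trigger_within_deadline_confirms(self):
        """Vertical triggers first; total follows inside the checking deadline."""
        n = 500
        ax, ay = np.zeros(n), np.zeros(n)
        az = np.full(n, -1.0)
        # pitch = 90 deg: |A_v| = |ay|, decoupled from the x/z components
        orient = flat_orientation(n, pitch=np.pi / 2)
        ay[100] = 0.6  # |A_v| range 0.6 > th_tv; |A_T| range ~0.17 < th_tt
        ax[115] = 3.0  # 0.3 s later: |A_T| range > th_tt; |A_v| unchanged
        acc = make_accel(ax, ay, az)
        events = detect_perfalld(acc, orient, PF)
        assert len(events) == 1
        assert events[0].t_trigger == pytest.approx(115 / FS)
        assert events[0].t_confirm == pytest.approx(115 / FS + PF.win_ct)
        assert_stream_matches("perfalld", acc, orient, PF, events)

    def test_vertical_check_failure_rejects(self):
        """Both trigger, total check clean, but |A_v| keeps moving: no event."""
        n = 500
        ax, ay = np.zeros(n), np.zeros(n)
        az = np.full(n, -1.0)
        orient = flat_orientation(n, pitch=np.pi / 2)
        ay[100] = 0.6
        ax[100] = 3.0
        ay[110:] = 0.35 * np.sin(np.arange(n - 110) * 0.9)  # |A_v| range > th_cv
        acc = make_accel(ax, ay, az)
        assert detect_perfalld(acc, orient, PF) == []

    def test_serialisation_blocks_overlapping_candidates(self):
        """A second impact during a pending (failing) check opens no new candidate."""
        ax, ay, az = pf_signal()
        az[100] = -3.0
        az[120] = -3.0  # inside the first candidate's checking window
        az[101:200] = -1.0 + 0.4 * np.sin(np.arange(99))  # first check dirty
        acc = make_accel(ax, ay, az)
        orient = flat_orientation(acc.n)
        events = detect_perfalld(acc, orient, PF)
        # the only event may come from a retrigger after the oscillation stops,
        # never from the blocked second impact
        for ev in events:
            assert ev.t_trigger >= 200 / FS
        assert_stream_matches("perfalld", acc, orient, PF, events)


# ---------------------------------------------------------------------------
# ifall: constructed signals for every clause
# ---------------------------------------------------------------------------

IF = IFallParams(lower=1.0, upper=3.5, crossing_window=1.0, postfall_window=2.0)


def ifall_scenario(
    n=500,
    dip_at=None,
    impact_at=None,
    lie_from=None,
    lie_until=None,
    fs=FS,
):
    """Upright 1 g base with optional dip/impact samples and a lying episode."""
    ax, ay = np.zeros(n), np.zeros(n)
    az = np.full(n, -1.0)
    pitch, roll = np.zeros(n), np.zeros(n)
    if dip_at is not None:
        az[int(dip_at * fs)] = -0.3
    if impact_at is not None:
        az[int(impact_at * fs)] = -4.0
    if lie_from is not None:
        end = int(lie_until * fs) if lie_until is not None else n
        roll[int(lie_from * fs) : end] = np.pi / 2  # tilt 90 deg from upright
    return make_accel(ax, ay, az, fs=fs), OrientationSeries(pitch=pitch, roll=roll)


class TestIFall:
    def test_constant_upright_gives_nothing(self):
        acc, orient = ifall_scenario()
        assert detect_ifall(acc, orient, IF) == []

    def test_dip_impact_lying_confirms(self):
        acc, orient = ifall_scenario(dip_at=3.0, impact_at=3.3, lie_from=3.5)
        events = detect_ifall(acc, orient, IF)
        assert len(events) == 1
        ev = events[0]
        assert ev.t_trigger == pytest.approx(3.3)
        assert ev.t_confirm == pytest.approx(3.3 + IF.postfall_window)
        assert ev.score == pytest.approx(4.0)
        assert_stream_matches("ifall", acc, orient, IF, events)

    def test_upright_recovery_suppresses(self):
        """Posture returns upright mid-window: the candidate is discarded."""
        acc, orient = ifall_scenario(dip_at=3.0, impact_at=3.3, lie_from=3.5, lie_until=4.3)
        assert detect_ifall(acc, orient, IF) == []
        assert stream_detect("ifall", acc, orient, IF) == []

    def test_impact_without_prior_dip_ignored(self):
        acc, orient = ifall_scenario(impact_at=3.3, lie_from=3.5)
        assert detect_ifall(acc, orient, IF) == []

    def test_dip_without_impact_ignored(self):
        acc, orient = ifall_scenario(dip_at=3.0, lie_from=3.5)
        assert detect_ifall(acc, orient, IF) == []

    def test_crossings_outside_window_ignored(self):
        """Dip and impact 1.5 s apart exceed the 1 s crossing window."""
        acc, orient = ifall_scenario(dip_at=3.0, impact_at=4.5, lie_from=4.6)
        assert detect_ifall(acc, orient, IF) == []

    def test_never_lying_suppresses(self):
        acc, orient = ifall_scenario(dip_at=3.0, impact_at=3.3)
        assert detect_ifall(acc, orient, IF) == []
        assert stream_detect("ifall", acc, orient, IF) == []

    def test_truncated_postfall_window_yields_nothing(self):
        """Data ending mid-observation leaves the candidate unresolved."""
        acc, orient = ifall_scenario(n=200, dip_at=3.0, impact_at=3.3, lie_from=3.5)
        assert detect_ifall(acc, orient, IF) == []
        assert stream_detect("ifall", acc, orient, IF) == []


# ---------------------------------------------------------------------------
# streaming interface contracts
# ---------------------------------------------------------------------------

class TestStreaming:
    def test_empty_stream_emits_nothing(self):
        state = make_stream("basic", BasicParams(), FS)
        assert state.finish() == []

    def test_out_of_order_timestamp_rejected(self):
        state = make_stream("basic", BasicParams(), FS)
        stream_push(state, (0.0, 0, 0, -1))
        stream_push(state, (0.02, 0, 0, -1))
        with pytest.raises(InvalidInputError):
            stream_push(state, (0.01, 0, 0, -1))

    def test_push_returns_event_exactly_once(self):
        acc = spike_signal(spikes=[(3.0, 4.0)])
        state = make_stream("basic", BasicParams(threshold=3.5), FS)
        emitted = []
        for t, x, y, z in zip(acc.times, acc.ax, acc.ay, acc.az):
            ev = stream_push(state, (t, x, y, z))
            if ev is not None:
                emitted.append(ev)
        emitted.extend(state.finish())
        assert len(emitted) == 1
        assert emitted[0].t_trigger == pytest.approx(3.0)

    def test_unknown_algorithm_rejected(self):
        from accelfall import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            make_stream("nope", BasicParams(), FS)
        with pytest.raises(InvalidParameterError):
            run_detector("nope", spike_signal(), None, BasicParams())
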