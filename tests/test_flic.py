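"""FLIC contact-event detection: I/O, baseline, segmentation, validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flysip import (
    DetectionParams,
    FeedingEvent,
    FlicTrace,
    FormatError,
    GroundTruth,
    ParameterError,
    detect_events,
    estimate_baseline,
    read_flic_csv,
    summarize,
    validate,
)
from flysip.flic import write_flic_csv

FS = 5.0


def make_trace(signal, fs=FS, well="W1"):
    signal = np.asarray(signal, dtype=float)
    return FlicTrace(well_id=well, time_s=np.arange(signal.size) / fs, signal=signal)


def pulse_trace(pulses, duration_s=60.0, fs=FS, amplitude=100.0, baseline=0.0):
    """Square pulses of `amplitude` on a constant baseline; pulses = [(start, end)]."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sig = np.full(n, baseline)
    for s, e in pulses:
        sig[(t >= s) & (t < e)] += amplitude
    return FlicTrace(well_id="W1", time_s=t, signal=sig)


def brute_force_events(trace, threshold, merge_gap_s, min_event_duration_s):
    """Naive reference scanner: supra-threshold runs, merge, min-duration filter.

    Independent of the vectorized implementation; assumes a zero baseline.
    """
    dt = float(np.median(np.diff(trace.time_s)))
    runs = []
    cur = None
    for ti, si in zip(trace.time_s, trace.signal):
        if si > threshold:
            if cur is None:
                cur = [ti, ti + dt, si]
            else:
                cur[1] = ti + dt
                cur[2] = max(cur[2], si)
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
    if cur is not None:
        runs.append(cur)
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < merge_gap_s:
            merged[-1][1] = r[1]
            merged[-1][2] = max(merged[-1][2], r[2])
        else:
            merged.append(r)
    return [tuple(r) for r in merged if r[1] - r[0] >= min_event_duration_s]


# ---------------------------------------------------------------------------
# I/O


class TestReadFlicCsv:
    def test_minimal_two_column_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,W1\n" + "\n".join(f"{i * 0.2},{i}" for i in range(10)))
        traces = read_flic_csv(p)
        assert len(traces) == 1 and len(traces[0]) == 10

    def test_twelve_well_file_shares_time_axis(self, tmp_path):
        p = tmp_path / "t.csv"
        header = "time_s," + ",".join(f"W{i}" for i in range(1, 13))
        rows = [f"{i * 0.2}," + ",".join("0" for _ in range(12)) for i in range(5)]
        p.write_text(header + "\n" + "\n".join(rows))
        traces = read_flic_csv(p)
        assert len(traces) == 12
        for tr in traces:
            assert np.array_equal(tr.time_s, traces[0].time_s)

    def test_decreasing_time_cites_row(self, tmp_path):
        p = tmp_path / "t.csv"
        times = [0.0, 0.2, 0.4, 0.6, 0.3, 0.8]
        p.write_text("time_s,W1\n" + "\n".join(f"{t},0" for t in times))
        with pytest.raises(FormatError, match="row 5"):
            read_flic_csv(p)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,W1\n0.0,1\n0.2,oops\n")
        with pytest.raises(FormatError, match="W1"):
            read_flic_csv(p)

    def test_round_trip_with_seed_comment(self, tmp_path):
        tr = pulse_trace([(2.0, 3.0)])
        p = tmp_path / "t.csv"
        write_flic_csv(p, [tr], seed=7)
        assert p.read_text().startswith("# seed=7")
        back = read_flic_csv(p)[0]
        assert np.allclose(back.signal, tr.signal)


# ---------------------------------------------------------------------------
# baseline


class TestEstimateBaseline:
    def test_constant_signal(self):
        tr = make_trace(np.full(600, 42.0))
        base = estimate_baseline(tr, DetectionParams(baseline_window_s=10.0))
        assert np.allclose(base, 42.0)

    def test_slow_ramp_tracked_away_from_edges(self):
        n = int(900 * FS)
        t = np.arange(n) / FS
        ramp = 10.0 * t / 900.0
        tr = make_trace(ramp)
        base = estimate_baseline(tr, DetectionParams(baseline_window_s=120.0))
        interior = slice(int(60 * FS), n - int(60 * FS))
        assert np.max(np.abs(base[interior] - ramp[interior])) < 1.0

    def test_median_ignores_brief_pulse(self):
        tr = pulse_trace([(450.0, 451.0)], duration_s=900.0)
        base = estimate_baseline(tr, DetectionParams(baseline_window_s=120.0))
        at_pulse = (tr.time_s >= 450.0) & (tr.time_s < 451.0)
        assert np.max(np.abs(base[at_pulse])) < 0.5

    def test_window_longer_than_trace_rejected(self):
        tr = make_trace(np.zeros(50))
        with pytest.raises(ParameterError):
            estimate_baseline(tr, DetectionParams(baseline_window_s=100.0))


# ---------------------------------------------------------------------------
# detection


class TestDetectEvents:
    def test_flat_trace_yields_nothing(self):
        assert detect_events(make_trace(np.zeros(600))) == []

    def test_single_pulse_boundaries_and_peak(self):
        tr = pulse_trace([(2.0, 3.0)], duration_s=60.0)
        params = DetectionParams(
            baseline_window_s=10.0, threshold=20.0, threshold_mads=None,
            min_event_duration_s=0.4,
        )
        events = detect_events(tr, params)
        assert len(events) == 1
        ev = events[0]
        dt = 1.0 / FS
        assert abs(ev.start_s - 2.0) <= dt
        assert abs(ev.end_s - 3.0) <= dt
        assert ev.peak_amplitude == pytest.approx(100.0)

    @given(
        st.dictionaries(
            keys=st.sampled_from([5.0, 15.0, 25.0, 35.0, 45.0]),
            values=st.floats(min_value=0.2, max_value=3.0),
            max_size=5,
        ),
        st.floats(min_value=5.0, max_value=90.0),
    )
    def test_oracle_equivalence_on_noiseless_pulses(self, pulses, threshold):
        """Segmentation matches a naive supra-threshold run scanner exactly.

        Pulses are kept sparse so the running median stays at the true
        zero baseline and both code paths see identical residuals.
        """
        intervals = [(s, s + d) for s, d in pulses.items()]
        tr = pulse_trace(intervals, duration_s=60.0)
        params = DetectionParams(
            baseline_window_s=10.0, threshold=threshold, threshold_mads=None,
        )
        got = np.array(
            [(e.start_s, e.end_s, e.peak_amplitude) for e in detect_events(tr, params)]
        )
        expected = np.array(
            brute_force_events(tr, threshold, params.merge_gap_s, params.min_event_duration_s)
        )
        assert got.shape == expected.shape
        assert np.allclose(got, expected)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        """Raising the threshold never increases the event count on pulse traces."""
        rng = np.random.default_rng(seed)
        starts = np.array([5.0, 15.0, 25.0, 35.0, 45.0]) + rng.uniform(0, 5, 5)
        intervals = [(s, s + d) for s, d in zip(starts, rng.uniform(0.5, 3, 5))]
        tr = pulse_trace(intervals, duration_s=60.0)
        counts = []
        for thr in (10.0, 40.0, 80.0, 120.0):
            params = DetectionParams(baseline_window_s=10.0, threshold=thr, threshold_mads=None)
            counts.append(len(detect_events(tr, params)))
        assert counts == sorted(counts, reverse=True)

    def test_lowering_min_duration_never_loses_events(self, rng):
        from flysip.simulate import FlicSimConfig, gen_flic_trace

        tr, _ = gen_flic_trace(FlicSimConfig(duration_s=300.0, seed=99))
        prev = -1
        for min_dur in (2.0, 1.0, 0.4, 0.2):
            params = DetectionParams(min_event_duration_s=min_dur)
            n = len(detect_events(tr, params))
            assert n >= prev
            prev = n

    def test_time_shift_invariance(self):
        from flysip.simulate import FlicSimConfig, gen_flic_trace

        tr, _ = gen_flic_trace(FlicSimConfig(duration_s=300.0, seed=7))
        shifted = FlicTrace(well_id=tr.well_id, time_s=tr.time_s + 7.3, signal=tr.signal)
        ev0 = detect_events(tr)
        ev1 = detect_events(shifted)
        assert len(ev0) == len(ev1)
        for a, b in zip(ev0, ev1):
            assert b.start_s == pytest.approx(a.start_s + 7.3)
            assert b.end_s == pytest.approx(a.end_s + 7.3)


# ---------------------------------------------------------------------------
# summaries


class TestSummarize:
    def test_empty(self):
        s = summarize([], (0.0, 900.0))
        assert (s.n_contacts, s.total_contact_time_s, s.mean_contact_duration_s) == (0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        events = [
            FeedingEvent(0.0, 1.0, 50.0),
            FeedingEvent(10.0, 12.0, 50.0),
            FeedingEvent(20.0, 23.0, 50.0),
        ]
        s = summarize(events, (0.0, 900.0))
        assert s.n_contacts == 3
        assert s.total_contact_time_s == pytest.approx(6.0)
        assert s.mean_contact_duration_s == pytest.approx(2.0)

    def test_clipping_at_window_edge(self):
        s = summarize([FeedingEvent(899.0, 905.0, 50.0)], (0.0, 900.0))
        assert s.total_contact_time_s == pytest.approx(1.0)

    def test_total_equals_sum_of_clipped_durations(self, rng):
        events = sorted(
            (FeedingEvent(s, s + d, 50.0) for s, d in
             zip(rng.uniform(0, 890, 40), rng.uniform(0.5, 20, 40))),
            key=lambda e: e.start_s,
        )
        window = (100.0, 700.0)
        s = summarize(events, window)
        expect = sum(
            max(0.0, min(e.end_s, window[1]) - max(e.start_s, window[0])) for e in events
        )
        assert s.total_contact_time_s == pytest.approx(expect)

    def test_inverted_window_rejected(self):
        with pytest.raises(ParameterError):
            summarize([], (10.0, 5.0))


# ---------------------------------------------------------------------------
# validation


class TestValidate:
    def test_identity(self):
        events = [FeedingEvent(1.0, 2.0, 50.0), FeedingEvent(5.0, 6.0, 50.0)]
        rep = validate(events, GroundTruth(np.array([[1.0, 2.0], [5.0, 6.0]])))
        assert rep.detection_rate == 1.0 and rep.false_positive_rate == 0.0

    def test_hand_matched_example(self):
        truth = GroundTruth(np.array([[1.0, 2.0], [5.0, 6.0]]))
        detected = [FeedingEvent(1.05, 2.1, 50.0), FeedingEvent(10.0, 11.0, 50.0)]
        rep = validate(detected, truth, tol=0.5)
        assert rep.n_matched == 1
        assert rep.detection_rate == pytest.approx(0.5)
        assert rep.false_positive_rate == pytest.approx(0.5)

    def test_nothing_detected_is_zero_fp_by_convention(self):
        rep = validate([], GroundTruth(np.array([[1.0, 2.0]])))
        assert rep.detection_rate == 0.0 and rep.false_positive_rate == 0.0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ParameterError):
            validate([], GroundTruth(np.empty((0, 2))), tol=-1.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_report_invariants(self, seed):
        rng = np.random.default_rng(seed)
        truth = GroundTruth(
            np.sort(rng.uniform(0, 100, (rng.integers(0, 10), 2)), axis=1) + [[0.0, 0.1]]
        )
        det = [
            FeedingEvent(s, s + d, 1.0)
            for s, d in zip(np.sort(rng.uniform(0, 100, 8)), rng.uniform(0.1, 5, 8))
        ]
        rep = validate(det, truth, tol=0.5)
        assert rep.n_matched <= min(rep.n_true, rep.n_detected)
        assert 0.0 <= rep.detection_rate <= 1.0
        assert 0.0 <= rep.false_positive_rate <= 1.0
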