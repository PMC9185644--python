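"""Bilateral fusion, spike filtering, event extraction and timing scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import propgest as pg
from propgest import schema
from propgest.fusion import (
    FusedTimeline,
    MIN_EVENT_MS,
    PredictionStream,
    despike,
    extract_events,
    fuse,
    fuse_streams,
    labeling_latency_ms,
    overall_accuracy,
)
from propgest.io import GestureAnnotation


class TestFuse:
    @pytest.mark.parametrize(
        "left,right,gid,name",
        [
            ("forward", "dance", 1, "left-forward"),
            ("backward", "dance", 2, "left-backward"),
            ("dance", "forward", 3, "right-forward"),
            ("dance", "backward", 4, "right-backward"),
            ("forward", "forward", 5, "forward"),
            ("backward", "backward", 6, "backward"),
            ("forward", "backward", 7, "clockwise"),
            ("backward", "forward", 8, "anticlockwise"),
            ("dance", "dance", 9, "dance"),
        ],
    )
    def test_all_nine_combinations(self, left, right, gid, name):
        assert fuse(left, right) == (gid, name)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            fuse("forward", "sideways")

    def test_table_is_total(self):
        pairs = {(l, r) for l in schema.SIDE_LABELS for r in schema.SIDE_LABELS}
        assert set(pg.FUSION_TABLE) == pairs


def _tl(*segments):
    return FusedTimeline(list(segments))


class TestDespike:
    def test_short_blip_inside_dance_removed(self):
        tl = _tl(("dance", 0, 1000), ("clockwise", 1000, 1033), ("dance", 1033, 2000))
        out = despike(tl)
        assert out.segments == [("dance", 0, 2000)]

    def test_segment_at_or_above_threshold_kept(self):
        tl = _tl(("dance", 0, 1000), ("forward", 1000, 1066), ("dance", 1066, 2000))
        assert ("forward", 1000, 1066) in despike(tl).segments

    def test_idempotent(self):
        tl = _tl(
            ("dance", 0, 500), ("forward", 500, 533), ("backward", 533, 1400),
            ("dance", 1400, 1433), ("left-forward", 1433, 1466), ("dance", 1466, 3000),
        )
        once = despike(tl)
        assert despike(once).segments == once.segments

    def test_never_increases_non_dance_segments_or_invents_labels(self):
        tl = _tl(
            ("forward", 0, 40), ("dance", 40, 600), ("backward", 600, 1800),
            ("clockwise", 1800, 1830), ("dance", 1830, 2000),
        )
        out = despike(tl)
        before = [s for s in tl.segments if s[0] != "dance"]
        after = [s for s in out.segments if s[0] != "dance"]
        assert len(after) <= len(before)
        assert {s[0] for s in out.segments} <= {s[0] for s in tl.segments} | {"dance"}

    def test_no_short_non_dance_segment_survives(self):
        tl = _tl(*[("forward" if i % 2 else "dance", i * 33, (i + 1) * 33) for i in range(40)])
        for name, a, b in despike(tl).segments:
            if name != "dance":
                assert b - a >= MIN_EVENT_MS


class TestExtractEvents:
    def test_one_event_per_propulsion_segment(self):
        tl = _tl(
            ("dance", 0, 1000), ("forward", 1000, 2000), ("dance", 2000, 3000),
            ("left-backward", 3000, 3800), ("dance", 3800, 5000),
        )
        events = extract_events(tl)
        assert [(e.gesture_id, e.onset_ms, e.duration_ms) for e in events] == [
            (5, 1000, 1000), (2, 3000, 800),
        ]

    def test_all_dance_yields_no_events(self):
        assert extract_events(_tl(("dance", 0, 5000))) == []

    def test_events_disjoint_and_ordered(self):
        tl = _tl(
            ("forward", 0, 900), ("dance", 900, 2000), ("backward", 2000, 2600),
            ("dance", 2600, 2900), ("clockwise", 2900, 3900),
        )
        events = extract_events(tl)
        for a, b in zip(events, events[1:]):
            assert a.onset_ms + a.duration_ms <= b.onset_ms

    def test_adjacent_runs_merge_into_majority_gesture(self):
        # one side resolved the bilateral onset later: sliver + main run
        tl = _tl(
            ("dance", 0, 1000), ("right-forward", 1000, 1100),
            ("forward", 1100, 2000), ("dance", 2000, 3000),
        )
        events = extract_events(tl)
        assert len(events) == 1
        assert events[0].gesture_name == "forward"
        assert events[0].onset_ms == 1000
        assert events[0].duration_ms == 1000

    def test_subthreshold_dance_hole_bridged(self):
        tl = _tl(
            ("dance", 0, 1000), ("forward", 1000, 1400), ("dance", 1400, 1433),
            ("forward", 1433, 2000), ("dance", 2000, 3000),
        )
        events = extract_events(tl)
        assert len(events) == 1
        assert events[0].duration_ms == 1000

    def test_latency_compensation_shifts_onsets(self):
        tl = _tl(("dance", 0, 1000), ("forward", 1000, 2000))
        assert extract_events(tl, onset_latency_ms=667)[0].onset_ms == 333
        assert labeling_latency_ms(w=30, fs_hz=30.0, stride=1) == 667


class TestScoreTiming:
    def test_bundled_example_reproduces_reference_errors(self):
        events, refs = pg.example_timing_events()
        rep = pg.score_timing(events, refs)
        assert rep.onset_errors_ms == [-60, -60, 360, 60, 60, 0, 210, 180]
        assert rep.mae_ms == pytest.approx(123.75)
        assert rep.mean_duration_error_pct == pytest.approx(47.84, abs=0.01)

    def test_perfect_prediction_scores_zero(self):
        refs = [GestureAnnotation("forward", 1000, 900, source="fsr")]
        events = [pg.PropulsionEvent(5, "forward", 1000, 900)]
        rep = pg.score_timing(events, refs)
        assert rep.mae_ms == 0
        assert rep.mean_duration_error_pct == 0

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            pg.score_timing([], [])

    def test_unmatched_events_reported_not_scored(self):
        refs = [GestureAnnotation("forward", 1000, 900, source="fsr")]
        events = [
            pg.PropulsionEvent(5, "forward", 1100, 800),
            pg.PropulsionEvent(3, "right-forward", 9000, 300),
        ]
        rep = pg.score_timing(events, refs)
        assert rep.n_matched == 1
        assert rep.unmatched_events == 1
        assert rep.onset_errors_ms == [100]


@pytest.fixture(scope="module")
def models(small_corpus):
    cfg = pg.TrainingConfig(seed=0)
    out = {}
    for side in ("left", "right"):
        ds = pg.build_dataset(small_corpus, side, "two-sensor", pg.WindowParams(30, 5), seed=0)
        out[side] = pg.train_side(ds, cfg, algos=("svm",))
    return out


class TestPredictionReplay:
    def test_stream_is_contiguous_and_one_entry_per_window(self, one_trial, models):
        stream = pg.predict_stream(one_trial, models["right"], stride=5)
        n_windows = pg.count_windows(one_trial.n_samples, pg.WindowParams(30, 5))
        assert len(stream.entries) == n_windows
        for (k1, _, _, b1), (k2, _, a2, _) in zip(stream.entries, stream.entries[1:]):
            assert k2 == k1 + 1
            assert a2 == b1

    def test_all_dance_recording_yields_all_dance_stream(self, one_trial, models):
        quiet = one_trial.data.copy()
        rng = np.random.default_rng(0)
        for c in quiet.columns:
            if c == "t_ms":
                continue
            base = 9.81 if c.endswith("_z") and "acc" in c else 0.0
            quiet[c] = base + 0.05 * rng.standard_normal(len(quiet))
        rec = pg.TrialRecording(quiet, one_trial.fs_hz)
        stream = pg.predict_stream(rec, models["left"])
        assert {lab for _, lab, _, _ in stream.entries} == {"dance"}
        assert pg.recognize(rec, models["left"], models["right"]) == []

    def test_streams_must_share_window_grid(self, one_trial, models):
        left = pg.predict_stream(one_trial, models["left"], stride=5)
        right = pg.predict_stream(one_trial, models["right"], stride=3)
        with pytest.raises(ValueError):
            fuse_streams(left, right)

    def test_forward_propulsion_detected_over_gesture_core(self, models, sim_config):
        plan = pg.make_choreography(42, config=sim_config)
        rec = pg.synthesize_trial(plan, sim_config)
        target = next(a for a in rec.annotations if a.label == "forward")
        stream_l = pg.predict_stream(rec, models["left"])
        stream_r = pg.predict_stream(rec, models["right"])
        # causal detection spans roughly [onset + 0.7 w, offset + 0.3 w]
        # in paint time; the core of that span must read forward on both
        # sides and never backward
        lo = target.onset_ms + 800
        hi = target.onset_ms + target.duration_ms + 200
        for stream in (stream_l, stream_r):
            labels = [lab for _, lab, a, b in stream.entries if a >= lo and b <= hi]
            assert "forward" in labels
            assert "backward" not in labels


def test_overall_accuracy_is_product():
    assert overall_accuracy(0.9, 0.8) == pytest.approx(0.72)
    with pytest.raises(ValueError):
        overall_accuracy(1.2, 0.5)
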