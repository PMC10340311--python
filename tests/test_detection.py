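import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdbdetect.core import CategoricalTrack, Event, EventList, Hypnogram
from sdbdetect.detection import (
    THRESHOLD_GRID,
    MatchCounts,
    NightPrediction,
    binarize_events,
    detection_metrics,
    detection_rate_by_type,
    event_length_summary,
    mask_wake,
    match_events_olsen,
    match_events_strict,
    select_threshold,
    stitch_predictions,
    stratified_detection_rate,
)

from conftest import oracle_olsen, oracle_strict, random_events


class TestStitch:
    def test_two_segments_cover_central_span(self):
        probs = [np.full(300, 0.3), np.full(300, 0.6)]
        pred = stitch_predictions(probs, [0.0, 180.0], (0.0, 480.0))
        assert not pred.scored[:60].any()
        assert pred.scored[60:420].all()
        assert not pred.scored[420:].any()
        assert (pred.probs[60:240] == 0.3).all()
        assert (pred.probs[240:420] == 0.6).all()
        assert (pred.probs[:60] == 0).all()

    def test_single_segment_scores_180s(self):
        pred = stitch_predictions([np.full(300, 0.5)], [0.0], (0.0, 300.0))
        assert pred.scored.sum() == 180

    def test_tiling_count(self):
        starts = [i * 180.0 for i in range(7)]
        probs = [np.full(300, 0.1)] * 7
        pred = stitch_predictions(probs, starts, (0.0, 7 * 180 + 120.0))
        assert pred.scored.sum() == 180 * 7

    def test_off_grid_start_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            stitch_predictions([np.full(300, 0.5)] * 2, [0.0, 90.0], (0.0, 600.0))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="300"):
            stitch_predictions([np.full(299, 0.5)], [0.0], (0.0, 300.0))


class TestMaskWake:
    def test_all_wake_zeroes_everything(self):
        pred = stitch_predictions([np.full(300, 0.9)], [0.0], (0.0, 300.0))
        hyp = Hypnogram(["W"] * 10)
        out = mask_wake(pred, hyp)
        assert (out.probs == 0).all()
        assert out.wake_masked

    def test_all_sleep_identity(self):
        pred = stitch_predictions([np.full(300, 0.9)], [0.0], (0.0, 300.0))
        out = mask_wake(pred, Hypnogram(["N2"] * 10))
        assert np.array_equal(out.probs, pred.probs)

    def test_single_wake_epoch_zeroes_30s(self):
        pred = stitch_predictions([np.full(300, 0.9)], [0.0], (0.0, 300.0))
        stages = ["N2"] * 10
        stages[3] = "W"  # seconds 90..119
        out = mask_wake(pred, Hypnogram(stages))
        zeroed = np.flatnonzero(pred.probs != out.probs)
        assert len(zeroed) == 30 and zeroed[0] == 90 and zeroed[-1] == 119


class TestBinarize:
    def test_run_length_rule(self):
        probs = np.array([0, 0, 0.9, 0.9, 0, 0.8])
        pred = NightPrediction(probs, np.ones(6, bool), t0=0.0)
        ev = binarize_events(pred, 0.5)
        assert [(e.start_s, e.end_s) for e in ev] == [(2, 4), (5, 6)]

    def test_all_below_empty(self):
        pred = NightPrediction(np.full(10, 0.2), np.ones(10, bool), 0.0)
        assert len(binarize_events(pred, 0.5)) == 0

    def test_strictly_greater(self):
        pred = NightPrediction(np.full(10, 0.9), np.ones(10, bool), 0.0)
        assert len(binarize_events(pred, 0.9)) == 0

    def test_unscored_breaks_runs(self):
        scored = np.ones(10, bool)
        scored[5] = False
        probs = np.full(10, 0.9)
        probs[5] = 0.0
        ev = binarize_events(NightPrediction(probs, scored, 0.0), 0.5)
        assert [(e.start_s, e.end_s) for e in ev] == [(0, 5), (6, 10)]

    def test_t0_offset(self):
        pred = NightPrediction(np.array([0.9, 0.0]), np.ones(2, bool), t0=120.0)
        ev = binarize_events(pred, 0.5)
        assert [(e.start_s, e.end_s) for e in ev] == [(120.0, 121.0)]

    def test_bad_threshold(self):
        pred = NightPrediction(np.zeros(5), np.ones(5, bool), 0.0)
        with pytest.raises(ValueError):
            binarize_events(pred, 1.5)


class TestMatchingRules:
    def test_second_overlap_is_fp_under_strict(self):
        ann = EventList([Event(0, 30)])
        det = EventList([Event(0, 10), Event(20, 30)])
        m = match_events_strict(det, ann)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_second_overlap_is_tp_under_olsen(self):
        ann = EventList([Event(0, 30)])
        det = EventList([Event(0, 10), Event(20, 30)])
        m = match_events_olsen(det, ann)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_spanning_detection_second_annotation_fn_under_strict(self):
        ann = EventList([Event(0, 10), Event(20, 30)])
        det = EventList([Event(5, 25)])
        m = match_events_strict(det, ann)
        assert (m.tp, m.fp, m.fn) == (1, 0, 1)

    def test_spanning_detection_detected_under_olsen(self):
        ann = EventList([Event(0, 10), Event(20, 30)])
        det = EventList([Event(5, 25)])
        m = match_events_olsen(det, ann)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_no_detections(self):
        ann = EventList([Event(0, 10), Event(20, 30)])
        m = match_events_strict(EventList([]), ann)
        assert (m.tp, m.fp, m.fn) == (0, 0, 2)

    def test_disjoint_all_wrong(self):
        ann = EventList([Event(0, 10)])
        det = EventList([Event(50, 60), Event(70, 80)])
        m = match_events_olsen(det, ann)
        assert (m.tp, m.fp, m.fn) == (0, 2, 1)

    def test_unsorted_rejected(self):
        class FakeList(list):
            pass

        bad = FakeList([Event(10, 20), Event(0, 5)])
        with pytest.raises(ValueError, match="sorted"):
            match_events_strict(bad, EventList([]))

    def test_oracle_agreement_random(self, rng):
        for _ in range(200):
            ann = random_events(rng, int(rng.integers(0, 15)), typed=True)
            det = random_events(rng, int(rng.integers(0, 15)))
            ms = match_events_strict(det, ann)
            mo = match_events_olsen(det, ann)
            assert (ms.tp, ms.fp, ms.fn) == oracle_strict(det, ann)
            assert (mo.tp, mo.fp, mo.fn) == oracle_olsen(det, ann)
            # structural invariants
            assert ms.tp + ms.fn == len(ann)
            assert ms.tp + ms.fp == len(det)
            assert ms.tp <= mo.tp


class TestDetectionMetrics:
    def test_ratio_arithmetic(self):
        m = MatchCounts(tp=77, fp=41, fn=23)
        out = detection_metrics([m])
        assert out.pooled["sensitivity"] == pytest.approx(0.77)
        assert out.pooled["precision"] == pytest.approx(77 / 118, abs=1e-4)
        assert out.pooled["f1"] == pytest.approx(0.7064, abs=1e-3)

    def test_perfect(self):
        out = detection_metrics([MatchCounts(tp=10, fp=0, fn=0)])
        assert out.pooled == {
            "sensitivity": 1.0, "precision": 1.0, "f1": 1.0, "tp": 10, "fp": 0, "fn": 0,
        }

    def test_pooled_differs_from_mean(self):
        nights = [MatchCounts(tp=90, fp=10, fn=10), MatchCounts(tp=1, fp=9, fn=9)]
        out = detection_metrics(nights)
        mean_sens = 0.5 * (90 / 100 + 1 / 10)
        pooled_sens = 91 / 110
        assert out.per_subject_mean["sensitivity"] == pytest.approx(mean_sens)
        assert out.pooled["sensitivity"] == pytest.approx(pooled_sens)
        assert abs(mean_sens - pooled_sens) > 0.05

    def test_undefined_ratio_excluded_with_warning(self):
        nights = [MatchCounts(tp=5, fp=0, fn=0), MatchCounts(tp=0, fp=0, fn=0)]
        with pytest.warns(UserWarning, match="undefined"):
            out = detection_metrics(nights)
        assert out.per_subject_mean["sensitivity"] == 1.0


class TestByTypeAndStrata:
    def test_per_type_rates(self):
        ann = EventList([
            Event(0, 20, "hypopnea"), Event(50, 70, "obstructive"), Event(100, 130, "central"),
        ])
        det = EventList([Event(55, 60), Event(105, 110)])  # miss the hypopnea
        m = match_events_strict(det, ann)
        rates = detection_rate_by_type([m])
        assert rates == {"hypopnea": 0.0, "obstructive": 1.0, "central": 1.0}

    def test_type_counts_conserved(self, rng):
        ann = random_events(rng, 12, typed=True)
        det = random_events(rng, 8)
        m = match_events_strict(det, ann)
        assert sum(tp + fn for tp, fn in m.by_type.values()) == len(ann)

    def test_stratified_by_stage(self):
        ann = EventList([Event(10, 25, "central"), Event(40, 55, "central")])
        det = EventList([Event(12, 20)])
        m = match_events_strict(det, ann)
        hyp = Hypnogram(["N2", "REM"])  # event 1 starts in N2, event 2 in REM
        rates = stratified_detection_rate([m], [hyp])
        assert rates == {"N2": 1.0, "REM": 0.0}

    def test_stratified_by_position_partition(self, rng):
        ann = random_events(rng, 10, typed=True, span=600)
        det = random_events(rng, 6, span=600)
        m = match_events_strict(det, ann)
        track = CategoricalTrack(["supine"] * 500 + ["prone"] * 3200)
        rates = stratified_detection_rate([m], [track])
        assert set(rates) <= {"supine", "prone"}

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            stratified_detection_rate([MatchCounts()], [None])

    def test_event_length_summary(self):
        ann = EventList([Event(0, 20, "central"), Event(50, 90, "central")])
        det = EventList([Event(5, 10)])
        m = match_events_strict(det, ann)
        out = event_length_summary([m])
        assert out["detected_mean_s"] == 20.0
        assert out["missed_mean_s"] == 40.0

    def test_all_detected_missed_absent(self):
        ann = EventList([Event(0, 20, "central")])
        m = match_events_strict(EventList([Event(1, 5)]), ann)
        out = event_length_summary([m])
        assert out["missed_mean_s"] is None


class TestSelectThreshold:
    def test_grid_has_249_points(self):
        assert THRESHOLD_GRID.size == 249
        assert THRESHOLD_GRID[0] == pytest.approx(0.004)
        assert THRESHOLD_GRID[-1] == pytest.approx(0.996)

    def test_clean_separation_picks_smallest_perfect_tau(self):
        probs = np.full(300, 0.1)
        probs[100:130] = 0.9
        probs[200:220] = 0.9
        pred = NightPrediction(probs, np.ones(300, bool), 0.0)
        ann = EventList([Event(100, 130, "central"), Event(200, 220, "obstructive")])
        sel = select_threshold([(pred, ann)])
        # strict '>' reading: tau = 0.100 already separates perfectly
        perfect = (THRESHOLD_GRID >= 0.1 - 1e-9) & (THRESHOLD_GRID <= 0.896 + 1e-9)
        assert np.allclose(sel.f1[perfect], 1.0)
        assert sel.chosen == pytest.approx(0.1)

    def test_single_point_grid(self):
        probs = np.full(10, 0.9)
        pred = NightPrediction(probs, np.ones(10, bool), 0.0)
        sel = select_threshold([(pred, EventList([Event(0, 10, "central")]))], grid=np.array([0.5]))
        assert sel.chosen == 0.5

    def test_all_zero_predictions_warns(self):
        pred = NightPrediction(np.zeros(100), np.ones(100, bool), 0.0)
        with pytest.warns(UserWarning, match="all-zero"):
            sel = select_threshold([(pred, EventList([Event(0, 10, "central")]))])
        assert sel.chosen == pytest.approx(0.004)

    def test_matches_exhaustive_oracle(self, rng):
        nights = []
        for k in range(3):
            probs = np.round(rng.random(400), 3)
            pred = NightPrediction(probs, np.ones(400, bool), 0.0)
            nights.append((pred, random_events(rng, 6, span=350, typed=True, max_len=30)))
        clipped = [(p, a.clipped(*p.scored_span)) for p, a in nights]
        sel = select_threshold(nights)
        best_f1, best_tau = -1.0, None
        for tau in THRESHOLD_GRID:
            tp = fp = fn = 0
            for pred, ann in clipped:
                m = match_events_strict(binarize_events(pred, float(tau)), ann)
                tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
            f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
            if f1 > best_f1 + 1e-12:
                best_f1, best_tau = f1, float(tau)
        assert sel.chosen == pytest.approx(best_tau)
        assert sel.f1.max() == pytest.approx(best_f1)


@given(st.data())
@settings(max_examples=30, deadline=None)
def test_threshold_monotonicity(data):
    probs = np.array(
        data.draw(st.lists(st.floats(0, 1), min_size=20, max_size=60)), dtype=float
    )
    pred = NightPrediction(probs, np.ones(probs.size, bool), 0.0)
    taus = sorted(data.draw(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=5)))
    seconds = [sum(e.duration for e in binarize_events(pred, t)) for t in taus]
    assert all(a >= b for a, b in zip(seconds, seconds[1:]))
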