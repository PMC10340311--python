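"""Night-level event detection and event-based scoring.

Per-segment 1 Hz probabilities are stitched (central 3 minutes of each
5-minute segment), wake-masked, binarized by a threshold into detected
events, and scored against annotations under two rules:

* strict: an annotated event is credited only by the first (earliest
  starting) not-yet-matched detection that overlaps it; every other
  detection is a false positive;
* olsen: any detection overlapping any annotation is a true positive and an
  annotation counts as detected if anything overlaps it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Event, EventList, Hypnogram

THRESHOLD_GRID = np.round(np.arange(1, 250) * 0.004, 6)  # 0.004 .. 0.996


@dataclass
class NightPrediction:
    """Stitched 1 Hz probability series over the lights-off span."""

    probs: np.ndarray
    scored: np.ndarray  # bool; False where no segment's central interval covers the second
    t0: float
    subject_id: str = ""
    wake_masked: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.scored = np.asarray(self.scored, dtype=bool)
        if self.probs.shape != self.scored.shape:
            raise ValueError("probs and scored mask must align")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(self.probs[~self.scored] != 0):
            raise ValueError("unscored seconds must carry probability 0")

    @property
    def scored_span(self) -> tuple[float, float]:
        idx = np.flatnonzero(self.scored)
        if idx.size == 0:
            return (self.t0, self.t0)
        return (self.t0 + idx[0], self.t0 + idx[-1] + 1)


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    by_type: dict[str, tuple[int, int]] = field(default_factory=dict)  # type -> (tp, fn)
    matched_annotated: list[bool] = field(default_factory=list)
    annotated_durations: list[float] = field(default_factory=list)
    annotated_starts: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stitching / masking / binarization


def stitch_predictions(
    segment_probs: Sequence[np.ndarray],
    segment_starts: Sequence[float],
    span: tuple[float, float],
    subject_id: str = "",
) -> NightPrediction:
    """Concatenate the central [start+60, start+240) of each segment.

    Segment starts must sit on the 180-s stride grid so central intervals
    tile; an overlap raises.  Seconds covered by no central interval are 0
    and marked unscored.
    """
    t0, t1 = span
    n = int(round(t1 - t0))
    probs = np.zeros(n)
    scored = np.zeros(n, dtype=bool)
    order = np.argsort(np.asarray(segment_starts))
    base = None
    for k in order:
        start = float(segment_starts[k])
        p = np.asarray(segment_probs[k], dtype=float)
        if p.shape != (300,):
            raise ValueError("each segment output must have length 300")
        if base is None:
            base = start
        elif abs((start - base) / 180.0 - round((start - base) / 180.0)) > 1e-6:
            raise ValueError("segment starts must lie on the 180-s grid")
        lo = int(round(start - t0)) + 60
        hi = lo + 180
        s, e = max(lo, 0), min(hi, n)
        if s >= e:
            continue
        if scored[s:e].any():
            raise ValueError("overlapping central intervals (grid violation)")
        probs[s:e] = p[60 + (s - lo) : 60 + (e - lo)]
        scored[s:e] = True
    return NightPrediction(probs, scored, t0, subject_id)


def mask_wake(pred: NightPrediction, hyp: Hypnogram) -> NightPrediction:
    """Zero the probability at every second whose 30-s epoch is wake."""
    if hyp.duration < pred.t0 + pred.probs.size - 1e-6:
        raise ValueError("hypnogram does not cover the prediction span")
    sec = pred.t0 + np.arange(pred.probs.size)
    epoch = np.minimum((sec // hyp.epoch_s).astype(int), len(hyp.stages) - 1)
    wake = np.asarray(hyp.stages, dtype=object)[epoch] == "W"
    probs = pred.probs.copy()
    probs[wake] = 0.0
    return NightPrediction(probs, pred.scored, pred.t0, pred.subject_id, wake_masked=True)


def binarize_events(pred: NightPrediction, threshold: float) -> EventList:
    """Maximal runs of scored seconds with probability strictly above the
    threshold become events; no minimum duration, no merging."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    active = pred.scored & (pred.probs > threshold)
    padded = np.r_[False, active, False].astype(int)
    edges = np.flatnonzero(np.diff(padded))
    events = [
        Event(pred.t0 + float(s), pred.t0 + float(e))
        for s, e in zip(edges[::2], edges[1::2])
    ]
    return EventList(events)


# ---------------------------------------------------------------------------
# matching rules


def _check_sorted(evs: EventList | Sequence[Event]) -> list[Event]:
    lst = list(evs)
    for a, b in zip(lst, lst[1:]):
        if b.start_s < a.start_s:
            raise ValueError("event list must be sorted by start time")
    return lst


def match_events_strict(detected, annotated) -> MatchCounts:
    """Greedy one-to-one: each annotated event (in time order) is credited to
    its earliest-starting overlapping, not-yet-matched detection."""
    det = _check_sorted(detected)
    ann = _check_sorted(annotated)
    used = [False] * len(det)
    m = MatchCounts()
    for a in ann:
        hit = False
        for j, d in enumerate(det):
            if d.start_s >= a.end_s:
                break
            if not used[j] and d.overlaps(a):
                used[j] = True
                hit = True
                break
        m.tp += hit
        m.fn += not hit
        m.matched_annotated.append(hit)
        m.annotated_durations.append(a.duration)
        m.annotated_starts.append(a.start_s)
        if a.type is not None:
            tp, fn = m.by_type.get(a.type, (0, 0))
            m.by_type[a.type] = (tp + hit, fn + (not hit))
    m.fp = sum(1 for u in used if not u)
    return m


def match_events_olsen(detected, annotated) -> MatchCounts:
    """Any-overlap crediting on both sides (no one-to-one constraint)."""
    det = _check_sorted(detected)
    ann = _check_sorted(annotated)
    m = MatchCounts()
    for d in det:
        if any(d.overlaps(a) for a in ann):
            m.tp += 1
        else:
            m.fp += 1
    for a in ann:
        hit = any(d.overlaps(a) for d in det)
        m.fn += not hit
        m.matched_annotated.append(hit)
        m.annotated_durations.append(a.duration)
        m.annotated_starts.append(a.start_s)
        if a.type is not None:
            tp, fn = m.by_type.get(a.type, (0, 0))
            m.by_type[a.type] = (tp + hit, fn + (not hit))
    return m


MATCHERS = {"strict": match_events_strict, "olsen": match_events_olsen}


# ---------------------------------------------------------------------------
# metrics


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def _f1(p: float | None, r: float | None) -> float | None:
    if p is None or r is None or p + r == 0:
        return None
    return 2 * p * r / (p + r)


@dataclass
class DetectionMetrics:
    per_subject_mean: dict[str, float]
    per_subject_sd: dict[str, float]
    pooled: dict[str, float]
    n_subjects: int


def detection_metrics(per_night: Sequence[MatchCounts]) -> DetectionMetrics:
    """Per-subject mean +/- SD and pooled sensitivity / precision / F1.

    Undefined per-subject ratios (0/0) are excluded from the mean with a
    warning; pooled metrics come from summed counts.
    """
    if not per_night:
        raise ValueError("need at least one night")
    cols: dict[str, list[float]] = {"sensitivity": [], "precision": [], "f1": []}
    for m in per_night:
        s = _ratio(m.tp, m.tp + m.fn)
        p = _ratio(m.tp, m.tp + m.fp)
        f = _f1(p, s)
        for key, v in (("sensitivity", s), ("precision", p), ("f1", f)):
            if v is None:
                warnings.warn(f"undefined per-subject {key} excluded from mean", stacklevel=2)
            else:
                cols[key].append(v)
    mean = {k: float(np.mean(v)) if v else float("nan") for k, v in cols.items()}
    sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in cols.items()}
    tp = sum(m.tp for m in per_night)
    fp = sum(m.fp for m in per_night)
    fn = sum(m.fn for m in per_night)
    ps = _ratio(tp, tp + fn)
    pp = _ratio(tp, tp + fp)
    pooled = {
        "sensitivity": float("nan") if ps is None else ps,
        "precision": float("nan") if pp is None else pp,
        "f1": float("nan") if _f1(pp, ps) is None else float(_f1(pp, ps)),
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }
    return DetectionMetrics(mean, sd, pooled, len(per_night))


def detection_rate_by_type(per_night: Sequence[MatchCounts]) -> dict[str, float]:
    """Pooled per-annotated-type sensitivity."""
    agg: dict[str, list[int]] = {}
    for m in per_night:
        for typ, (tp, fn) in m.by_type.items():
            a = agg.setdefault(typ, [0, 0])
            a[0] += tp
            a[1] += fn
    return {t: tp / (tp + fn) for t, (tp, fn) in agg.items() if tp + fn > 0}


def stratified_detection_rate(
    per_night: Sequence[MatchCounts], tracks: Sequence
) -> dict[str, float]:
    """Sensitivity per category (sleep stage or position) at event start."""
    if len(per_night) != len(tracks):
        raise ValueError("one track per night required")
    agg: dict[str, list[int]] = {}
    for m, track in zip(per_night, tracks):
        if track is None or len(track) == 0:
            raise ValueError("empty category track")
        get = track.stage_at if isinstance(track, Hypnogram) else track.label_at
        for start, hit in zip(m.annotated_starts, m.matched_annotated):
            cat = get(start)
            a = agg.setdefault(cat, [0, 0])
            a[0] += hit
            a[1] += not hit
    return {c: tp / (tp + fn) for c, (tp, fn) in agg.items() if tp + fn > 0}


def event_length_summary(per_night: Sequence[MatchCounts]) -> dict[str, float | None]:
    """Mean annotated-event length for detected vs missed events."""
    det, mis = [], []
    for m in per_night:
        for dur, hit in zip(m.annotated_durations, m.matched_annotated):
            (det if hit else mis).append(dur)
    return {
        "detected_mean_s": float(np.mean(det)) if det else None,
        "missed_mean_s": float(np.mean(mis)) if mis else None,
    }


# ---------------------------------------------------------------------------
# threshold selection


@dataclass
class ThresholdSelection:
    grid: np.ndarray
    f1: np.ndarray
    chosen: float


def select_threshold(
    nights: Sequence[tuple[NightPrediction, EventList]],
    grid: np.ndarray | None = None,
) -> ThresholdSelection:
    """Pooled strict-rule F1 at every grid point; argmax, ties -> smallest."""
    grid = THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
    if not nights:
        raise ValueError("need at least one validation night")
    if all(np.all(p.probs == 0) for p, _ in nights):
        warnings.warn("all-zero predictions; returning smallest grid threshold", stacklevel=2)
        return ThresholdSelection(grid, np.zeros(grid.size), float(grid[0]))

    clipped = []
    for pred, ann in nights:
        lo, hi = pred.scored_span
        clipped.append((pred, ann.clipped(lo, hi)))

    f1s = np.zeros(grid.size)
    for i, tau in enumerate(grid):
        tp = fp = fn = 0
        for pred, ann in clipped:
            m = match_events_strict(binarize_events(pred, float(tau)), ann)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
        p = _ratio(tp, tp + fp)
        s = _ratio(tp, tp + fn)
        f = _f1(p, s)
        f1s[i] = 0.0 if f is None else f
    best = int(np.argmax(f1s))  # argmax returns the first (smallest) maximizer
    return ThresholdSelection(grid, f1s, float(grid[best]))


def evaluate_night(
    pred: NightPrediction,
    annotated: EventList,
    threshold: float,
    rule: str = "strict",
) -> MatchCounts:
    """Binarize one night and score it; annotations are clipped to the scored
    span first so uncovered seconds can neither credit nor penalize."""
    lo, hi = pred.scored_span
    detected = binarize_events(pred, threshold)
    return MATCHERS[rule](detected, annotated.clipped(lo, hi))
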