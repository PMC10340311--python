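"""Training-segment construction and the stratified subject split.

Segments are 5-minute windows (1200 samples per channel at 4 Hz) advanced
every 3 minutes (2-minute overlap), each with a 300-entry 1 Hz binary target
and sample weights (label 0 -> 1, label 1 -> 10).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import EventList, SampledSignal, SubjectRecord
from .synthgen import SEVERITY_CLASSES, severity_of

log = logging.getLogger(__name__)

WINDOW_S = 300
STRIDE_S = 180
SAMPLES_PER_WINDOW = 1200  # 300 s * 4 Hz
TARGET_LEN = 300
POSITIVE_WEIGHT = 10.0


@dataclass
class Segment:
    inputs: np.ndarray  # (1200, 2), channel order: RR, respiration surrogate
    target: np.ndarray  # (300,) binary
    weights: np.ndarray  # (300,) positive
    subject_id: str
    start_s: float

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.inputs.shape != (SAMPLES_PER_WINDOW, 2):
            raise ValueError(f"inputs must be (1200, 2), got {self.inputs.shape}")
        if self.target.shape != (TARGET_LEN,):
            raise ValueError(f"target must have length {TARGET_LEN}")
        if self.weights.shape != (TARGET_LEN,):
            raise ValueError(f"weights must have length {TARGET_LEN}")
        expect = np.where(self.target > 0.5, POSITIVE_WEIGHT, 1.0)
        if not np.array_equal(self.weights, expect):
            raise ValueError("weights must be 10 where target=1 and 1 where target=0")


def soft_minmax(channel: np.ndarray) -> np.ndarray:
    """Soft min-max: map the 5th/95th percentiles to 0/1, no clipping.

    A degenerate channel (p95 == p5) maps to all 0.5 with a warning.
    """
    x = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("channel contains non-finite values")
    p5, p95 = np.percentile(x, [5, 95])
    if p95 <= p5:
        warnings.warn("degenerate segment channel (p95 == p5); set to 0.5", stacklevel=2)
        return np.full_like(x, 0.5)
    return (x - p5) / (p95 - p5)


def build_target(events: EventList, window: tuple[float, float]) -> np.ndarray:
    """1 Hz labels for ``window``: second t is 1 iff [t, t+1) overlaps an event."""
    start, end = window
    n = int(round(end - start))
    if n != TARGET_LEN:
        raise ValueError(f"window must span {TARGET_LEN} s")
    y = np.zeros(n)
    for e in events:
        lo = int(np.floor(e.start_s - start))
        hi = int(np.ceil(e.end_s - start))
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            y[lo:hi] = 1.0
    return y


def make_weights(target: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(target) > 0.5, POSITIVE_WEIGHT, 1.0)


def segment_record(
    channels: Sequence[SampledSignal],
    events: EventList,
    lights_window: tuple[float, float],
    subject_id: str = "",
    normalize: bool = True,
) -> list[Segment]:
    """Cut 300-s windows every 180 s wholly inside the lights-off span.

    ``channels`` is the ordered input pairing (RR first).  The window grid is
    anchored at lights-off; a trailing partial window is dropped.
    """
    if len(channels) != 2:
        raise ValueError("expected exactly 2 input channels")
    fs = channels[0].fs
    if any(c.fs != fs for c in channels) or fs != 4.0:
        raise ValueError("all channels must be sampled at 4 Hz")
    n = channels[0].values.size
    if any(c.values.size != n for c in channels):
        raise ValueError("channels must have equal length")

    lights_off, lights_on = lights_window
    usable = min(lights_on, n / fs) - lights_off
    if usable < WINDOW_S:
        log.warning("usable span %.0f s is shorter than one window; no segments", usable)
        return []

    out: list[Segment] = []
    start = lights_off
    while start + WINDOW_S <= lights_off + usable + 1e-9:
        i0 = int(round(start * fs))
        block = np.stack([c.values[i0 : i0 + SAMPLES_PER_WINDOW] for c in channels], axis=1)
        if normalize:
            block = np.stack([soft_minmax(block[:, j]) for j in range(2)], axis=1)
        target = build_target(events, (start, start + WINDOW_S))
        out.append(
            Segment(
                inputs=block,
                target=target,
                weights=make_weights(target),
                subject_id=subject_id,
                start_s=start,
            )
        )
        start += STRIDE_S
    return out


def build_segments(
    record: SubjectRecord,
    channels: Mapping[str, SampledSignal],
    pairing: str = "rr+re",
    normalize: bool = True,
) -> list[Segment]:
    """Convenience: assemble the (RR, EDR) or (RR, RE) pairing for a record."""
    second = {"rr+re": "re", "rr+edr": "edr"}[pairing]
    return segment_record(
        [channels["rr"], channels[second]],
        record.events,
        (record.lights_off_s, record.lights_on_s),
        subject_id=record.subject_id,
        normalize=normalize,
    )


# ---------------------------------------------------------------------------
# stratified split


def _round_half_down(x: float) -> int:
    return int(np.ceil(x - 0.5))


def stratified_split(
    cohort: Sequence[SubjectRecord],
    fractions: tuple[float, float] = (0.25, 0.25),
    seed: int = 0,
) -> dict[str, str]:
    """Subject id -> {train, validation, test}, stratified by severity class.

    ``fractions`` = (test fraction of all, validation fraction of the
    remainder).  Per class the counts are rounded half-down (ties toward the
    smaller set); the shuffle is seeded.
    """
    f_test, f_val = fractions
    if not (0 < f_test < 1 and 0 < f_val < 1):
        raise ValueError("fractions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {c: [] for c in SEVERITY_CLASSES}
    for rec in cohort:
        by_class[severity_of(rec.reference_ahi)].append(rec.subject_id)

    assign: dict[str, str] = {}
    for cls in SEVERITY_CLASSES:
        ids = by_class[cls]
        if not ids:
            warnings.warn(f"severity class {cls!r} has no subjects; skipped", stacklevel=2)
            continue
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n_test = _round_half_down(len(ids) * f_test)
        rest = ids[n_test:]
        n_val = _round_half_down(len(rest) * f_val)
        for sid in ids[:n_test]:
            assign[sid] = "test"
        for sid in rest[:n_val]:
            assign[sid] = "validation"
        for sid in rest[n_val:]:
            assign[sid] = "train"
    return assign
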