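"""Shared domain types for cardiorespiratory SDB analysis.

All times are seconds from the start of the recording; event intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

EVENT_TYPES = ("hypopnea", "obstructive", "central", "mixed")
SLEEP_STAGES = ("W", "N1", "N2", "N3", "REM")
POSITIONS = ("supine", "prone", "left", "right")

EPOCH_S = 30.0


@dataclass
class SampledSignal:
    """A uniformly sampled channel."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass(frozen=True)
class Event:
    start_s: float
    end_s: float
    type: str | None = None

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"event must have start < end, got [{self.start_s}, {self.end_s})")
        if self.type is not None and self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, other: "Event") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s


class EventList:
    """Sorted, pairwise non-overlapping half-open intervals.

    ``min_duration`` is enforced for annotated events (default 0 so that
    detector output, which has no minimum length, can reuse the type).
    """

    def __init__(self, events: Sequence[Event] = (), min_duration: float = 0.0):
        evs = sorted(events, key=lambda e: (e.start_s, e.end_s))
        for a, b in zip(evs, evs[1:]):
            if a.end_s > b.start_s:
                raise ValueError(f"overlapping events: [{a.start_s},{a.end_s}) and [{b.start_s},{b.end_s})")
        for e in evs:
            if e.duration < min_duration - 1e-9:
                raise ValueError(f"event [{e.start_s},{e.end_s}) shorter than minimum {min_duration}s")
        self.events: list[Event] = evs
        self.min_duration = min_duration

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __getitem__(self, i: int) -> Event:
        return self.events[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EventList) and self.events == other.events

    def total_duration(self) -> float:
        return sum(e.duration for e in self.events)

    def clipped(self, start_s: float, end_s: float) -> "EventList":
        """Intersect every event with [start_s, end_s); drop empty remains."""
        out = []
        for e in self.events:
            s, t = max(e.start_s, start_s), min(e.end_s, end_s)
            if s < t:
                out.append(Event(s, t, e.type))
        return EventList(out)


class Hypnogram:
    """Per-epoch sleep stage labels covering a whole recording."""

    def __init__(self, stages: Sequence[str], epoch_s: float = EPOCH_S):
        stages = list(stages)
        if not stages:
            raise ValueError("hypnogram must contain at least one epoch")
        for s in stages:
            if s not in SLEEP_STAGES:
                raise ValueError(f"unknown sleep stage {s!r}")
        if epoch_s <= 0:
            raise ValueError("epoch length must be positive")
        self.stages = stages
        self.epoch_s = float(epoch_s)

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_s

    def stage_at(self, t: float) -> str:
        i = int(t // self.epoch_s)
        i = min(max(i, 0), len(self.stages) - 1)
        return self.stages[i]

    def sleep_mask_seconds(self, n_seconds: int) -> np.ndarray:
        """Boolean per-second mask: True where the enclosing epoch is not wake."""
        sec = np.arange(n_seconds)
        idx = np.minimum((sec // int(self.epoch_s)).astype(int), len(self.stages) - 1)
        st = np.asarray(self.stages, dtype=object)[idx]
        return st != "W"

    def total_sleep_time_s(self) -> float:
        return sum(self.epoch_s for s in self.stages if s != "W")


class CategoricalTrack:
    """One categorical label per second (e.g. body position)."""

    def __init__(self, labels: Sequence[str]):
        if len(labels) == 0:
            raise ValueError("track must contain at least one label")
        self.labels = list(labels)

    def __len__(self) -> int:
        return len(self.labels)

    def label_at(self, t: float) -> str:
        i = min(max(int(t), 0), len(self.labels) - 1)
        return self.labels[i]


@dataclass
class SubjectRecord:
    """One (synthetic or real) night of data."""

    subject_id: str
    age: float
    bmi: float
    sex: str
    ecg: SampledSignal | None
    effort: SampledSignal | None
    beat_times: np.ndarray
    events: EventList
    hypnogram: Hypnogram
    position: CategoricalTrack
    lights_off_s: float
    lights_on_s: float
    reference_ahi: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.validate()

    @property
    def duration(self) -> float:
        return self.hypnogram.duration

    def validate(self) -> None:
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if not (self.lights_off_s < self.lights_on_s <= self.duration + 1e-6):
            raise ValueError("requires lights_off < lights_on <= duration")
        tst_h = self.hypnogram.total_sleep_time_s() / 3600.0
        if tst_h > 0:
            expect = len(self.events) / tst_h
            if abs(expect - self.reference_ahi) > 1e-6:
                raise ValueError(
                    f"reference_ahi {self.reference_ahi} inconsistent with "
                    f"{len(self.events)} events over {tst_h:.3f} h sleep"
                )
        elif len(self.events):
            raise ValueError("events present but total sleep time is zero")
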