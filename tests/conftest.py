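import numpy as np
import pytest

from sdbdetect.core import Event, EventList, Hypnogram
from sdbdetect.preprocess import preprocess_record
from sdbdetect.synthgen import SimConfig, generate_subject


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_config():
    return SimConfig(duration_s=1800.0, ectopic_per_hour=0.0, seed=5)


@pytest.fixture(scope="session")
def short_record(short_config):
    """A 30-minute synthetic night with signals, moderate severity."""
    return generate_subject(short_config, 5, severity="moderate", subject_id="SREC")


@pytest.fixture(scope="session")
def short_channels(short_record):
    return preprocess_record(
        short_record.ecg, short_record.effort, duration_s=short_record.duration
    )


@pytest.fixture()
def all_sleep_hypnogram():
    def make(duration_s: float) -> Hypnogram:
        return Hypnogram(["N2"] * int(np.ceil(duration_s / 30.0)))

    return make


def oracle_strict(detected, annotated):
    """Independent O(n^2) matrix-based implementation of the strict rule."""
    det = list(detected)
    ann = list(annotated)
    overlap = [[d.start_s < a.end_s and a.start_s < d.end_s for d in det] for a in ann]
    used = set()
    tp = 0
    for i in range(len(ann)):
        candidates = [
            (det[j].start_s, j) for j in range(len(det)) if overlap[i][j] and j not in used
        ]
        if candidates:
            used.add(min(candidates)[1])
            tp += 1
    return tp, len(det) - len(used), len(ann) - tp


def oracle_olsen(detected, annotated):
    """Independent any-overlap implementation of the permissive rule."""
    det = list(detected)
    ann = list(annotated)
    overlap = [[d.start_s < a.end_s and a.start_s < d.end_s for d in det] for a in ann]
    tp = sum(1 for j in range(len(det)) if any(overlap[i][j] for i in range(len(ann))))
    fn = sum(1 for i in range(len(ann)) if not any(overlap[i]))
    return tp, len(det) - tp, fn


def random_events(rng, n, span=3600.0, typed=False, max_len=60.0):
    """Sorted non-overlapping random intervals for matcher tests."""
    types = ["hypopnea", "obstructive", "central", "mixed"]
    starts = np.sort(rng.uniform(0, span, size=n))
    events = []
    prev_end = -1.0
    for s in starts:
        s = max(s, prev_end + rng.uniform(0.5, 5.0))
        length = rng.uniform(1.0, max_len)
        if s + length > span + 200:
            continue
        typ = str(rng.choice(types)) if typed else None
        events.append(Event(round(s, 2), round(s + length, 2), typ))
        prev_end = events[-1].end_s
    return EventList(events)
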