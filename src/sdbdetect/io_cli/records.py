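"""SubjectRecord persistence: EDF for signals, CSV for annotations, JSON
for metadata."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from ..core import (
    EVENT_TYPES,
    CategoricalTrack,
    Event,
    EventList,
    Hypnogram,
    SampledSignal,
    SubjectRecord,
)
from .edf import read_edf, write_edf

ECG_LABEL = "ECG"
EFFORT_LABEL = "Effort"


def write_record(record: SubjectRecord, out_dir: str | Path) -> dict[str, Path]:
    """Write one record into ``out_dir``; returns the path of each artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    channels: dict[str, SampledSignal] = {}
    if record.ecg is not None:
        channels[ECG_LABEL] = record.ecg
    if record.effort is not None:
        channels[EFFORT_LABEL] = record.effort
    if channels:
        paths["edf"] = out / "signals.edf"
        write_edf(paths["edf"], channels, patient_id=record.subject_id)

    paths["events"] = out / "events.csv"
    with open(paths["events"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["start_s", "end_s", "type"])
        for e in record.events:
            w.writerow([f"{e.start_s:.3f}", f"{e.end_s:.3f}", e.type])

    paths["hypnogram"] = out / "hypnogram.csv"
    with open(paths["hypnogram"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["epoch", "stage"])
        for i, st in enumerate(record.hypnogram.stages):
            w.writerow([i, st])

    paths["position"] = out / "position.csv"
    with open(paths["position"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["second", "position"])
        for i, lab in enumerate(record.position.labels):
            w.writerow([i, lab])

    paths["beats"] = out / "beats.csv"
    with open(paths["beats"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["time_s"])
        for t in record.beat_times:
            w.writerow([f"{t:.4f}"])

    paths["meta"] = out / "meta.json"
    with open(paths["meta"], "w") as f:
        json.dump(
            {
                "subject_id": record.subject_id,
                "age": record.age,
                "bmi": record.bmi,
                "sex": record.sex,
                "lights_off_s": record.lights_off_s,
                "lights_on_s": record.lights_on_s,
                "epoch_s": record.hypnogram.epoch_s,
                "reference_ahi": record.reference_ahi,
            },
            f,
            indent=1,
        )
    return paths


def _read_events(path: Path) -> EventList:
    events = []
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                start, end = float(row["start_s"]), float(row["end_s"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row {i}: {row}") from exc
            if end <= start:
                raise ValueError(f"{path}: row {i}: event end {end} <= start {start}")
            typ = row.get("type") or None
            if typ is not None and typ not in EVENT_TYPES:
                raise ValueError(f"{path}: row {i}: unknown event type {typ!r}")
            events.append(Event(start, end, typ))
    try:
        return EventList(events)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_record(record_dir: str | Path) -> SubjectRecord:
    """Read a record written by :func:`write_record`."""
    d = Path(record_dir)
    with open(d / "meta.json") as f:
        meta = json.load(f)

    ecg = effort = None
    if (d / "signals.edf").exists():
        channels = read_edf(d / "signals.edf")
        if ECG_LABEL not in channels:
            raise ValueError(f"{d}: EDF is missing the {ECG_LABEL!r} channel")
        ecg = channels[ECG_LABEL]
        effort = channels.get(EFFORT_LABEL)

    events = _read_events(d / "events.csv")

    stages = []
    with open(d / "hypnogram.csv", newline="") as f:
        for i, row in enumerate(csv.DictReader(f), start=2):
            if "stage" not in row or row["stage"] is None:
                raise ValueError(f"{d}/hypnogram.csv: malformed row {i}")
            stages.append(row["stage"])
    hyp = Hypnogram(stages, meta.get("epoch_s", 30.0))

    labels = []
    with open(d / "position.csv", newline="") as f:
        for row in csv.DictReader(f):
            labels.append(row["position"])

    beats = []
    with open(d / "beats.csv", newline="") as f:
        for row in csv.DictReader(f):
            beats.append(float(row["time_s"]))

    return SubjectRecord(
        subject_id=meta["subject_id"],
        age=meta["age"],
        bmi=meta["bmi"],
        sex=meta["sex"],
        ecg=ecg,
        effort=effort,
        beat_times=np.asarray(beats),
        events=events,
        hypnogram=hyp,
        position=CategoricalTrack(labels),
        lights_off_s=meta["lights_off_s"],
        lights_on_s=meta["lights_on_s"],
        reference_ahi=meta["reference_ahi"],
    )
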