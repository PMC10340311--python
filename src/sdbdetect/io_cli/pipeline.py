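"""End-to-end experiment: simulate -> preprocess -> split -> train (both
input pairings) -> threshold selection -> test evaluation -> agreement
report.  Every stage draws its randomness from one root seed."""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .. import agreement as agr
from .. import detection as det
from ..core import SubjectRecord
from ..dataset import Segment, build_segments, stratified_split
from ..model import build_model, predict_segments, train_model
from ..preprocess import preprocess_record
from ..synthgen import generate_cohort
from .config import PipelineConfig

log = logging.getLogger(__name__)

PAIRINGS = ("rr+edr", "rr+re")


def _night_prediction(
    model, segments: Sequence[Segment], record: SubjectRecord
) -> det.NightPrediction:
    probs = predict_segments(model, segments)
    pred = det.stitch_predictions(
        probs,
        [s.start_s for s in segments],
        (record.lights_off_s, record.lights_on_s),
        subject_id=record.subject_id,
    )
    return det.mask_wake(pred, record.hypnogram)


def _ensure_nonempty_split(assign: dict[str, str], order: Sequence[str]) -> dict[str, str]:
    """Tiny cohorts can produce empty validation/test sets; repair by moving
    train subjects (deterministically) so each set has at least one."""
    assign = dict(assign)
    for needed in ("test", "validation"):
        if needed not in assign.values():
            donor = next(sid for sid in order if assign[sid] == "train")
            log.warning("split left %s empty; moving %s from train", needed, donor)
            assign[donor] = needed
    if "train" not in assign.values():
        raise ValueError("cohort too small to form a train/validation/test split")
    return assign


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full experiment; returns the experiment directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    root = np.random.SeedSequence(config.seed)
    s_cohort, s_split, s_model, s_train = (int(s.generate_state(1)[0]) for s in root.spawn(4))

    log.info("stage simulate: %d subjects", config.sim.n_subjects)
    cohort = generate_cohort(config.sim.n_subjects, None, config.sim, seed=s_cohort)

    log.info("stage preprocess")
    channels = {}
    for rec in cohort:
        try:
            channels[rec.subject_id] = preprocess_record(
                rec.ecg, rec.effort, config.preprocess, duration_s=rec.duration
            )
        except Exception as exc:
            raise RuntimeError(f"stage preprocess failed for {rec.subject_id}: {exc}") from exc

    assign = stratified_split(cohort, config.split_fractions, seed=s_split)
    assign = _ensure_nonempty_split(assign, [r.subject_id for r in cohort])
    by_set: dict[str, list[SubjectRecord]] = {"train": [], "validation": [], "test": []}
    for rec in cohort:
        by_set[assign[rec.subject_id]].append(rec)
    log.info(
        "split: %d train / %d validation / %d test",
        *(len(by_set[s]) for s in ("train", "validation", "test")),
    )

    report: dict[str, object] = {
        "seed": config.seed,
        "split": assign,
        "n_subjects": len(cohort),
        "pairings": {},
    }
    per_subject_rows = []

    for pairing in PAIRINGS:
        log.info("stage train: %s", pairing)
        segs = {
            rec.subject_id: build_segments(rec, channels[rec.subject_id], pairing)
            for rec in cohort
        }
        train_segs = [s for rec in by_set["train"] for s in segs[rec.subject_id]]
        val_segs = [s for rec in by_set["validation"] for s in segs[rec.subject_id]]
        model = build_model(replace(config.model), seed=s_model)
        tcfg = replace(config.train, seed=s_train)
        model, history = train_model(model, train_segs, val_segs, tcfg)
        model.save(out / f"model_{pairing.replace('+', '_')}.npz")
        with open(out / f"history_{pairing.replace('+', '_')}.csv", "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["epoch", "train_loss", "val_loss"])
            for i, (tl, vl) in enumerate(zip(history["train_loss"], history["val_loss"]), 1):
                w.writerow([i, f"{tl:.6f}", f"{vl:.6f}"])

        if config.evaluation.auto_threshold:
            val_nights = [
                (_night_prediction(model, segs[r.subject_id], r), r.events)
                for r in by_set["validation"]
            ]
            sel = det.select_threshold(val_nights)
            threshold = sel.chosen
        else:
            threshold = config.evaluation.threshold
        log.info("stage evaluate: %s at threshold %.3f", pairing, threshold)

        matches = {"strict": [], "olsen": []}
        ahi_pairs = []
        hyps, positions = [], []
        for rec in by_set["test"]:
            pred = _night_prediction(model, segs[rec.subject_id], rec)
            for rule in ("strict", "olsen"):
                matches[rule].append(det.evaluate_night(pred, rec.events, threshold, rule))
            detected = det.binarize_events(pred, threshold)
            ahi_pairs.append(
                agr.AhiPair(
                    rec.subject_id,
                    agr.compute_ahi(len(detected), rec.hypnogram),
                    rec.reference_ahi,
                    age=rec.age,
                    bmi=rec.bmi,
                )
            )
            hyps.append(rec.hypnogram)
            positions.append(rec.position)

        pairing_report: dict[str, object] = {"threshold": threshold, "history": history}
        for rule in ("strict", "olsen"):
            m = det.detection_metrics(matches[rule])
            pairing_report[rule] = {
                "per_subject_mean": m.per_subject_mean,
                "per_subject_sd": m.per_subject_sd,
                "pooled": m.pooled,
            }
        pairing_report["detection_rate_by_type"] = det.detection_rate_by_type(matches["strict"])
        pairing_report["sensitivity_by_stage"] = det.stratified_detection_rate(matches["strict"], hyps)
        pairing_report["sensitivity_by_position"] = det.stratified_detection_rate(
            matches["strict"], positions
        )
        pairing_report["event_length"] = det.event_length_summary(matches["strict"])
        try:
            zones = agr.NBLZones(config.evaluation.nbl_zones)
            pairing_report["agreement"] = {
                "bland_altman": agr.bland_altman(ahi_pairs),
                "spearman": agr.spearman_r(ahi_pairs),
                "spearman_ahi_lt_30": _maybe(agr.spearman_r, ahi_pairs, 30.0),
                "icc": agr.icc_two_way(ahi_pairs) if len(ahi_pairs) >= 5 else None,
                "severity": _maybe(agr.severity_report, ahi_pairs, zones),
                "covariates": agr.covariate_error_correlation(ahi_pairs),
            }
        except ValueError as exc:
            log.warning("agreement statistics skipped: %s", exc)
            pairing_report["agreement"] = None
        report["pairings"][pairing] = pairing_report  # type: ignore[index]

        for rec, m, pair in zip(by_set["test"], matches["strict"], ahi_pairs):
            sens = m.tp / (m.tp + m.fn) if m.tp + m.fn else ""
            prec = m.tp / (m.tp + m.fp) if m.tp + m.fp else ""
            per_subject_rows.append(
                [pairing, rec.subject_id, m.tp, m.fp, m.fn, sens, prec, pair.ahi_est, pair.ahi_ref]
            )

    with open(out / "per_subject.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["pairing", "subject", "tp", "fp", "fn", "sensitivity", "precision", "ahi_est", "ahi_ref"])
        w.writerows(per_subject_rows)
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=1, default=_jsonable)
    log.info("experiment written to %s", out)
    return out


def _maybe(fn, *args):
    try:
        return fn(*args)
    except ValueError:
        return None


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
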