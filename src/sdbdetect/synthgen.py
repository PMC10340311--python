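"""Synthetic annotated cardiorespiratory night generator.

Produces whole-night records carrying the physiological structure a
cardiorespiratory SDB detector exploits:

* beat-to-beat intervals with a bradycardia--tachycardia excursion locked to
  respiratory events,
* QRS amplitudes modulated by the instantaneous respiratory effort (the
  substrate for ECG-derived respiration),
* an effort belt whose amplitude is reduced or suppressed inside events
  (type-dependent depth),
* a 30-s-epoch hypnogram, a per-second body-position track, lights-off/on
  edges, and demographics.

Everything is driven by a single seed so a cohort is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    EVENT_TYPES,
    POSITIONS,
    CategoricalTrack,
    Event,
    EventList,
    Hypnogram,
    SampledSignal,
    SubjectRecord,
)

SEVERITY_CLASSES = ("normal", "mild", "moderate", "severe")

#: target-AHI sampling bands per severity class, kept well inside the
#: canonical 5/15/30 boundaries so realized class membership is unambiguous
DEFAULT_AHI_BANDS: dict[str, tuple[float, float]] = {
    "normal": (0.5, 4.0),
    "mild": (7.0, 13.0),
    "moderate": (17.0, 28.0),
    "severe": (32.0, 50.0),
}


@dataclass
class StageParams:
    edge_wake_epochs: int = 4
    mean_bout_epochs: Mapping[str, float] = field(
        default_factory=lambda: {"W": 2.0, "N1": 2.0, "N2": 8.0, "N3": 6.0, "REM": 5.0}
    )
    transitions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "W": {"N1": 0.8, "N2": 0.2},
            "N1": {"N2": 0.7, "REM": 0.2, "W": 0.1},
            "N2": {"N3": 0.35, "REM": 0.3, "N1": 0.15, "W": 0.2},
            "N3": {"N2": 0.8, "W": 0.2},
            "REM": {"N2": 0.5, "N1": 0.3, "W": 0.2},
        }
    )


@dataclass
class SimConfig:
    """Knobs for one synthetic cohort. ``seed`` fixes the whole cohort."""

    n_subjects: int = 20
    duration_s: float = 10800.0
    ahi_bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AHI_BANDS)
    )
    event_mix: tuple[float, float, float, float] = (0.55, 0.20, 0.15, 0.10)
    event_dur_log_mean: float = 3.2
    event_dur_log_sd: float = 0.35
    min_event_s: float = 10.0
    max_event_s: float = 120.0
    min_gap_s: float = 5.0
    base_hr_bpm: float = 62.0
    hr_slow_amp_bpm: float = 2.5
    hr_excursion_bpm: float = 12.0
    rr_jitter_s: float = 0.006
    ectopic_per_hour: float = 2.0
    resp_rate_hz: float = 0.25
    effort_depths: Mapping[str, float] = field(
        default_factory=lambda: {"hypopnea": 0.5, "obstructive": 0.4, "central": 0.05}
    )
    recovery_overshoot: float = 1.35
    recovery_tau_s: float = 6.0
    ecg_mod_depth: float = 0.15
    ecg_amp: float = 1.0
    qrs_sigma_s: float = 0.012
    ecg_baseline_amp: float = 0.05
    ecg_noise_sd: float = 0.01
    effort_noise_sd: float = 0.03
    ecg_fs: float = 256.0
    effort_fs: float = 32.0
    lights_off_s: float = 60.0
    lights_margin_s: float = 60.0
    age_range: tuple[float, float] = (18.0, 86.0)
    bmi_range: tuple[float, float] = (18.6, 45.2)
    stage_params: StageParams = field(default_factory=StageParams)
    render_signals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.event_mix) - 1.0) > 1e-9:
            raise ValueError("event mix fractions must sum to 1")
        if not 30.0 <= self.base_hr_bpm <= 180.0:
            raise ValueError("base heart rate must be in [30, 180] bpm")
        if not 0.1 <= self.resp_rate_hz <= 0.5:
            raise ValueError("respiratory rate must be in [0.1, 0.5] Hz")
        for name in ("hr_excursion_bpm", "ectopic_per_hour", "ecg_mod_depth",
                     "ecg_noise_sd", "effort_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class InfeasibleDensityError(ValueError):
    """Requested event rate cannot be realized within the available sleep."""


# ---------------------------------------------------------------------------
# event planting


def plant_events(
    duration_s: float,
    target_ahi: float,
    mix: Sequence[float],
    dur_params: tuple[float, float],
    sleep_mask: np.ndarray,
    seed: int | np.random.Generator,
    *,
    min_event_s: float = 10.0,
    max_event_s: float = 120.0,
    min_gap_s: float = 5.0,
) -> EventList:
    """Place non-overlapping typed events in sleep at a known rate.

    ``sleep_mask`` is a per-second boolean array; events are placed wholly
    inside runs of True, separated by at least ``min_gap_s``.  The number of
    events is ``round(target_ahi * sleep_hours)`` so the realized AHI against
    the same mask matches the target up to rounding.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if target_ahi < 0:
        raise ValueError("target AHI must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sleep_mask = np.asarray(sleep_mask, dtype=bool)
    sleep_h = sleep_mask.sum() / 3600.0
    count = int(round(target_ahi * sleep_h))
    if count == 0:
        return EventList([], min_duration=min_event_s)

    mu, sigma = dur_params
    durations = np.clip(rng.lognormal(mu, sigma, size=count), min_event_s, max_event_s)
    types = rng.choice(EVENT_TYPES, size=count, p=np.asarray(mix, dtype=float))

    # maximal sleep bouts as (start, length) in seconds
    padded = np.r_[False, sleep_mask, False].astype(int)
    edges = np.flatnonzero(np.diff(padded))
    bouts = [(int(s), int(e - s)) for s, e in zip(edges[::2], edges[1::2])]
    capacity = np.array([length for _, length in bouts], dtype=float)
    if durations.sum() + count * min_gap_s > capacity.sum():
        raise InfeasibleDensityError(
            f"cannot fit {count} events totalling {durations.sum():.0f}s "
            f"into {capacity.sum():.0f}s of sleep"
        )

    # assign each event to a bout with room, probability ~ remaining capacity
    assignment: list[list[int]] = [[] for _ in bouts]
    order = rng.permutation(count)
    for i in order:
        cost = durations[i] + min_gap_s
        ok = np.flatnonzero(capacity >= cost)
        if ok.size == 0:
            raise InfeasibleDensityError(
                "event density infeasible: no sleep bout has room left"
            )
        p = capacity[ok] / capacity[ok].sum()
        j = int(rng.choice(ok, p=p))
        assignment[j].append(int(i))
        capacity[j] -= cost

    events: list[Event] = []
    for (bout_start, bout_len), idxs in zip(bouts, assignment):
        if not idxs:
            continue
        # random left-to-right layout: Dirichlet spacing of the free slack
        idxs = [idxs[k] for k in rng.permutation(len(idxs))]
        k = len(idxs)
        slack = bout_len - durations[idxs].sum() - (k - 1) * min_gap_s
        extra = rng.dirichlet(np.ones(k + 1)) * max(slack, 0.0)
        t = bout_start + extra[0]
        for i, ei in zip(idxs, extra[1:]):
            t_end = t + durations[i]
            events.append(Event(round(t, 3), round(t_end, 3), str(types[i])))
            t = t_end + min_gap_s + ei

    return EventList(events, min_duration=min_event_s - 1e-3)


# ---------------------------------------------------------------------------
# hypnogram / position


def generate_hypnogram(
    duration_s: float,
    stage_params: StageParams | None = None,
    seed: int | np.random.Generator = 0,
    epoch_s: float = 30.0,
) -> Hypnogram:
    """Semi-Markov stage sequence with wake forced at both edges."""
    if duration_s < epoch_s:
        raise ValueError("duration must cover at least one epoch")
    sp = stage_params or StageParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_epochs = int(math.ceil(duration_s / epoch_s))
    edge = min(sp.edge_wake_epochs, n_epochs // 2)
    stages: list[str] = ["W"] * edge
    cur = "W"
    while len(stages) < n_epochs - edge:
        nxt = sp.transitions.get(cur, {"N1": 1.0})
        names, probs = zip(*nxt.items())
        cur = str(rng.choice(names, p=np.asarray(probs) / sum(probs)))
        mean_bout = sp.mean_bout_epochs.get(cur, 4.0)
        bout = 1 + rng.geometric(1.0 / max(mean_bout, 1.0))
        stages.extend([cur] * int(bout))
    stages = stages[: n_epochs - edge] + ["W"] * edge
    return Hypnogram(stages, epoch_s)


def generate_position_track(
    duration_s: float,
    params: Mapping[str, object] | None = None,
    seed: int | np.random.Generator = 0,
) -> CategoricalTrack:
    params = dict(params or {})
    positions = list(params.get("positions", POSITIONS))
    mean_bout_s = float(params.get("mean_bout_s", 1800.0))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(math.ceil(duration_s))
    labels: list[str] = []
    cur = str(rng.choice(positions))
    while len(labels) < n:
        bout = int(max(1, rng.exponential(mean_bout_s))) if len(positions) > 1 else n
        labels.extend([cur] * bout)
        if len(positions) > 1:
            others = [p for p in positions if p != cur]
            cur = str(rng.choice(others))
    return CategoricalTrack(labels[:n])


# ---------------------------------------------------------------------------
# signals


def _event_hr_profile(
    t: np.ndarray, events: EventList, excursion_bpm: float
) -> np.ndarray:
    """Heart-rate offset: bradycardia during each event, tachycardia after."""
    delta = np.zeros_like(t)
    for e in events:
        inside = (t >= e.start_s) & (t < e.end_s)
        # ramp down into bradycardia over the event
        frac = np.clip((t[inside] - e.start_s) / max(e.duration, 1.0), 0, 1)
        delta[inside] -= excursion_bpm * (0.3 + 0.7 * frac)
        after = (t >= e.end_s) & (t < e.end_s + 15.0)
        delta[after] += excursion_bpm * np.exp(-(t[after] - e.end_s) / 5.0)
    return delta


def generate_beat_times(
    duration_s: float,
    hr_params: Mapping[str, float],
    events: EventList,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Strictly increasing beat times with event-locked cyclic HR variation."""
    base = float(hr_params.get("base_hr_bpm", 60.0))
    if not 30.0 <= base <= 180.0:
        raise ValueError("base heart rate must be in [30, 180] bpm")
    slow_amp = float(hr_params.get("hr_slow_amp_bpm", 2.5))
    excursion = float(hr_params.get("hr_excursion_bpm", 12.0))
    jitter = float(hr_params.get("rr_jitter_s", 0.0))
    ectopic_rate = float(hr_params.get("ectopic_per_hour", 0.0))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    grid = np.arange(0.0, duration_s, 1.0)
    phase = rng.uniform(0, 2 * np.pi)
    hr = base + slow_amp * np.sin(2 * np.pi * 0.02 * grid + phase)
    hr = hr + _event_hr_profile(grid, events, excursion)
    hr = np.clip(hr, 25.0, 200.0)

    beats = []
    t = float(rng.uniform(0, 0.5))
    while t < duration_s:
        beats.append(t)
        hr_t = hr[min(int(t), grid.size - 1)]
        rr = 60.0 / hr_t + (jitter * rng.standard_normal() if jitter else 0.0)
        t += max(rr, 0.25)
    times = np.asarray(beats)

    n_ect = rng.poisson(ectopic_rate * duration_s / 3600.0) if ectopic_rate > 0 else 0
    if n_ect and times.size > 3:
        idx = rng.choice(times.size - 2, size=min(n_ect, times.size // 4), replace=False) + 1
        extra = times[idx] + 0.4 * (times[idx + 1] - times[idx])
        times = np.sort(np.concatenate([times, extra]))
        # enforce strict monotonicity after insertion
        times = times[np.r_[True, np.diff(times) > 1e-4]]
    return times


def render_ecg(
    beat_times: np.ndarray,
    resp_signal: SampledSignal,
    params: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> SampledSignal:
    """Gaussian-template QRS train whose amplitude is modulated by respiration.

    The respiration channel is normalized to roughly [-1, 1] before
    modulation so the depth parameter has a stable meaning.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        raise ValueError("cannot render ECG from an empty beat list")
    p = dict(params or {})
    fs = float(p.get("ecg_fs", 256.0))
    if fs < 100.0:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    amp = float(p.get("ecg_amp", 1.0))
    depth = float(p.get("ecg_mod_depth", 0.15))
    sigma = float(p.get("qrs_sigma_s", 0.012))
    wander = float(p.get("ecg_baseline_amp", 0.05))
    noise = float(p.get("ecg_noise_sd", 0.01))
    duration = float(p.get("duration_s", resp_signal.duration))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    scale = np.percentile(np.abs(resp_signal.values), 95)
    resp_norm = resp_signal.values / scale if scale > 0 else resp_signal.values
    r_at_beat = np.interp(beat_times, resp_signal.times(), resp_norm)
    amps = amp * (1.0 + depth * r_at_beat)

    n = int(round(duration * fs))
    sig = np.zeros(n)
    half = int(round(4 * sigma * fs))
    tmpl_idx = np.arange(-half, half + 1)
    tmpl = np.exp(-0.5 * (tmpl_idx / (sigma * fs)) ** 2)
    centers = np.round(beat_times * fs).astype(int)
    for c, a in zip(centers, amps):
        lo, hi = c - half, c + half + 1
        s = max(lo, 0)
        e = min(hi, n)
        if s < e:
            sig[s:e] += a * tmpl[s - lo : e - lo]

    t = np.arange(n) / fs
    if wander:
        sig += wander * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
        sig += wander * 0.5 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    if noise:
        sig += noise * rng.standard_normal(n)
    return SampledSignal(sig, fs)


def generate_respiratory_effort(
    duration_s: float,
    events: EventList,
    resp_params: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> SampledSignal:
    """Quasi-sinusoidal effort with per-type suppression inside events.

    Default in-event amplitude scale factors: central 0.05, obstructive 0.4,
    hypopnea 0.5; mixed events run the central factor over their first half
    and the obstructive factor over the second.  A configurable recovery
    overshoot follows each event.
    """
    p = dict(resp_params or {})
    fs = float(p.get("effort_fs", 32.0))
    rate = float(p.get("resp_rate_hz", 0.25))
    if not 0.1 <= rate <= 0.5:
        raise ValueError("respiratory rate must be in [0.1, 0.5] Hz")
    depths = {"hypopnea": 0.5, "obstructive": 0.4, "central": 0.05}
    depths.update(p.get("effort_depths", {}))
    overshoot = float(p.get("recovery_overshoot", 1.35))
    tau = float(p.get("recovery_tau_s", 6.0))
    noise = float(p.get("effort_noise_sd", 0.03))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = 2 * np.pi * rate * t + rng.uniform(0, 2 * np.pi)

    env = np.ones(n)
    for e in events:
        if e.type == "mixed":
            mid = 0.5 * (e.start_s + e.end_s)
            env[(t >= e.start_s) & (t < mid)] = depths["central"]
            env[(t >= mid) & (t < e.end_s)] = depths["obstructive"]
        else:
            env[(t >= e.start_s) & (t < e.end_s)] = depths.get(e.type or "hypopnea", 0.5)
        rec = (t >= e.end_s) & (t < e.end_s + 4 * tau)
        env[rec] = np.maximum(
            env[rec], 1.0 + (overshoot - 1.0) * np.exp(-(t[rec] - e.end_s) / tau)
        )

    slow = 1.0 + 0.08 * np.sin(2 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))
    sig = env * slow * np.sin(phase)
    if noise:
        sig += noise * rng.standard_normal(n)
    return SampledSignal(sig, fs)


# ---------------------------------------------------------------------------
# subjects and cohorts


def generate_subject(
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    severity: str | None = None,
    subject_id: str = "S000",
) -> SubjectRecord:
    """One internally consistent synthetic night."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(7)]
    r_hyp, r_evt, r_eff, r_beat, r_ecg, r_pos, r_demo = rngs

    duration = config.duration_s
    hyp = generate_hypnogram(duration, config.stage_params, r_hyp)
    lights_off = config.lights_off_s
    lights_on = duration - config.lights_margin_s

    n_sec = int(math.ceil(duration))
    mask = hyp.sleep_mask_seconds(n_sec)
    sec = np.arange(n_sec)
    mask &= (sec >= lights_off) & (sec < lights_on)

    severity = severity or str(r_demo.choice(SEVERITY_CLASSES))
    lo, hi = config.ahi_bands[severity]
    target_ahi = float(r_evt.uniform(lo, hi))
    events = plant_events(
        duration,
        target_ahi,
        config.event_mix,
        (config.event_dur_log_mean, config.event_dur_log_sd),
        mask,
        r_evt,
        min_event_s=config.min_event_s,
        max_event_s=config.max_event_s,
        min_gap_s=config.min_gap_s,
    )

    hr_params = {
        "base_hr_bpm": config.base_hr_bpm + float(r_demo.uniform(-8, 8)),
        "hr_slow_amp_bpm": config.hr_slow_amp_bpm,
        "hr_excursion_bpm": config.hr_excursion_bpm,
        "rr_jitter_s": config.rr_jitter_s,
        "ectopic_per_hour": config.ectopic_per_hour,
    }
    beat_times = generate_beat_times(duration, hr_params, events, r_beat)

    ecg = effort = None
    if config.render_signals:
        effort = generate_respiratory_effort(
            duration,
            events,
            {
                "effort_fs": config.effort_fs,
                "resp_rate_hz": config.resp_rate_hz,
                "effort_depths": dict(config.effort_depths),
                "recovery_overshoot": config.recovery_overshoot,
                "recovery_tau_s": config.recovery_tau_s,
                "effort_noise_sd": config.effort_noise_sd,
            },
            r_eff,
        )
        ecg = render_ecg(
            beat_times,
            effort,
            {
                "ecg_fs": config.ecg_fs,
                "ecg_amp": config.ecg_amp,
                "ecg_mod_depth": config.ecg_mod_depth,
                "qrs_sigma_s": config.qrs_sigma_s,
                "ecg_baseline_amp": config.ecg_baseline_amp,
                "ecg_noise_sd": config.ecg_noise_sd,
                "duration_s": duration,
            },
            r_ecg,
        )

    position = generate_position_track(duration, None, r_pos)
    tst_h = hyp.total_sleep_time_s() / 3600.0
    ahi = len(events) / tst_h if tst_h > 0 else 0.0

    return SubjectRecord(
        subject_id=subject_id,
        age=float(np.round(r_demo.uniform(*config.age_range), 1)),
        bmi=float(np.round(r_demo.uniform(*config.bmi_range), 1)),
        sex=str(r_demo.choice(["M", "F"])),
        ecg=ecg,
        effort=effort,
        beat_times=beat_times,
        events=events,
        hypnogram=hyp,
        position=position,
        lights_off_s=lights_off,
        lights_on_s=lights_on,
        reference_ahi=ahi,
    )


def generate_cohort(
    n: int,
    severity_mix: Mapping[str, int] | Sequence[int] | None = None,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> list[SubjectRecord]:
    """A cohort with requested per-class counts and unique subject ids."""
    config = config or SimConfig()
    seed = config.seed if seed is None else seed
    if severity_mix is None:
        base = n // 4
        counts = {c: base for c in SEVERITY_CLASSES}
        for c in SEVERITY_CLASSES[: n - 4 * base]:
            counts[c] += 1
    elif isinstance(severity_mix, Mapping):
        counts = {c: int(severity_mix.get(c, 0)) for c in SEVERITY_CLASSES}
    else:
        counts = dict(zip(SEVERITY_CLASSES, severity_mix))
    if sum(counts.values()) != n:
        raise ValueError("severity mix must account for every subject")

    root = np.random.SeedSequence(seed)
    seeds = root.spawn(n)
    cohort: list[SubjectRecord] = []
    i = 0
    for cls in SEVERITY_CLASSES:
        for _ in range(counts[cls]):
            cohort.append(
                generate_subject(config, seeds[i], severity=cls, subject_id=f"S{i:03d}")
            )
            i += 1
    return cohort


def severity_of(ahi: float) -> str:
    """Canonical class bands; boundary values go to the upper class."""
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"
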