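"""Raw ECG / effort channels -> the three 4 Hz model-input series.

Pipeline: R-peak detection (nonlinear transform + peak finding), ectopic-beat
flagging by a beat-to-beat rate-change limit, RR interpolation to 4 Hz with
artifact spans zeroed, a phase-space ECG-derived-respiration surrogate, and
anti-aliased resampling + 0.05 Hz high-pass for the effort belt.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .core import SampledSignal

log = logging.getLogger(__name__)

TARGET_FS = 4.0


@dataclass
class BeatSeries:
    """Beat times plus per-beat validity (artifact/ectopic = invalid)."""

    times: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.times.size != self.valid.size:
            raise ValueError("times and validity flags must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def detect_r_peaks(ecg: SampledSignal, params: Mapping[str, float] | None = None) -> BeatSeries:
    """Detect R peaks via band-pass -> squaring -> integration -> peak finding.

    Returns an all-valid :class:`BeatSeries`; a flat or silent signal yields
    zero beats rather than an error.  Peak locations are refined by parabolic
    interpolation on the band-passed signal.
    """
    p = dict(params or {})
    fs = ecg.fs
    if fs < 100:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    if ecg.duration < 10:
        raise ValueError("need at least 10 s of ECG")
    refractory_s = float(p.get("refractory_s", 0.25))
    rel_height = float(p.get("rel_height", 0.25))

    x = ecg.values - np.mean(ecg.values)
    if np.max(np.abs(x)) < 1e-9:
        return BeatSeries(np.empty(0), np.empty(0, dtype=bool))

    sos = sps.butter(3, [8.0, 30.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    nl = bp * bp
    win = max(int(round(0.10 * fs)), 1)
    integ = np.convolve(nl, np.ones(win) / win, mode="same")

    height = rel_height * np.percentile(integ, 99)
    if height <= 0:
        return BeatSeries(np.empty(0), np.empty(0, dtype=bool))
    locs, _ = sps.find_peaks(integ, height=height, distance=max(int(refractory_s * fs), 1))
    if locs.size == 0:
        return BeatSeries(np.empty(0), np.empty(0, dtype=bool))

    # snap to the local |bp| maximum, then parabolic sub-sample refinement
    half = int(round(0.05 * fs))
    times = []
    absbp = np.abs(bp)
    for c in locs:
        lo, hi = max(c - half, 0), min(c + half + 1, absbp.size)
        k = lo + int(np.argmax(absbp[lo:hi]))
        if 0 < k < absbp.size - 1:
            y0, y1, y2 = absbp[k - 1], absbp[k], absbp[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        times.append(ecg.t0 + (k + delta) / fs)
    times = np.asarray(times)
    keep = np.r_[True, np.diff(times) > refractory_s / 2]
    times = times[keep]
    return BeatSeries(times, np.ones(times.size, dtype=bool))


def reject_ectopic(beats: BeatSeries, limits: Mapping[str, float] | None = None) -> BeatSeries:
    """Flag beats whose interval jumps by more than ``rel_limit`` vs the last
    accepted interval (default +/-30% beat-to-beat). Times are unchanged."""
    if len(beats) < 3:
        raise ValueError("need at least 3 beats")
    rel_limit = float((limits or {}).get("rel_limit", 0.30))
    valid = beats.valid.copy()
    intervals = np.diff(beats.times)
    ref = intervals[0]
    for i, rr in enumerate(intervals):
        b = i + 1  # beat terminating this interval
        if not valid[b]:
            continue
        if abs(rr / ref - 1.0) > rel_limit:
            valid[b] = False
        else:
            ref = rr
    return BeatSeries(beats.times, valid)


def _grid(duration_s: float, fs: float = TARGET_FS) -> np.ndarray:
    n = int(math.ceil(duration_s * fs))
    return np.arange(n) / fs


def invalid_spans(beats: BeatSeries) -> list[tuple[float, float]]:
    """Enclosing inter-beat span [t_{i-1}, t_{i+1}) around each invalid beat."""
    spans = []
    for i in np.flatnonzero(~beats.valid):
        lo = beats.times[i - 1] if i > 0 else beats.times[i]
        hi = beats.times[i + 1] if i < len(beats) - 1 else beats.times[i]
        spans.append((lo, hi))
    return spans


def rr_series(
    beats: BeatSeries, duration_s: float | None = None, fs: float = TARGET_FS
) -> SampledSignal:
    """RR (s) at 4 Hz: linear interpolation between valid-beat interval
    midpoints; samples inside invalid spans are set exactly to 0."""
    vt = beats.times[beats.valid]
    if vt.size < 2:
        raise ValueError("need at least 2 valid beats for an RR series")
    duration_s = duration_s if duration_s is not None else beats.times[-1]
    t = _grid(duration_s, fs)
    mids = 0.5 * (vt[:-1] + vt[1:])
    rr = np.diff(vt)
    out = np.interp(t, mids, rr)
    for lo, hi in invalid_spans(beats):
        out[(t >= lo) & (t < hi)] = 0.0
    return SampledSignal(out, fs)


def extract_edr(
    ecg: SampledSignal,
    beats: BeatSeries,
    params: Mapping[str, float] | None = None,
    duration_s: float | None = None,
) -> SampledSignal:
    """Phase-space respiration surrogate from QRS morphology at 4 Hz.

    For each valid beat, the QRS (window +/-``qrs_half_s``) is delay-embedded
    in 2-D with delay ``delay_s`` and the area enclosed by the trajectory
    (shoelace formula) is the per-beat descriptor.  The per-beat series is
    linearly interpolated onto the common 4 Hz grid and linearly detrended.
    """
    p = dict(params or {})
    delay = int(round(float(p.get("delay_s", 0.020)) * ecg.fs))
    half = int(round(float(p.get("qrs_half_s", 0.060)) * ecg.fs))
    duration_s = duration_s if duration_s is not None else ecg.duration
    x = ecg.values

    vals, times = [], []
    for t_beat, ok in zip(beats.times, beats.valid):
        if not ok:
            continue
        c = int(round((t_beat - ecg.t0) * ecg.fs))
        lo, hi = c - half, c + half + delay + 1
        if lo < 0 or hi > x.size:
            log.debug("EDR: beat at %.3f s window exceeds signal bounds, skipped", t_beat)
            continue
        seg = x[lo:hi]
        a = seg[: seg.size - delay]
        b = seg[delay:]
        # closed-trajectory shoelace area in the (x(t), x(t+tau)) plane
        area = 0.5 * abs(np.dot(a, np.roll(b, -1)) - np.dot(b, np.roll(a, -1)))
        vals.append(area)
        times.append(t_beat)
    if len(vals) < 2:
        raise ValueError("too few usable beats for EDR extraction")

    grid = _grid(duration_s)
    edr = np.interp(grid, np.asarray(times), np.asarray(vals))
    edr = sps.detrend(edr, type="linear")
    return SampledSignal(edr, TARGET_FS)


def preprocess_effort(re_raw: SampledSignal, params: Mapping[str, float] | None = None) -> SampledSignal:
    """Anti-aliased polyphase resample to 4 Hz, then zero-phase 0.05 Hz
    high-pass (4th-order Butterworth, forward-backward)."""
    p = dict(params or {})
    cutoff = float(p.get("highpass_hz", 0.05))
    if re_raw.fs < TARGET_FS:
        raise ValueError("effort sampling rate must be >= 4 Hz")
    if re_raw.fs != TARGET_FS:
        frac = Fraction(TARGET_FS / re_raw.fs).limit_denominator(1000)
        y = sps.resample_poly(re_raw.values, frac.numerator, frac.denominator, padtype="line")
    else:
        y = re_raw.values.copy()
    sos = sps.butter(4, cutoff, btype="highpass", fs=TARGET_FS, output="sos")
    y = sps.sosfiltfilt(sos, y)
    return SampledSignal(y, TARGET_FS)


def _match_length(sig: SampledSignal, n: int) -> SampledSignal:
    v = sig.values
    if v.size > n:
        v = v[:n]
    elif v.size < n:
        v = np.r_[v, np.full(n - v.size, v[-1])]
    return SampledSignal(v, sig.fs, sig.t0)


def preprocess_record(
    ecg: SampledSignal,
    effort: SampledSignal | None,
    params: Mapping[str, object] | None = None,
    duration_s: float | None = None,
) -> dict[str, SampledSignal]:
    """Full front end: returns ``{"rr", "edr", "re"}`` on one 4 Hz grid."""
    p = dict(params or {})
    duration_s = duration_s if duration_s is not None else ecg.duration
    n = int(math.ceil(duration_s * TARGET_FS))

    beats = detect_r_peaks(ecg, p.get("rpeak"))  # type: ignore[arg-type]
    beats = reject_ectopic(beats, p.get("ectopic"))  # type: ignore[arg-type]
    out = {
        "rr": _match_length(rr_series(beats, duration_s), n),
        "edr": _match_length(extract_edr(ecg, beats, p.get("edr"), duration_s), n),  # type: ignore[arg-type]
    }
    if effort is not None:
        out["re"] = _match_length(preprocess_effort(effort, p.get("effort")), n)  # type: ignore[arg-type]
    return out
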