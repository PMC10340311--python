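import numpy as np
import pytest
from scipy import signal as sps

from sdbdetect.core import Event, EventList, Hypnogram
from sdbdetect.synthgen import (
    SEVERITY_CLASSES,
    InfeasibleDensityError,
    SimConfig,
    StageParams,
    generate_beat_times,
    generate_cohort,
    generate_hypnogram,
    generate_position_track,
    generate_respiratory_effort,
    generate_subject,
    plant_events,
    render_ecg,
    severity_of,
)

MIX = (0.55, 0.20, 0.15, 0.10)
DUR_PARAMS = (3.2, 0.35)


def full_sleep_mask(hours):
    return np.ones(int(hours * 3600), dtype=bool)


class TestPlantEvents:
    def test_zero_rate_empty(self):
        ev = plant_events(3600, 0.0, MIX, DUR_PARAMS, full_sleep_mask(1), 0)
        assert len(ev) == 0

    def test_count_matches_target(self):
        # 8 h of sleep at AHI 18 -> 18 * 8 = 144 events
        ev = plant_events(8 * 3600, 18.0, MIX, DUR_PARAMS, full_sleep_mask(8), 1)
        assert len(ev) == 144

    def test_degenerate_mix_all_hypopnea(self):
        ev = plant_events(3600, 20.0, (1, 0, 0, 0), DUR_PARAMS, full_sleep_mask(1), 2)
        assert len(ev) == 20
        assert all(e.type == "hypopnea" for e in ev)

    def test_events_only_in_sleep(self):
        mask = np.zeros(7200, dtype=bool)
        mask[1800:5400] = True  # one sleep hour in the middle
        ev = plant_events(7200, 10.0, MIX, DUR_PARAMS, mask, 3)
        for e in ev:
            assert e.start_s >= 1800 and e.end_s <= 5400

    def test_min_gap_respected(self):
        ev = plant_events(3600, 40.0, MIX, DUR_PARAMS, full_sleep_mask(1), 4, min_gap_s=5.0)
        for a, b in zip(ev, list(ev)[1:]):
            assert b.start_s - a.end_s >= 5.0 - 1e-6

    def test_infeasible_density_raises(self):
        with pytest.raises(InfeasibleDensityError):
            plant_events(3600, 200.0, MIX, DUR_PARAMS, full_sleep_mask(1), 5)

    def test_deterministic(self):
        a = plant_events(3600, 15.0, MIX, DUR_PARAMS, full_sleep_mask(1), 7)
        b = plant_events(3600, 15.0, MIX, DUR_PARAMS, full_sleep_mask(1), 7)
        assert a == b

    def test_rate_recovery_calibration(self):
        # mean absolute AHI error over 20 independent nights <= 2 events/h
        rng = np.random.default_rng(0)
        errs = []
        for k in range(20):
            target = float(rng.uniform(1, 45))
            hyp = generate_hypnogram(6 * 3600, seed=k)
            mask = hyp.sleep_mask_seconds(6 * 3600)
            ev = plant_events(6 * 3600, target, MIX, DUR_PARAMS, mask, 100 + k)
            realized = len(ev) / (mask.sum() / 3600.0)
            errs.append(abs(realized - target))
        assert np.mean(errs) <= 2.0


class TestHypnogramGen:
    def test_epoch_count(self):
        assert len(generate_hypnogram(600, seed=0)) == 20

    def test_all_wake_flagged_unusable(self):
        sp = StageParams(edge_wake_epochs=100)
        hyp = generate_hypnogram(600, sp, seed=0)
        assert hyp.total_sleep_time_s() == 0.0

    def test_deterministic(self):
        a = generate_hypnogram(3600, seed=3)
        b = generate_hypnogram(3600, seed=3)
        assert a.stages == b.stages

    def test_wake_at_edges_sleep_present(self):
        hyp = generate_hypnogram(2 * 3600, seed=1)
        assert hyp.stages[0] == "W" and hyp.stages[-1] == "W"
        assert hyp.total_sleep_time_s() > 0


class TestPositionTrack:
    def test_length(self):
        assert len(generate_position_track(120, seed=0)) == 120

    def test_single_position_constant(self):
        t = generate_position_track(300, {"positions": ["supine"]}, seed=0)
        assert set(t.labels) == {"supine"}

    def test_deterministic(self):
        a = generate_position_track(600, seed=9)
        b = generate_position_track(600, seed=9)
        assert a.labels == b.labels


class TestBeatTimes:
    def test_constant_rate_no_noise(self):
        params = {"base_hr_bpm": 60.0, "hr_slow_amp_bpm": 0.0, "rr_jitter_s": 0.0,
                  "ectopic_per_hour": 0.0}
        beats = generate_beat_times(60.0, params, EventList([]), seed=0)
        rr = np.diff(beats)
        assert np.allclose(rr, 1.0, atol=1e-9)

    def test_event_excursion_widens_rr_range(self):
        params = {"base_hr_bpm": 60.0, "hr_slow_amp_bpm": 0.0, "rr_jitter_s": 0.0,
                  "hr_excursion_bpm": 15.0, "ectopic_per_hour": 0.0}
        events = EventList([Event(100, 130, "obstructive")])
        beats = generate_beat_times(300.0, params, events, seed=0)
        rr = np.diff(beats)
        mids = 0.5 * (beats[:-1] + beats[1:])
        inside = (mids >= 100) & (mids < 145)  # event + tachycardic recovery
        assert inside.any() and (~inside).any()
        assert np.ptp(rr[inside]) > np.ptp(rr[~inside]) + 0.01

    def test_strictly_increasing_with_ectopics(self):
        params = {"base_hr_bpm": 70.0, "ectopic_per_hour": 30.0}
        beats = generate_beat_times(1800.0, params, EventList([]), seed=4)
        assert np.all(np.diff(beats) > 0)

    def test_no_ectopics_no_short_intervals(self):
        params = {"base_hr_bpm": 60.0, "hr_slow_amp_bpm": 1.0, "rr_jitter_s": 0.0,
                  "ectopic_per_hour": 0.0}
        beats = generate_beat_times(600.0, params, EventList([]), seed=2)
        assert np.diff(beats).min() > 0.8

    def test_bad_base_rate(self):
        with pytest.raises(ValueError):
            generate_beat_times(60.0, {"base_hr_bpm": 20.0}, EventList([]), 0)


def _sine_resp(duration, rate=0.25, fs=32.0):
    from sdbdetect.core import SampledSignal

    t = np.arange(int(duration * fs)) / fs
    return SampledSignal(np.sin(2 * np.pi * rate * t), fs)


class TestRenderEcg:
    def test_zero_depth_equal_amplitudes(self):
        beats = np.arange(0.5, 60.0, 1.0)
        resp = _sine_resp(60.0)
        ecg = render_ecg(beats, resp, {"ecg_mod_depth": 0.0, "ecg_noise_sd": 0.0,
                                       "ecg_baseline_amp": 0.0}, seed=0)
        peaks, _ = sps.find_peaks(ecg.values, height=0.5)
        assert np.ptp(ecg.values[peaks]) < 1e-6

    def test_beat_count_matches_maxima(self):
        beats = np.arange(0.5, 120.0, 0.8)
        resp = _sine_resp(120.0)
        ecg = render_ecg(beats, resp, {"ecg_mod_depth": 0.1, "ecg_noise_sd": 0.0,
                                       "ecg_baseline_amp": 0.0}, seed=0)
        peaks, _ = sps.find_peaks(ecg.values, height=0.5)
        assert peaks.size == beats.size

    def test_amplitude_modulation_carries_respiration(self):
        # periodogram of per-beat peak amplitudes peaks at the planted rate
        beats = np.arange(0.5, 600.0, 1.0)
        resp = _sine_resp(600.0, rate=0.25)
        ecg = render_ecg(beats, resp, {"ecg_mod_depth": 0.2, "ecg_noise_sd": 0.0,
                                       "ecg_baseline_amp": 0.0}, seed=0)
        idx = np.round(beats * ecg.fs).astype(int)
        amps = ecg.values[idx]
        amps = amps - amps.mean()
        # beats are 1 s apart -> uniform series at 1 Hz
        f, p = sps.periodogram(amps, fs=1.0)
        peak = f[np.argmax(p)]
        assert abs(peak - 0.25) <= 0.02

    def test_empty_beats_error(self):
        with pytest.raises(ValueError, match="empty beat"):
            render_ecg(np.array([]), _sine_resp(10.0), seed=0)


class TestRespiratoryEffort:
    def test_no_events_stable_envelope(self):
        eff = generate_respiratory_effort(600.0, EventList([]), {"effort_noise_sd": 0.0}, 0)
        # RMS over 30 s blocks should vary little
        v = eff.values[: 19 * 32 * 30].reshape(19, -1)
        rms = np.sqrt((v**2).mean(axis=1))
        assert rms.max() / rms.min() < 1.35

    @pytest.mark.parametrize(
        "etype,lo,hi",
        [("central", 0.0, 0.2), ("hypopnea", 0.3, 0.7), ("obstructive", 0.2, 0.6)],
    )
    def test_event_rms_ratio(self, etype, lo, hi):
        ev = EventList([Event(100, 120, etype)])
        eff = generate_respiratory_effort(300.0, ev, {"effort_noise_sd": 0.0}, 1)
        t = eff.times()
        inside = (t >= 100) & (t < 120)
        outside = (t < 90) | (t >= 140)  # exclude recovery overshoot
        ratio = np.sqrt((eff.values[inside] ** 2).mean()) / np.sqrt(
            (eff.values[outside] ** 2).mean()
        )
        assert lo <= ratio <= hi

    def test_mixed_event_two_phases(self):
        ev = EventList([Event(100, 140, "mixed")])
        eff = generate_respiratory_effort(300.0, ev, {"effort_noise_sd": 0.0}, 2)
        t = eff.times()
        first = np.sqrt((eff.values[(t >= 100) & (t < 120)] ** 2).mean())
        second = np.sqrt((eff.values[(t >= 120) & (t < 140)] ** 2).mean())
        assert first < second

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            generate_respiratory_effort(60.0, EventList([]), {"resp_rate_hz": 0.7}, 0)


class TestSubjectAndCohort:
    def test_deterministic_subject(self):
        cfg = SimConfig(duration_s=1500.0)
        a = generate_subject(cfg, 11, severity="mild")
        b = generate_subject(cfg, 11, severity="mild")
        assert np.array_equal(a.beat_times, b.beat_times)
        assert np.array_equal(a.ecg.values, b.ecg.values)
        assert np.array_equal(a.effort.values, b.effort.values)
        assert a.events == b.events
        assert a.hypnogram.stages == b.hypnogram.stages
        assert (a.age, a.bmi, a.sex) == (b.age, b.bmi, b.sex)

    def test_severe_target_exceeds_30(self):
        cfg = SimConfig(duration_s=3600.0, render_signals=False)
        rec = generate_subject(cfg, 3, severity="severe")
        assert rec.reference_ahi > 30

    def test_invariant_audit_random_configs(self):
        # constructor-level validation plus sleep placement, for many seeds
        for seed in range(50):
            cfg = SimConfig(duration_s=1500.0, render_signals=False, seed=seed)
            rec = generate_subject(cfg, seed)
            mask = rec.hypnogram.sleep_mask_seconds(int(rec.duration))
            for e in rec.events:
                assert mask[int(e.start_s) : int(np.ceil(e.end_s))].all()
                assert e.start_s >= rec.lights_off_s and e.end_s <= rec.lights_on_s

    def test_effort_separability_inside_events(self, short_record):
        eff = short_record.effort
        t = eff.times()
        inside = np.zeros(t.size, dtype=bool)
        near = np.zeros(t.size, dtype=bool)
        for e in short_record.events:
            inside |= (t >= e.start_s) & (t < e.end_s)
            near |= (t >= e.start_s - 30) & (t < e.end_s + 30)
        assert inside.sum() > 0
        rms_in = np.sqrt((eff.values[inside] ** 2).mean())
        rms_out = np.sqrt((eff.values[~near] ** 2).mean())
        assert rms_in < 0.7 * rms_out

    def test_cohort_counts_and_ids(self):
        cfg = SimConfig(duration_s=1500.0, render_signals=False)
        cohort = generate_cohort(20, (5, 5, 5, 5), cfg, seed=0)
        assert len({r.subject_id for r in cohort}) == 20
        counts = {c: 0 for c in SEVERITY_CLASSES}
        for r in cohort:
            counts[severity_of(r.reference_ahi)] += 1
        assert counts == {c: 5 for c in SEVERITY_CLASSES}

    def test_cohort_seeds_disjoint(self):
        cfg = SimConfig(duration_s=1500.0, render_signals=False)
        a = generate_cohort(4, (1, 1, 1, 1), cfg, seed=1)
        b = generate_cohort(4, (1, 1, 1, 1), cfg, seed=2)
        assert not np.array_equal(a[0].beat_times, b[0].beat_times)

    def test_mix_must_cover_n(self):
        with pytest.raises(ValueError):
            generate_cohort(5, (1, 1, 1, 1), SimConfig(render_signals=False), seed=0)
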