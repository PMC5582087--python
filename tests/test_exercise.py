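"""Stimulus schedule and exercise-success / exercise-share statistics."""

import numpy as np
import pytest

from damsleep import (
    StimulusSchedule,
    build_stimulus_schedule,
    call_death,
    exercise_share,
    exercise_success,
    fly_mean_success,
    group_success_summary,
    rebin,
    simulate_cohort,
)
from damsleep.simulate import GenotypeProfile, Peak

from conftest import make_series


def _window_counts_series(per_minute, days=1, baseline=0):
    """Counts = `per_minute` inside the daily ZT7-7.5 window, baseline elsewhere."""
    counts = np.full(days * 1440, baseline, dtype=int)
    for d in range(days):
        w0 = d * 1440 + 7 * 60
        counts[w0 : w0 + 30] = per_minute
    return make_series(counts)


def test_default_schedule_has_90_stimuli_within_window():
    sched = build_stimulus_schedule()
    assert sched.stimuli_per_day == 90
    zt = sched.stimulus_zt_hours()
    assert zt.size == 90
    assert (zt >= 7.0).all() and (zt < 7.5).all()


def test_zero_duration_schedule_is_empty():
    sched = build_stimulus_schedule(duration_minutes=0.0)
    assert sched.stimuli_per_day == 0
    assert sched.stimulus_offsets_minutes().size == 0


def test_one_per_minute_schedule_spacing():
    sched = build_stimulus_schedule(duration_minutes=10.0, stimuli_per_minute=1.0)
    offsets = sched.stimulus_offsets_minutes()
    assert offsets.size == 10
    assert np.allclose(np.diff(offsets), 1.0)  # 60 s apart


def test_non_integral_stimulus_count_rejected():
    with pytest.raises(ValueError):
        build_stimulus_schedule(duration_minutes=10.0, stimuli_per_minute=0.25)


def test_zero_counts_give_zero_success():
    s = _window_counts_series(0)
    assert exercise_success(s, StimulusSchedule(), day=1) == 0.0


def test_response_to_every_stimulus_gives_100():
    s = _window_counts_series(3)  # 3 counts/min = one per stimulus
    assert exercise_success(s, StimulusSchedule(), day=1) == 100.0


def test_capped_estimator_hand_case():
    # 1-min bins, 3 stimuli/min, constant 1 count/min over 30 min:
    # credited = 30 x min(1, 3) = 30 of 90 stimuli
    s = _window_counts_series(1)
    assert exercise_success(s, StimulusSchedule(), day=1) == pytest.approx(100 * 30 / 90)


def test_success_ignores_counts_outside_window():
    a = _window_counts_series(2, baseline=0)
    b = _window_counts_series(2, baseline=9)
    sched = StimulusSchedule()
    assert exercise_success(a, sched, 1) == exercise_success(b, sched, 1)


def test_fine_mode_with_minute_stimuli():
    # 1 stimulus/min -> 1-min bins resolve individual response windows
    sched = build_stimulus_schedule(duration_minutes=30.0, stimuli_per_minute=1.0)
    counts = np.zeros(1440, dtype=int)
    counts[7 * 60 : 7 * 60 + 30 : 2] = 1  # respond to every other stimulus
    s = make_series(counts)
    assert exercise_success(s, sched, 1, mode="fine") == pytest.approx(50.0)


def test_coarse_never_exceeds_fine_for_response_streams(rng):
    # for streams with at most one count per response window the capped
    # coarse estimator can only lose (cap) responses, never invent them
    sched = build_stimulus_schedule(duration_minutes=30.0, stimuli_per_minute=1.0)
    for _ in range(25):
        counts = np.zeros(1440, dtype=int)
        hits = rng.random(30) < rng.random()
        counts[7 * 60 : 7 * 60 + 30][hits] = 1
        fine = exercise_success(make_series(counts), sched, 1, mode="fine")
        coarse = exercise_success(rebin(make_series(counts), 5), sched, 1, mode="coarse")
        assert coarse <= fine + 1e-9


def test_fully_masked_window_gives_nan():
    s = _window_counts_series(3)
    mask = np.ones(s.n_bins, dtype=bool)
    mask[7 * 60 : 7 * 60 + 30] = False
    s = s.replace(mask=mask)
    assert np.isnan(exercise_success(s, StimulusSchedule(), 1))


def test_fly_mean_excludes_days_after_death():
    s = _window_counts_series(3, days=12)
    counts = s.counts.copy()
    counts[int(4.6 * 1440):] = 0  # dies during day 5
    s = s.replace(counts=counts)
    death = call_death(s)
    assert death.event
    mean, detail = fly_mean_success(s, StimulusSchedule(), death=death)
    assert detail.loc[detail["alive"], "day"].max() == 4
    assert mean == pytest.approx(100.0)  # all living days responded fully


def test_exercise_share_planted_ratio():
    counts = np.zeros(1440, dtype=int)
    counts[7 * 60 : 7 * 60 + 30] = 2           # 60 exercise-window counts
    # morning is clock 4-12 (ZT20-4), evening clock 16-22 (ZT8-14)
    counts[2 * 60 : 2 * 60 + 50] = 2           # ZT2 = clock 10:00, morning: 100 counts
    counts[10 * 60 : 10 * 60 + 50] = 2         # ZT10 = clock 18:00, evening: 100 counts
    s = make_series(counts)
    share, detail = exercise_share(s, StimulusSchedule(active_days=(1, 1)))
    assert share == pytest.approx(100.0 * 60 / 200)


def test_exercise_share_zero_window_counts():
    counts = np.zeros(1440, dtype=int)
    counts[2 * 60 : 2 * 60 + 50] = 2
    s = make_series(counts)
    share, _ = exercise_share(s, StimulusSchedule(active_days=(1, 1)))
    assert share == 0.0


def test_exercise_share_flags_zero_peak_days():
    s = _window_counts_series(3)
    share, detail = exercise_share(s, StimulusSchedule(active_days=(1, 1)))
    assert np.isnan(share)
    assert detail["flagged_zero_peaks"].all()


def test_group_summary_examples():
    single = group_success_summary([40.0])
    assert single["median"] == 40.0 and single["q1"] == single["q3"] == 40.0
    trio = group_success_summary([10.0, 20.0, 30.0])
    assert trio["median"] == 20.0


def test_success_monotone_in_response_probability(stimulus):
    base = GenotypeProfile(
        label="probe",
        baseline_rate=0.0,
        morning_peak=Peak(0.5, 0.8, 0.0),
        evening_peak=Peak(11.5, 0.8, 0.0),
        night_spikes_per_night=0.0,
        median_survival_days=1000.0,
    )
    medians = []
    for p in (0.1, 0.4, 0.8):
        import dataclasses

        prof = dataclasses.replace(base, p_resp=p)
        flies = simulate_cohort(prof, True, n_flies=4, days=3, seed=5)
        means = [fly_mean_success(f.series, stimulus)[0] for f in flies]
        medians.append(group_success_summary(means)["median"])
    assert medians[0] < medians[1] < medians[2]
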