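"""Sleep scoring: rebinning, bout detection, death calls, daily summaries."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from damsleep import (
    EpisodeWindows,
    call_death,
    detect_sleep_bouts,
    partition_episodes,
    rebin,
    summarize_daily,
)

from conftest import START, make_series


def brute_force_bouts(counts, mask, bin_minutes, threshold):
    """Independent maximal-zero-run scan (reference oracle)."""
    runs = []
    i, n = 0, len(counts)
    while i < n:
        if mask[i] and counts[i] == 0:
            j = i
            while j < n and mask[j] and counts[j] == 0:
                j += 1
            duration = (j - i) * bin_minutes
            if duration >= threshold:
                runs.append((i, duration))
            i = j
        else:
            i += 1
    return runs


def as_tuples(series, bouts):
    out = []
    for b in bouts:
        start_bin = (b.start - series.start).total_seconds() / 60 / series.bin_minutes
        out.append((int(start_bin), b.duration_minutes))
    return out


# ---------------------------------------------------------------------------
# rebin
# ---------------------------------------------------------------------------

def test_rebin_day_of_ones_gives_288_fives():
    s = make_series(np.ones(1440))
    r = rebin(s, 5)
    assert r.n_bins == 288
    assert (r.counts == 5).all()


def test_rebin_identity_and_errors():
    s = make_series(np.arange(60))
    assert (rebin(s, 1).counts == s.counts).all()
    with pytest.raises(ValueError):
        rebin(rebin(s, 5), 3)  # 3 not a multiple of 5


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 9), min_size=30, max_size=30))
def test_rebin_conserves_totals(values):
    s = make_series(values)
    for target in (2, 3, 5, 6):
        assert rebin(s, target).counts.sum() == s.counts.sum()


def test_rebin_masks_bin_if_any_subbin_masked():
    mask = np.ones(10, dtype=bool)
    mask[3] = False
    s = make_series(np.ones(10), mask=mask)
    r = rebin(s, 5)
    assert not r.mask[0] and r.mask[1]


# ---------------------------------------------------------------------------
# sleep bouts
# ---------------------------------------------------------------------------

def test_all_zero_day_is_one_long_bout():
    s = make_series(np.zeros(1440))
    bouts = detect_sleep_bouts(s)
    assert len(bouts) == 1
    assert bouts[0].duration_minutes == 1440
    assert bouts[0].bout_class == "long"


def test_four_minute_run_is_not_sleep():
    counts = np.ones(20)
    counts[8:12] = 0  # 4-min inactivity, below the 5-min rule
    assert detect_sleep_bouts(make_series(counts)) == []
    counts[8:13] = 0  # 5 min qualifies
    bouts = detect_sleep_bouts(make_series(counts))
    assert len(bouts) == 1 and bouts[0].duration_minutes == 5


def test_bout_class_boundary_at_60_minutes():
    counts = np.ones(200)
    counts[10:70] = 0  # exactly 60 min
    counts[100:161] = 0  # 61 min
    bouts = detect_sleep_bouts(make_series(counts))
    assert [b.bout_class for b in bouts] == ["short", "long"]


def test_bouts_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        counts = (rng.random(200) < 0.35).astype(int) * rng.integers(1, 5, 200)
        mask = rng.random(200) > 0.02
        s = make_series(counts, mask=mask)
        expected = brute_force_bouts(counts, mask, 1, 5)
        assert as_tuples(s, detect_sleep_bouts(s)) == expected


def test_five_minute_bins_score_single_zero_bin():
    counts = np.array([3, 0, 2, 0, 0, 1])
    s = make_series(counts, bin_minutes=5)
    bouts = detect_sleep_bouts(s)
    assert as_tuples(s, bouts) == [(1, 5.0), (3, 10.0)]


def test_threshold_monotonicity():
    rng = np.random.default_rng(7)
    for _ in range(30):
        counts = (rng.random(300) < 0.4).astype(int)
        s = make_series(counts)
        sleep5 = sum(b.duration_minutes for b in detect_sleep_bouts(s, 5))
        sleep10 = sum(b.duration_minutes for b in detect_sleep_bouts(s, 10))
        assert sleep10 <= sleep5


def test_all_masked_series_warns_and_returns_nothing():
    s = make_series(np.zeros(30), mask=np.zeros(30, dtype=bool))
    with pytest.warns(UserWarning):
        assert detect_sleep_bouts(s) == []


# ---------------------------------------------------------------------------
# death calls
# ---------------------------------------------------------------------------

def _terminal_zero_series(active_minutes, zero_hours):
    counts = np.ones(active_minutes + int(zero_hours * 60))
    counts[active_minutes:] = 0
    return make_series(counts)


def test_death_called_after_25h_terminal_immobility():
    s = _terminal_zero_series(600, 25)
    d = call_death(s)
    assert d.event
    assert d.time == START + dt.timedelta(minutes=600)  # end of last active bin


def test_23h_terminal_zeros_is_censored():
    s = _terminal_zero_series(600, 23)
    d = call_death(s)
    assert not d.event and d.time == s.end


def test_exactly_24h_is_censored_strict_boundary():
    d = call_death(_terminal_zero_series(600, 24))
    assert not d.event
    d = call_death(_terminal_zero_series(600, 24 + 1 / 60))
    assert d.event


def test_midseries_immobility_is_not_death():
    counts = np.ones(3 * 1440)
    counts[1000 : 1000 + 30 * 60] = 0  # 30 h mid-series, then resumed activity
    d = call_death(make_series(counts))
    assert not d.event


def test_death_call_stable_under_appending_zeros():
    s = _terminal_zero_series(600, 25)
    d1 = call_death(s)
    longer = make_series(np.concatenate([s.counts, np.zeros(500, dtype=int)]))
    d2 = call_death(longer)
    assert d1.event and d2.event and d1.time == d2.time


def test_never_active_fly_flagged():
    d = call_death(make_series(np.zeros(2 * 1440)))
    assert d.event and d.flag == "never_active" and d.time == START


# ---------------------------------------------------------------------------
# episodes and daily summaries
# ---------------------------------------------------------------------------

def test_windows_must_tile_24h():
    with pytest.raises(ValueError):
        EpisodeWindows(
            windows=(("night", 22 * 60, 4 * 60), ("rest", 4 * 60, 21 * 60))
        )


def test_fully_asleep_day_gives_window_lengths():
    s = make_series(np.zeros(3 * 1440))
    bouts = detect_sleep_bouts(s)
    part = partition_episodes(s, bouts)
    day2 = part[part["day"] == 2].set_index("episode")["sleep"]
    assert day2["night"] == 360
    assert day2["morning"] == 480
    assert day2["siesta"] == 240
    assert day2["evening"] == 360


def test_fully_active_day_has_zero_episode_sleep():
    s = make_series(np.ones(1440))
    part = partition_episodes(s, detect_sleep_bouts(s))
    assert (part["sleep"] == 0).all()
    assert part["activity"].sum() == 1440


def test_episode_totals_tile_daily_sleep(rng):
    counts = (rng.random(2 * 1440) < 0.3).astype(int)
    s = make_series(counts)
    bouts = detect_sleep_bouts(s)
    part = partition_episodes(s, bouts)
    total_sleep = sum(b.duration_minutes for b in bouts)
    assert part["sleep"].sum() == pytest.approx(total_sleep)
    assert part["sleep_short"].sum() + part["sleep_long"].sum() == pytest.approx(total_sleep)


def test_summary_death_on_day_8_of_20():
    counts = np.ones(20 * 1440)
    death_min = int(7.5 * 1440)  # mid day 8
    counts[death_min:] = 0
    s = make_series(counts)
    summary = summarize_daily(s)
    alive = summary[summary["alive"]]
    assert list(alive["day"]) == list(range(1, 8))
    dead = summary[~summary["alive"]]
    assert dead["day"].min() == 8
    assert dead["activity"].isna().all()


def test_immortal_active_fly_sleeps_zero():
    s = make_series(np.ones(20 * 1440))
    summary = summarize_daily(s)
    assert len(summary) == 20
    assert summary["alive"].all()
    assert (summary["sleep"] == 0).all()


def test_short_plus_long_equals_total_sleep(rng):
    counts = (rng.random(5 * 1440) < 0.25).astype(int) * rng.integers(1, 4, 5 * 1440)
    s = make_series(counts)
    summary = summarize_daily(s)
    ok = summary[summary["alive"] & ~summary["excluded"]]
    assert np.allclose(ok["sleep_short"] + ok["sleep_long"], ok["sleep"])
    ep_cols = [f"sleep_{e}" for e in ("night", "morning", "siesta", "evening")]
    assert np.allclose(ok[ep_cols].sum(axis=1), ok["sleep"])
    act_cols = [f"activity_{e}" for e in ("night", "morning", "siesta", "evening")]
    assert np.allclose(ok[act_cols].sum(axis=1), ok["activity"])


def test_high_missingness_day_is_excluded(rng):
    counts = np.ones(3 * 1440, dtype=int)
    mask = np.ones(counts.size, dtype=bool)
    mask[1440 : 1440 + 200] = False  # >5% of day 2 masked
    s = make_series(counts, mask=mask)
    summary = summarize_daily(s)
    assert bool(summary.loc[summary["day"] == 2, "excluded"].iloc[0])
    assert not bool(summary.loc[summary["day"] == 1, "excluded"].iloc[0])
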