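"""Monitor-file IO: round trips, validation, channel extraction."""

import datetime as dt

import numpy as np
import pytest

from damsleep import (
    LightSchedule,
    read_monitor_file,
    table_from_series,
    to_activity_series,
    write_monitor_file,
)
from damsleep.io import DamDialectError, DamFormatError, MonitorTable

from conftest import START, make_series


def _random_table(rng, n_readings=10, interval=1):
    counts = rng.integers(0, 20, size=(n_readings, 32))
    stamps = [START + dt.timedelta(minutes=i * interval) for i in range(n_readings)]
    light = [1 if 0 <= (t.hour - 8) % 24 < 12 else 0 for t in stamps]
    return MonitorTable(
        monitor_id="M001",
        index=np.arange(1, n_readings + 1),
        timestamps=stamps,
        status=np.ones(n_readings, dtype=np.int64),
        light=np.asarray(light, dtype=np.int64),
        counts=counts,
        interval_minutes=interval,
    )


def test_write_read_round_trip(tmp_path, rng):
    table = _random_table(rng, n_readings=10)
    path = tmp_path / "M001.txt"
    write_monitor_file(table, path)
    back = read_monitor_file(path)
    assert back == table
    assert back.issues == []


def test_double_round_trip_is_byte_identical(tmp_path, rng):
    table = _random_table(rng, n_readings=25)
    p1, p2 = tmp_path / "M001.txt", tmp_path / "M001b.txt"
    write_monitor_file(table, p1)
    write_monitor_file(read_monitor_file(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_empty_table_round_trip(tmp_path):
    table = MonitorTable(
        monitor_id="M000",
        index=np.empty(0, dtype=np.int64),
        timestamps=[],
        status=np.empty(0, dtype=np.int64),
        light=np.empty(0, dtype=np.int64),
        counts=np.empty((0, 32), dtype=np.int64),
        interval_minutes=1,
    )
    path = tmp_path / "M000.txt"
    write_monitor_file(table, path)
    assert path.read_text() == ""
    assert read_monitor_file(path).n_readings == 0


def test_single_all_zero_reading(tmp_path, rng):
    table = _random_table(rng, n_readings=1)
    table.counts[:] = 0
    path = tmp_path / "M.txt"
    write_monitor_file(table, path)
    back = read_monitor_file(path)
    assert back.n_readings == 1
    assert back.counts.sum() == 0
    assert back.issues == []


def test_bad_status_flagged_not_dropped(tmp_path, rng):
    table = _random_table(rng, n_readings=10)
    table.status[4] = 51  # line 5
    path = tmp_path / "M.txt"
    write_monitor_file(table, path)
    back = read_monitor_file(path)
    assert back.n_readings == 10
    assert [i.line for i in back.issues] == [5]
    assert "51" in back.issues[0].detail


def test_full_day_of_minutes(tmp_path, rng):
    table = _random_table(rng, n_readings=1440)
    path = tmp_path / "M.txt"
    write_monitor_file(table, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 1440
    back = read_monitor_file(path)
    spacing = {
        (b - a).total_seconds() for a, b in zip(back.timestamps[:-1], back.timestamps[1:])
    }
    assert spacing == {60.0}


def test_channel_extraction_identity_and_bounds(rng):
    table = _random_table(rng, n_readings=8)
    for ch in range(32):
        table.counts[:, ch] = ch + 1
    s7 = to_activity_series(table, 7)
    assert (s7.counts == 7).all()
    assert s7.bin_minutes == table.interval_minutes
    assert s7.start == table.timestamps[0]
    with pytest.raises(IndexError):
        to_activity_series(table, 0)
    with pytest.raises(IndexError):
        to_activity_series(table, 33)


def test_extraction_conserves_counts(rng):
    table = _random_table(rng, n_readings=50)
    total = sum(to_activity_series(table, ch).total() for ch in range(1, 33))
    assert total == table.counts.sum()


def test_masked_channels_from_bad_status(rng):
    table = _random_table(rng, n_readings=10)
    table.status[3] = 2
    s = to_activity_series(table, 1)
    assert not s.mask[3] and s.mask.sum() == 9
    assert s.total() == table.counts[table.status == 1, 0].sum()


def test_shuffled_lines_rejected_unless_resorted(tmp_path, rng):
    table = _random_table(rng, n_readings=6)
    path = tmp_path / "M001.txt"
    write_monitor_file(table, path)
    lines = path.read_text().splitlines()
    path.write_text("\n".join([lines[3]] + lines[:3] + lines[4:]) + "\n")
    with pytest.raises(DamFormatError):
        read_monitor_file(path)
    back = read_monitor_file(path, resort=True)
    assert back == table


def test_wrong_field_count_names_dialect(tmp_path):
    path = tmp_path / "M.txt"
    path.write_text("1\t1 Jun 16\t08:00:00\t1\t0\t0\n")
    with pytest.raises(DamDialectError, match="n_fields=6"):
        read_monitor_file(path)


def test_bad_datetime_names_line(tmp_path, rng):
    table = _random_table(rng, n_readings=3)
    path = tmp_path / "M.txt"
    write_monitor_file(table, path)
    lines = path.read_text().splitlines()
    fields = lines[1].split("\t")
    fields[1] = "not a date"
    lines[1] = "\t".join(fields)
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(DamFormatError, match=":2"):
        read_monitor_file(path)


def test_table_from_series_alignment():
    a = make_series(np.arange(10), fly_id="a")
    b = make_series(np.arange(10) * 2, fly_id="b")
    table = table_from_series([a, b])
    assert table.counts.shape == (10, 32)
    assert (table.counts[:, 0] == a.counts).all()
    assert (table.counts[:, 1] == b.counts).all()
    assert (table.counts[:, 2:] == 0).all()
    with pytest.raises(ValueError):
        table_from_series([a, make_series(np.arange(5), fly_id="c")])


def test_light_flag_follows_schedule(tmp_path):
    s = make_series(np.ones(1440))
    table = table_from_series([s])
    zt_h = np.arange(1440) / 60.0
    assert (table.light == (zt_h < 12)).all()
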