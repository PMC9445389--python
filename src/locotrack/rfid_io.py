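"""Reading and cleaning raw RFID registration logs.

A registration log is a delimited text stream of (timestamp, tag_id,
antenna_id) rows at nominally 1 Hz. Cleaning applies two group-level
rules before any activity is computed:

* intervals longer than five consecutive minutes with no registration
  from *any* tag are treated as sensor downtime and excluded;
* only the main light period (07:00-23:00 by default) is analysed, and
  handling periods (weighing, leg-band checks) are excluded.

The result is one :class:`BirdDayStream` per bird and day of age, with
the effectively recorded duration tracked so that daily distances can be
normalised to m/h.
"""

from __future__ import annotations

import datetime as dt
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DaySchedule

__all__ = [
    "ExclusionWindow",
    "BirdDayStream",
    "parse_rfid_log",
    "find_group_gaps",
    "normalize_windows",
    "clip_to_light_period",
    "records_from_streams",
]

GAP_THRESHOLD_S = 300.0  # "more than five consecutive minutes"

_COLUMNS = ["time", "tag_id", "antenna_id"]


@dataclass(frozen=True)
class ExclusionWindow:
    """Half-open interval [start, end) during which records are discarded."""

    start: pd.Timestamp
    end: pd.Timestamp
    reason: str = "custom"  # group_gap | handling | custom

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must be after start")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class BirdDayStream:
    """Time-ordered registrations of one bird on one day of age.

    ``times`` are seconds of day within the light period; ``segments``
    label maximal runs of events not interrupted by an exclusion window,
    so downstream distance sums never bridge unobserved intervals.
    ``effective_seconds`` is the light-period length minus excluded
    overlap; a day with no effective time is carried as missing.
    """

    bird_id: str
    round_id: int
    age_days: int
    date: dt.date
    times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    antennas: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    segments: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    effective_seconds: int = 0

    @property
    def missing(self) -> bool:
        return self.effective_seconds <= 0

    @property
    def n_events(self) -> int:
        return int(self.times.size)


def parse_rfid_log(source, delimiter: str = ",", header: bool = True,
                   known_antennas=None) -> pd.DataFrame:
    """Parse a registration log into a time-sorted DataFrame.

    Duplicate (time, tag) rows with different antennas are both retained:
    at an antenna switch the reader can register a tag twice within the
    same second. Malformed rows raise with their line numbers; unknown
    antennas raise listing the offending ids.
    """
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        source = io.StringIO(source)
    raw = pd.read_csv(
        source,
        sep=delimiter,
        header=0 if header else None,
        names=_COLUMNS,
        dtype=str,
        skip_blank_lines=False,
    )
    if raw.empty:
        return pd.DataFrame({"time": pd.Series(dtype="datetime64[ns]"),
                             "tag_id": pd.Series(dtype=str),
                             "antenna_id": pd.Series(dtype=np.int64)})
    offset = 2 if header else 1  # 1-based line number of the first data row
    time = pd.to_datetime(raw["time"], errors="coerce", format="ISO8601")
    antenna = pd.to_numeric(raw["antenna_id"], errors="coerce")
    bad = time.isna() | antenna.isna() | raw["tag_id"].isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + offset).tolist()
        raise ValueError(f"malformed RFID log rows at lines {lines[:20]}")
    df = pd.DataFrame({"time": time, "tag_id": raw["tag_id"].astype(str),
                       "antenna_id": antenna.astype(np.int64)})
    if known_antennas is not None:
        unknown = sorted(set(df["antenna_id"]) - set(int(a) for a in known_antennas))
        if unknown:
            raise ValueError(f"unknown antenna ids in log: {unknown}")
    return df.sort_values("time", kind="stable").reset_index(drop=True)


def find_group_gaps(records: pd.DataFrame, threshold_s: float = GAP_THRESHOLD_S) -> list[ExclusionWindow]:
    """Windows of group-level silence strictly longer than ``threshold_s``.

    Group-level means *no tag at all* registered: a single silent bird
    while others keep registering never produces a window. Each window
    spans the silent interval exactly (last registration before, first
    registration after).
    """
    if records.empty:
        return []
    times = records["time"].sort_values(kind="stable").to_numpy()
    gaps = (times[1:] - times[:-1]) / np.timedelta64(1, "s")
    out = []
    for i in np.flatnonzero(gaps > threshold_s):
        out.append(ExclusionWindow(pd.Timestamp(times[i]), pd.Timestamp(times[i + 1]),
                                   reason="group_gap"))
    return out


def normalize_windows(windows) -> list[ExclusionWindow]:
    """Sort windows and merge any that overlap (reasons joined with '+')."""
    if not windows:
        return []
    ws = sorted(windows, key=lambda w: (w.start, w.end))
    merged = [ws[0]]
    for w in ws[1:]:
        last = merged[-1]
        if w.start < last.end:
            reason = last.reason if w.reason == last.reason else f"{last.reason}+{w.reason}"
            merged[-1] = ExclusionWindow(last.start, max(last.end, w.end), reason)
        else:
            merged.append(w)
    return merged


def _day_windows_s(windows, date: dt.date, light: tuple[int, int]) -> list[tuple[int, int]]:
    """Exclusion windows of one date, clipped to the light period, in
    seconds of day."""
    day_start = pd.Timestamp(date)
    out = []
    for w in windows:
        s = (w.start - day_start).total_seconds()
        e = (w.end - day_start).total_seconds()
        s, e = max(s, light[0]), min(e, light[1])
        if e > s:
            out.append((int(s), int(e)))
    return sorted(out)


def clip_to_light_period(records: pd.DataFrame, windows, rounds, roster,
                         schedule: DaySchedule | None = None,
                         max_age: int | None = None) -> list[BirdDayStream]:
    """Produce one BirdDayStream per (bird, age) with light-period clipping.

    ``rounds`` maps each calendar date to an age via its round's metadata;
    ``roster`` is a mapping round_id -> list of tag ids, so that bird-days
    with zero registrations are still emitted (as zero-distance or missing
    days). Events outside the light period or inside any exclusion window
    are removed; ``effective_seconds`` is reduced by the excluded overlap.
    """
    schedule = schedule or DaySchedule()
    light = schedule.light_period
    windows = normalize_windows(windows)

    rounds = sorted(rounds, key=lambda r: r.round_id)
    grouped: dict[tuple[dt.date, str], pd.DataFrame] = {}
    if not records.empty:
        recs = records.copy()
        recs["date"] = recs["time"].dt.date
        recs["sod"] = (
            recs["time"] - recs["time"].dt.normalize()
        ).dt.total_seconds().astype(np.int64)
        grouped = {k: v for k, v in recs.groupby(["date", "tag_id"], sort=False)}

    streams: list[BirdDayStream] = []
    for r in rounds:
        last_age = r.end_age if max_age is None else min(r.end_age, max_age)
        for age in range(r.start_age, last_age + 1):
            date = r.date_of_age(age)
            day_wins = _day_windows_s(windows, date, light)
            excluded = sum(e - s for s, e in day_wins)
            effective = int(light[1] - light[0] - excluded)
            starts = np.array([s for s, _ in day_wins], dtype=np.int64)
            ends = np.array([e for _, e in day_wins], dtype=np.int64)
            for tag in roster[r.round_id]:
                sub = grouped.get((date, tag))
                if sub is None or effective <= 0:
                    times = np.empty(0, dtype=np.int64)
                    ants = np.empty(0, dtype=np.int64)
                    segs = np.empty(0, dtype=np.int64)
                else:
                    sod = sub["sod"].to_numpy()
                    keep = (sod >= light[0]) & (sod < light[1])
                    if day_wins:
                        inside = np.zeros(sod.shape, dtype=bool)
                        for s, e in day_wins:
                            inside |= (sod >= s) & (sod < e)
                        keep &= ~inside
                    times = sod[keep]
                    ants = sub["antenna_id"].to_numpy()[keep]
                    # segment index = number of windows entirely before the event
                    segs = np.searchsorted(ends, times, side="right") if day_wins else \
                        np.zeros(times.shape, dtype=np.int64)
                streams.append(BirdDayStream(
                    bird_id=tag, round_id=r.round_id, age_days=age, date=date,
                    times=times, antennas=ants, segments=np.asarray(segs, dtype=np.int64),
                    effective_seconds=effective if effective > 0 else 0,
                ))
    return streams


def records_from_streams(streams) -> pd.DataFrame:
    """Rebuild a registration DataFrame from clipped streams (round-trip
    helper, used e.g. to check that clipping is idempotent)."""
    frames = []
    for s in streams:
        if s.n_events == 0:
            continue
        t = pd.Timestamp(s.date) + pd.to_timedelta(s.times, unit="s")
        frames.append(pd.DataFrame({"time": t, "tag_id": s.bird_id, "antenna_id": s.antennas}))
    if not frames:
        return pd.DataFrame({"time": pd.Series(dtype="datetime64[ns]"),
                             "tag_id": pd.Series(dtype=str),
                             "antenna_id": pd.Series(dtype=np.int64)})
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values("time", kind="stable").reset_index(drop=True)
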