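"""Reading, validating and annotating Drosophila Activity Monitor (DAM) records.

A DAM monitor reports infrared beam-break counts for 32 flies housed in
individual tubes.  The on-disk format handled here is the common DAM2 text
dialect: one tab-separated row per reading with an index column, a date
(``1 Jan 24``), a time (``08:00:00``), a status code (1 = valid), a run of
auxiliary columns (6 by default) and then the 32 per-channel counts.

Counts are binned to one-minute resolution and annotated against an
:class:`ExperimentDesign` describing the light cycle and the role of each
recording day (baseline / activation / recovery).  Minutes without a valid
reading are carried as *missing* (NaN), never imputed as zero: an absent
reading is not evidence of sleep.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

N_CHANNELS = 32
DEFAULT_N_AUX = 6
MINUTES_PER_DAY = 1440

DAY_ROLES = ("baseline", "activation", "recovery")
GENOTYPE_ROLES = ("experimental", "gal4_control", "uas_control")


class DamParseError(ValueError):
    """A monitor file row could not be parsed; the message names the line."""


class DamValidationError(ValueError):
    """A monitor file parsed but violated a structural invariant."""


@dataclass(frozen=True)
class MonitorReading:
    """One row of a DAM monitor file.

    Parameters
    ----------
    timestamp : datetime.datetime
        Reading time, minute resolution or finer.
    status_code : int
        Monitor status; 1 means valid.  Other codes are retained but the
        reading is treated as missing downstream.
    channel_counts : tuple of int
        Beam-break counts for the 32 channels, in channel order.
    index : int
        The file's running row index (first column), preserved for
        round-tripping.
    aux : tuple of str
        The auxiliary columns between status and counts, preserved verbatim.
    """

    timestamp: dt.datetime
    status_code: int
    channel_counts: tuple[int, ...]
    index: int = 0
    aux: tuple[str, ...] = ("0",) * DEFAULT_N_AUX

    def __post_init__(self) -> None:
        if len(self.channel_counts) != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channel counts, got {len(self.channel_counts)}"
            )
        if any(c < 0 for c in self.channel_counts):
            raise ValueError("channel counts must be non-negative")

    @property
    def valid(self) -> bool:
        return self.status_code == 1


def _parse_timestamp(date_str: str, time_str: str, lineno: int) -> dt.datetime:
    try:
        return dt.datetime.strptime(f"{date_str.strip()} {time_str.strip()}", "%d %b %y %H:%M:%S")
    except ValueError as exc:
        raise DamParseError(f"line {lineno}: bad date/time {date_str!r} {time_str!r}: {exc}") from exc


def read_dam_monitor(path: str | Path, n_aux: int = DEFAULT_N_AUX) -> list[MonitorReading]:
    """Read a DAM2-dialect monitor file.

    Rows with a status code other than 1 are retained (callers decide how to
    treat them; :func:`bin_to_minutes` treats their minutes as missing).
    Malformed rows and non-monotone timestamps raise with the line number.
    """
    path = Path(path)
    expected = 4 + n_aux + N_CHANNELS
    readings: list[MonitorReading] = []
    last_ts: dt.datetime | None = None
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != expected:
                raise DamParseError(
                    f"line {lineno}: expected {expected} tab-separated columns, got {len(cols)}"
                )
            ts = _parse_timestamp(cols[1], cols[2], lineno)
            try:
                idx = int(cols[0])
                status = int(cols[3])
                counts = tuple(int(c) for c in cols[4 + n_aux:])
            except ValueError as exc:
                raise DamParseError(f"line {lineno}: non-integer field: {exc}") from exc
            if any(c < 0 for c in counts):
                raise DamParseError(f"line {lineno}: negative count")
            if last_ts is not None and ts <= last_ts:
                raise DamValidationError(
                    f"line {lineno}: timestamp {ts} not after previous reading {last_ts}"
                )
            last_ts = ts
            readings.append(
                MonitorReading(ts, status, counts, index=idx, aux=tuple(cols[4:4 + n_aux]))
            )
    return readings


def write_dam_monitor(readings: Iterable[MonitorReading], path: str | Path) -> None:
    """Write readings in the canonical DAM2 dialect (round-trips byte-identically)."""
    path = Path(path)
    with open(path, "w", encoding="ascii", newline="") as fh:
        for r in readings:
            date = f"{r.timestamp.day} {r.timestamp.strftime('%b %y')}"
            time = r.timestamp.strftime("%H:%M:%S")
            fields = [str(r.index), date, time, str(r.status_code), *r.aux]
            fields += [str(c) for c in r.channel_counts]
            fh.write("\t".join(fields) + "\n")


def bin_to_minutes(readings: Sequence[MonitorReading], channel: int) -> pd.Series:
    """Sum one channel's counts into 1-minute bins.

    Returns a float Series indexed by minute timestamps spanning the recording.
    Minutes with no valid reading are NaN (missing), not zero; a minute
    containing any invalid-status reading is likewise missing.
    """
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError(f"channel must be in 1..{N_CHANNELS}, got {channel}")
    if not readings:
        return pd.Series(dtype=float)
    ts = pd.DatetimeIndex([r.timestamp for r in readings])
    counts = np.array([r.channel_counts[channel - 1] for r in readings], dtype=float)
    valid = np.array([r.valid for r in readings], dtype=bool)
    minutes = ts.floor("min")
    frame = pd.DataFrame({"minute": minutes, "count": counts, "valid": valid})
    per_min = frame.groupby("minute").agg(count=("count", "sum"), all_valid=("valid", "all"))
    per_min.loc[~per_min["all_valid"], "count"] = np.nan
    full = pd.date_range(minutes[0], minutes[-1], freq="min")
    return per_min["count"].reindex(full)


@dataclass
class ExperimentDesign:
    """The 3-day screen design: light cycle plus day-role calendar.

    ``day_roles`` maps each calendar date to exactly one of baseline,
    activation, recovery (the 21 °C / 30 °C / 21 °C days).
    """

    lights_on: dt.time
    day_roles: dict[dt.date, str]
    photoperiod_minutes: int = 720
    channel_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0 < self.photoperiod_minutes < MINUTES_PER_DAY:
            raise ValueError("photoperiod_minutes must be in (0, 1440)")
        roles = sorted(self.day_roles.values())
        if roles != sorted(DAY_ROLES):
            raise ValueError(
                f"day_roles must contain exactly one of each of {DAY_ROLES}, got {roles}"
            )

    @property
    def lights_on_minute(self) -> int:
        return self.lights_on.hour * 60 + self.lights_on.minute

    def date_for_role(self, role: str) -> dt.date:
        for date, r in self.day_roles.items():
            if r == role:
                return date
        raise KeyError(role)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        lights_on = dt.time.fromisoformat(str(raw["lights_on"]))
        day_roles = {
            dt.date.fromisoformat(str(date)): role for date, role in raw["day_roles"].items()
        }
        return cls(
            lights_on=lights_on,
            day_roles=day_roles,
            photoperiod_minutes=int(raw.get("photoperiod_minutes", 720)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "lights_on": self.lights_on.isoformat(timespec="minutes"),
            "day_roles": {d.isoformat(): r for d, r in self.day_roles.items()},
            "photoperiod_minutes": self.photoperiod_minutes,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def read_channel_map(path: str | Path) -> pd.DataFrame:
    """Read the monitor/channel → fly metadata map.

    Expected CSV columns: monitor, channel, fly_id, genotype, driver,
    genotype_role.  ``driver`` may be empty for control genotypes.
    """
    cm = pd.read_csv(path, dtype={"monitor": str, "fly_id": str, "genotype": str, "driver": str})
    required = {"monitor", "channel", "fly_id", "genotype", "driver", "genotype_role"}
    missing = required - set(cm.columns)
    if missing:
        raise DamValidationError(f"channel map missing columns: {sorted(missing)}")
    bad = set(cm["genotype_role"]) - set(GENOTYPE_ROLES)
    if bad:
        raise DamValidationError(f"unknown genotype_role values: {sorted(bad)}")
    return cm


@dataclass
class FlyActivitySeries:
    """One fly's minute-binned activity, annotated with day role and phase.

    ``data`` has one row per minute inside the design days, with columns
    ``date``, ``zt_minute``, ``day_role``, ``phase`` (LP/DP) and ``count``
    (float; NaN = missing minute).
    """

    fly_id: str
    genotype: str
    driver: str | None
    genotype_role: str
    data: pd.DataFrame = field(repr=False)

    @property
    def counts(self) -> np.ndarray:
        return self.data["count"].to_numpy()

    def day(self, day_role: str) -> pd.DataFrame:
        return self.data[self.data["day_role"] == day_role]

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "fly_id", self.fly_id)
        out.insert(1, "genotype", self.genotype)
        out.insert(2, "driver", self.driver if self.driver is not None else "")
        out.insert(3, "genotype_role", self.genotype_role)
        return out


def annotate(
    minute_counts: pd.Series,
    design: ExperimentDesign,
    *,
    fly_id: str,
    genotype: str,
    driver: str | None,
    genotype_role: str,
) -> FlyActivitySeries:
    """Label each minute with day role, zeitgeber time and light phase.

    Minutes on calendar dates outside the design are dropped.  ZT 0 is
    lights-on; phase is LP on the half-open interval [0, photoperiod) and DP
    on [photoperiod, 1440).
    """
    if genotype_role not in GENOTYPE_ROLES:
        raise ValueError(f"unknown genotype_role {genotype_role!r}")
    idx = minute_counts.index
    dates = np.array([ts.date() for ts in idx])
    roles = np.array([design.day_roles.get(d, "") for d in dates])
    keep = roles != ""
    clock_min = idx.hour * 60 + idx.minute
    zt = (np.asarray(clock_min) - design.lights_on_minute) % MINUTES_PER_DAY
    phase = np.where(zt < design.photoperiod_minutes, "LP", "DP")
    data = pd.DataFrame(
        {
            "date": dates[keep],
            "zt_minute": zt[keep].astype(int),
            "day_role": roles[keep],
            "phase": phase[keep],
            "count": minute_counts.to_numpy()[keep],
        }
    ).reset_index(drop=True)
    for role in DAY_ROLES:
        n = int((data["day_role"] == role).sum())
        if n > MINUTES_PER_DAY:
            raise DamValidationError(f"{fly_id}: {role} day has {n} minutes (> {MINUTES_PER_DAY})")
    return FlyActivitySeries(
        fly_id=fly_id, genotype=genotype, driver=driver, genotype_role=genotype_role, data=data
    )


@dataclass(frozen=True)
class FilterDecision:
    fly_id: str
    keep: bool
    active_minutes_last_day: int
    reason: str


def filter_dead_flies(
    series: FlyActivitySeries, min_active_minutes_last_day: int = 1
) -> FilterDecision:
    """Drop flies that stopped moving: too few active minutes on the recovery day.

    A fly that dies mid-experiment registers as perpetually asleep, corrupting
    every downstream metric; the standard hygiene check requires some activity
    on the final day.
    """
    recovery = series.day("recovery")
    active = int((recovery["count"].fillna(0) > 0).sum())
    keep = active >= min_active_minutes_last_day
    reason = (
        "kept"
        if keep
        else (
            f"dropped: {active} active minutes on recovery day "
            f"< threshold {min_active_minutes_last_day}"
        )
    )
    return FilterDecision(series.fly_id, keep, active, reason)


def load_screen(
    monitor_paths: Mapping[str, str | Path],
    channel_map: pd.DataFrame,
    design: ExperimentDesign,
    n_aux: int = DEFAULT_N_AUX,
) -> list[FlyActivitySeries]:
    """Load every mapped fly from a set of monitor files.

    ``monitor_paths`` maps monitor names (as used in the channel map) to file
    paths.  Returns one annotated series per channel-map row.
    """
    series: list[FlyActivitySeries] = []
    for monitor, path in monitor_paths.items():
        readings = read_dam_monitor(path, n_aux=n_aux)
        rows = channel_map[channel_map["monitor"] == monitor]
        for _, row in rows.iterrows():
            binned = bin_to_minutes(readings, int(row["channel"]))
            driver = row["driver"] if isinstance(row["driver"], str) and row["driver"] else None
            series.append(
                annotate(
                    binned,
                    design,
                    fly_id=row["fly_id"],
                    genotype=row["genotype"],
                    driver=driver,
                    genotype_role=row["genotype_role"],
                )
            )
    return series
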