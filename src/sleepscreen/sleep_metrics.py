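"""Sleep-bout scoring and per-phase sleep-structure metrics.

Fly sleep is defined behaviorally: a bout (episode) is a maximal run of at
least ``min_bout`` consecutive inactive minutes (5 by convention).  Each
experiment day is scored independently and three metrics are reported per
light phase: total sleep minutes, number of episodes, and maximum episode
length.

Missing minutes break runs — sleep is never inferred through unobserved
time.  A bout straddling the LP/DP boundary contributes its minutes to the
phase they fall in; the episode itself is counted once, by default in the
phase containing its start (``straddle="start"``; ``straddle="both"`` counts
it in both phases, matching an alternative scoring dialect).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .dam_io import DAY_ROLES, FlyActivitySeries

# Minute-state codes.
INACTIVE = 0
ACTIVE = 1
MISSING = -1

DEFAULT_MIN_BOUT = 5
PHASES = ("LP", "DP")
PARAMETERS = ("total_sleep", "n_episodes", "max_episode")

Straddle = Literal["start", "both"]


@dataclass(frozen=True)
class SleepBout:
    """A maximal run of >= min_bout consecutive inactive minutes."""

    start: int  # index into the day's minute vector
    duration: int

    @property
    def end(self) -> int:  # exclusive
        return self.start + self.duration


@dataclass(frozen=True)
class SleepMetricsRow:
    fly_id: str
    day_role: str
    phase: str
    total_sleep: int
    n_episodes: int
    max_episode: int

    def __post_init__(self) -> None:
        if self.total_sleep == 0 and (self.n_episodes or self.max_episode):
            raise ValueError(f"no sleep minutes but nonzero episodes: {self}")
        # total_sleep > 0 with n_episodes == 0 is legal under the "start"
        # dialect: the tail of a bout that began in the other phase.
        if self.max_episode > self.total_sleep:
            raise ValueError("max_episode cannot exceed total_sleep")


def binarize(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map per-minute counts to states: active iff count > 0; NaN -> missing."""
    arr = np.asarray(counts, dtype=float)
    states = np.where(arr > 0, ACTIVE, INACTIVE).astype(np.int8)
    states[np.isnan(arr)] = MISSING
    return states


def score_bouts(states: np.ndarray, min_bout: int = DEFAULT_MIN_BOUT) -> list[SleepBout]:
    """Find all sleep bouts in one fly-day's state vector.

    Runs of inactivity interrupted by a missing minute are split there: the
    missing minute is not counted as sleep and does not join its neighbours.
    """
    if min_bout < 1:
        raise ValueError("min_bout must be >= 1")
    states = np.asarray(states, dtype=np.int8)
    # Boundaries where the run of INACTIVE breaks (ACTIVE and MISSING both break).
    inactive = states == INACTIVE
    padded = np.concatenate(([False], inactive, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    bouts = [
        SleepBout(int(s), int(e - s)) for s, e in zip(starts, ends) if e - s >= min_bout
    ]
    return bouts


def sleep_minutes_mask(states: np.ndarray, min_bout: int = DEFAULT_MIN_BOUT) -> np.ndarray:
    """Boolean mask of minutes inside a scored bout."""
    mask = np.zeros(len(states), dtype=bool)
    for b in score_bouts(states, min_bout):
        mask[b.start:b.end] = True
    return mask


def summarize_day(
    fly_id: str,
    states: np.ndarray,
    phases: Sequence[str],
    day_role: str,
    min_bout: int = DEFAULT_MIN_BOUT,
    straddle: Straddle = "start",
) -> list[SleepMetricsRow]:
    """Per-phase metrics for one fly-day.

    Bouts are scored on the whole day, then intersected with each phase
    window: total sleep counts a bout's minutes in the phase they occur;
    max episode is the longest within-phase contiguous sleeping segment of
    any single bout; the episode count attributes a straddling bout per the
    ``straddle`` dialect.
    """
    phases_arr = np.asarray(phases)
    if len(phases_arr) != len(states):
        raise ValueError("states and phases must have equal length")
    bouts = score_bouts(states, min_bout)
    rows = []
    for phase in PHASES:
        in_phase = phases_arr == phase
        total = 0
        n_epi = 0
        max_epi = 0
        for b in bouts:
            seg = in_phase[b.start:b.end]
            overlap = int(seg.sum())
            if overlap == 0:
                continue
            total += overlap
            # Longest contiguous within-phase stretch of this bout.
            pad = np.concatenate(([False], seg, [False]))
            d = np.diff(pad.astype(np.int8))
            lengths = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
            max_epi = max(max_epi, int(lengths.max()))
            if straddle == "both":
                n_epi += 1
            elif in_phase[b.start]:
                n_epi += 1
        rows.append(SleepMetricsRow(fly_id, day_role, phase, total, n_epi, max_epi))
    return rows


def metrics_table(
    series: Iterable[FlyActivitySeries],
    min_bout: int = DEFAULT_MIN_BOUT,
    straddle: Straddle = "start",
) -> pd.DataFrame:
    """Tidy per fly x day x phase metrics for a set of annotated flies.

    Returns columns: fly_id, genotype, driver, genotype_role, day_role,
    phase, total_sleep, n_episodes, max_episode.
    """
    records = []
    for fly in series:
        for role in DAY_ROLES:
            day = fly.day(role)
            if day.empty:
                continue
            states = binarize(day["count"].to_numpy())
            for row in summarize_day(
                fly.fly_id, states, day["phase"].to_numpy(), role, min_bout, straddle
            ):
                records.append(
                    {
                        "fly_id": fly.fly_id,
                        "genotype": fly.genotype,
                        "driver": fly.driver if fly.driver is not None else "",
                        "genotype_role": fly.genotype_role,
                        "day_role": row.day_role,
                        "phase": row.phase,
                        "total_sleep": row.total_sleep,
                        "n_episodes": row.n_episodes,
                        "max_episode": row.max_episode,
                    }
                )
    return pd.DataFrame.from_records(records)


def batch_phase_metrics(
    states: np.ndarray,
    phase_bounds: tuple[int, int] = (0, 720),
    min_bout: int = DEFAULT_MIN_BOUT,
    day_length: int = 1440,
) -> dict[str, np.ndarray]:
    """Vectorized per-phase metrics over many fly-days at once.

    ``states`` is (n_flydays, day_length) with rows aligned to ZT 0 and the
    LP window at ``phase_bounds`` (half-open).  Episode attribution follows
    the "start" dialect.  Returns arrays of shape (n_flydays,) per metric and
    phase, keyed ``"<metric>_<phase>"``.

    This is the bulk path used by the simulator-driven calibration runs; it
    is equivalent to :func:`summarize_day` row by row (tested property).
    """
    states = np.asarray(states, dtype=np.int8)
    n, width = states.shape
    if width != day_length:
        raise ValueError(f"expected rows of {day_length} minutes, got {width}")
    lp_lo, lp_hi = phase_bounds
    # Separate rows with an ACTIVE sentinel so runs never span flies.
    sent = np.full((n, 1), ACTIVE, dtype=np.int8)
    flat = np.concatenate([states, sent], axis=1).ravel()
    stride = width + 1
    inactive = flat == INACTIVE
    pad = np.concatenate(([False], inactive, [False]))
    d = np.diff(pad.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    keep = (ends - starts) >= min_bout
    starts, ends = starts[keep], ends[keep]
    row = starts // stride
    s = starts % stride
    e = ends - row * stride  # end position within the row (exclusive, <= width)

    out: dict[str, np.ndarray] = {}
    windows = {"LP": (lp_lo, lp_hi)}
    # DP is the complement of LP within the day; with the standard alignment
    # (lp_lo == 0) it is a single window [lp_hi, width).
    if lp_lo != 0:
        raise ValueError("batch path requires rows aligned to lights-on (LP starting at 0)")
    windows["DP"] = (lp_hi, width)
    for phase, (lo, hi) in windows.items():
        ov = np.clip(np.minimum(e, hi) - np.maximum(s, lo), 0, None)
        total = np.bincount(row, weights=ov, minlength=n).astype(int)
        in_phase_start = (s >= lo) & (s < hi)
        n_epi = np.bincount(row[in_phase_start], minlength=n).astype(int)
        max_epi = np.zeros(n, dtype=int)
        if len(row):
            order = np.argsort(row, kind="stable")
            np.maximum.at(max_epi, row[order], ov[order].astype(int))
        out[f"total_sleep_{phase}"] = total
        out[f"n_episodes_{phase}"] = n_epi
        out[f"max_episode_{phase}"] = max_epi
    return out
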