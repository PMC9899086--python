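"""Minute-to-minute behavioral-state transition probabilities.

P(wake) is the conditional probability that an inactive fly is active in the
next minute (a proxy for sleep depth / arousability); P(doze) is the reverse
transition, active to inactive (a proxy for sleep pressure).  Both are
estimated on the raw 1-minute activity/inactivity states — not on the
5-minute sleep-scored states — as simple transition frequencies.

A minute pair (t, t+1) contributes only when both minutes are observed and
minute t lies in the requested phase window; the successor may belong to the
next phase.  Estimates with zero opportunities are undefined (NaN), never
zero, and stay undefined through downstream contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dam_io import DAY_ROLES, FlyActivitySeries
from .sleep_metrics import ACTIVE, INACTIVE, binarize


@dataclass(frozen=True)
class TransitionEstimate:
    """P(wake)/P(doze) with the transition and opportunity counts behind them."""

    n_wake_transitions: int
    n_wake_opportunities: int
    n_doze_transitions: int
    n_doze_opportunities: int

    def __post_init__(self) -> None:
        if self.n_wake_transitions > self.n_wake_opportunities:
            raise ValueError("wake transitions exceed opportunities")
        if self.n_doze_transitions > self.n_doze_opportunities:
            raise ValueError("doze transitions exceed opportunities")

    @property
    def p_wake(self) -> float:
        if self.n_wake_opportunities == 0:
            return float("nan")
        return self.n_wake_transitions / self.n_wake_opportunities

    @property
    def p_doze(self) -> float:
        if self.n_doze_opportunities == 0:
            return float("nan")
        return self.n_doze_transitions / self.n_doze_opportunities


def estimate(states: np.ndarray, window: np.ndarray | None = None) -> TransitionEstimate:
    """Estimate P(wake) and P(doze) from one fly's minute states.

    Parameters
    ----------
    states : array of {ACTIVE, INACTIVE, MISSING}
    window : optional boolean mask over minutes; pair (t, t+1) counts when
        ``window[t]`` is True.  Default: all minutes.
    """
    states = np.asarray(states, dtype=np.int8)
    if len(states) < 2:
        return TransitionEstimate(0, 0, 0, 0)
    cur, nxt = states[:-1], states[1:]
    observed = (cur != -1) & (nxt != -1)
    if window is not None:
        window = np.asarray(window, dtype=bool)
        if len(window) != len(states):
            raise ValueError("window mask must match states length")
        observed &= window[:-1]
    inactive_now = observed & (cur == INACTIVE)
    active_now = observed & (cur == ACTIVE)
    return TransitionEstimate(
        n_wake_transitions=int((inactive_now & (nxt == ACTIVE)).sum()),
        n_wake_opportunities=int(inactive_now.sum()),
        n_doze_transitions=int((active_now & (nxt == INACTIVE)).sum()),
        n_doze_opportunities=int(active_now.sum()),
    )


def pool(estimates: Iterable[TransitionEstimate]) -> TransitionEstimate:
    """Pool estimates by summing counts and recomputing the probabilities."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("cannot pool an empty list of estimates")
    return TransitionEstimate(
        n_wake_transitions=sum(e.n_wake_transitions for e in estimates),
        n_wake_opportunities=sum(e.n_wake_opportunities for e in estimates),
        n_doze_transitions=sum(e.n_doze_transitions for e in estimates),
        n_doze_opportunities=sum(e.n_doze_opportunities for e in estimates),
    )


def transition_table(series: Iterable[FlyActivitySeries]) -> pd.DataFrame:
    """Per fly x day x phase transition estimates for a set of annotated flies.

    Pairs are attributed to the phase of minute t; the successor minute may
    be the first minute of the next phase (or day's end neighbour within the
    same calendar day).
    """
    records = []
    for fly in series:
        for role in DAY_ROLES:
            day = fly.day(role)
            if day.empty:
                continue
            states = binarize(day["count"].to_numpy())
            phases = day["phase"].to_numpy()
            for phase in ("LP", "DP"):
                est = estimate(states, window=phases == phase)
                records.append(
                    {
                        "fly_id": fly.fly_id,
                        "genotype": fly.genotype,
                        "driver": fly.driver if fly.driver is not None else "",
                        "genotype_role": fly.genotype_role,
                        "day_role": role,
                        "phase": phase,
                        "p_wake": est.p_wake,
                        "p_doze": est.p_doze,
                        "n_wake_transitions": est.n_wake_transitions,
                        "n_wake_opportunities": est.n_wake_opportunities,
                        "n_doze_transitions": est.n_doze_transitions,
                        "n_doze_opportunities": est.n_doze_opportunities,
                    }
                )
    return pd.DataFrame.from_records(records)


def batch_transition_counts(
    states: np.ndarray, window: slice
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized transition counts over many fly-days.

    ``states`` is (n, minutes); ``window`` selects the minutes t whose pairs
    count.  Returns (wake_transitions, wake_opportunities, doze_transitions,
    doze_opportunities), each shape (n,).
    """
    states = np.asarray(states, dtype=np.int8)
    t_idx = np.arange(states.shape[1] - 1)[window]
    cur = states[:, t_idx]
    nxt = states[:, t_idx + 1]
    observed = (cur != -1) & (nxt != -1)
    inact = observed & (cur == INACTIVE)
    act = observed & (cur == ACTIVE)
    return (
        (inact & (nxt == ACTIVE)).sum(axis=1),
        inact.sum(axis=1),
        (act & (nxt == INACTIVE)).sum(axis=1),
        act.sum(axis=1),
    )
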