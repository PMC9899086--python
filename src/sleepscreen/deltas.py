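"""Baseline-subtracted changes and the genetic-control correction.

The screen's effect sizes are built in three steps:

1. per-fly paired difference (activation − baseline, or recovery − baseline)
   for each sleep parameter and phase;
2. genotype means of those per-fly deltas;
3. genetic-control correction per driver:
   ``experimental Δ − (GAL4 Δ + UAS Δ) / 2``.

Because the thermogenetic trigger is a temperature step that itself alters
sleep, the controls undergo the same step without the effector; subtracting
their mean delta removes the pure temperature effect (the correction is
invariant to adding any constant to all three genotypes).

The subtype GLM instead consumes *change rates*:
``(activation − baseline) / baseline`` per fly, averaged per driver, with
zero-baseline flies excluded (and counted).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

SLEEP_PARAMETERS = ("total_sleep", "n_episodes", "max_episode")
PROB_PARAMETERS = ("p_wake", "p_doze")


def per_fly_delta(
    values: pd.DataFrame,
    parameters: Iterable[str],
    contrast: str = "activation",
) -> pd.DataFrame:
    """Per-fly paired difference (contrast day − baseline) per parameter and phase.

    ``values`` is a tidy table with columns fly_id, genotype, driver,
    genotype_role, day_role, phase and one column per parameter.  Flies
    missing either day are skipped (logged in the returned frame's ``attrs``
    under ``"skipped"``); a parameter undefined (NaN) on either day yields a
    NaN delta.
    """
    if contrast not in ("activation", "recovery"):
        raise ValueError(f"unknown contrast {contrast!r}")
    parameters = list(parameters)
    keys = ["fly_id", "genotype", "driver", "genotype_role", "phase"]
    base = values[values["day_role"] == "baseline"].set_index(keys)
    other = values[values["day_role"] == contrast].set_index(keys)
    common = base.index.intersection(other.index)
    skipped = sorted(
        set(base.index.symmetric_difference(other.index).get_level_values("fly_id"))
    )
    out = (other.loc[common, parameters] - base.loc[common, parameters]).reset_index()
    out.insert(5, "contrast", f"{contrast}-baseline")
    out.attrs["skipped"] = skipped
    return out


def control_correct(
    exp_mean_delta: float, gal4_mean_delta: float, uas_mean_delta: float
) -> float:
    """Genetic-control corrected delta: exp − (gal4 + uas)/2.

    Undefined (NaN) inputs propagate to an undefined output.
    """
    if any(
        v is None or (isinstance(v, float) and math.isnan(v))
        for v in (exp_mean_delta, gal4_mean_delta, uas_mean_delta)
    ):
        return float("nan")
    return exp_mean_delta - (gal4_mean_delta + uas_mean_delta) / 2.0


def driver_points(
    deltas: pd.DataFrame, parameters: Iterable[str] = PROB_PARAMETERS
) -> pd.DataFrame:
    """One control-corrected coordinate per driver x phase.

    ``deltas`` is the output of :func:`per_fly_delta` carrying the given
    parameter columns (by default ΔP(wake), ΔP(doze)).  Per-fly deltas are
    averaged within genotype role, then corrected:
    ``exp − (gal4 + uas)/2``.  Returns columns driver, phase, d_<parameter>.
    """
    parameters = list(parameters)
    means = (
        deltas.groupby(["driver", "phase", "genotype_role"])[parameters]
        .mean()
        .reset_index()
    )
    records = []
    for (driver, phase), grp in means.groupby(["driver", "phase"]):
        byrole = grp.set_index("genotype_role")
        rec = {"driver": driver, "phase": phase}
        for p in parameters:
            try:
                rec[f"d_{p}"] = control_correct(
                    byrole.at["experimental", p],
                    byrole.at["gal4_control", p],
                    byrole.at["uas_control", p],
                )
            except KeyError:
                rec[f"d_{p}"] = float("nan")
        records.append(rec)
    return pd.DataFrame.from_records(records)


def change_rate(activation: float, baseline: float) -> float:
    """Relative change (activation − baseline) / baseline; undefined at baseline 0."""
    if baseline == 0 or math.isnan(baseline) or math.isnan(activation):
        return float("nan")
    return (activation - baseline) / baseline


def driver_change_rates(
    values: pd.DataFrame, parameters: Iterable[str] = SLEEP_PARAMETERS
) -> pd.DataFrame:
    """Mean per-fly change rate per driver x parameter x phase (experimental flies).

    Change rates are computed per fly as (activation − baseline)/baseline;
    flies with baseline 0 (or a missing day) are excluded from the mean and
    counted in ``n_excluded``.
    """
    parameters = list(parameters)
    exp = values[values["genotype_role"] == "experimental"]
    keys = ["fly_id", "driver", "phase"]
    base = exp[exp["day_role"] == "baseline"].set_index(keys)
    act = exp[exp["day_role"] == "activation"].set_index(keys)
    common = base.index.intersection(act.index)
    b = base.loc[common, parameters]
    a = act.loc[common, parameters]
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = (a - b) / b.replace(0, np.nan)
    rates = rates.reset_index()
    records = []
    for (driver, phase), grp in rates.groupby(["driver", "phase"]):
        for p in parameters:
            vals = grp[p]
            records.append(
                {
                    "driver": driver,
                    "parameter": p,
                    "phase": phase,
                    "value": vals.mean(),
                    "n_flies": int(vals.notna().sum()),
                    "n_excluded": int(vals.isna().sum()),
                }
            )
    return pd.DataFrame.from_records(records)
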