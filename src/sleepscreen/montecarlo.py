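"""Array-path screen analysis for simulation studies.

Monte-Carlo calibration runs (parameter recovery, type-I rates, detection
power) need hundreds of full screens, so these helpers compute the same
quantities as the file-based pipeline — per-driver change rates, per-driver
control-corrected ΔP coordinates — directly from an in-memory
:class:`~sleepscreen.simulate.ScreenData`, using the vectorized metric and
transition kernels (tested equivalent to the per-fly scalar paths).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sleep_metrics import DEFAULT_MIN_BOUT, batch_phase_metrics
from .simulate import ScreenData
from .transitions import batch_transition_counts

PHASE_WINDOWS = {"LP": slice(0, 720), "DP": slice(720, 1439)}


def screen_change_rates(
    screen: ScreenData, min_bout: int = DEFAULT_MIN_BOUT
) -> pd.DataFrame:
    """Per-driver mean change rates of the sleep metrics (experimental flies).

    Matches :func:`sleepscreen.deltas.driver_change_rates` on the same data:
    per-fly (activation − baseline)/baseline, zero-baseline flies excluded.
    Returns columns driver, parameter, phase, value, n_flies, n_excluded.
    """
    per_day = {
        role: batch_phase_metrics(screen.day_states(role), min_bout=min_bout)
        for role in ("baseline", "activation")
    }
    flies = screen.flies
    exp_mask = (flies["genotype_role"] == "experimental").to_numpy()
    records = []
    for parameter in ("total_sleep", "n_episodes", "max_episode"):
        for phase in ("LP", "DP"):
            key = f"{parameter}_{phase}"
            base = per_day["baseline"][key].astype(float)
            act = per_day["activation"][key].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                rate = np.where(base > 0, (act - base) / base, np.nan)
            sub = pd.DataFrame(
                {"driver": flies["driver"].to_numpy()[exp_mask], "rate": rate[exp_mask]}
            )
            for driver, grp in sub.groupby("driver"):
                records.append(
                    {
                        "driver": driver,
                        "parameter": parameter,
                        "phase": phase,
                        "value": grp["rate"].mean(),
                        "n_flies": int(grp["rate"].notna().sum()),
                        "n_excluded": int(grp["rate"].isna().sum()),
                    }
                )
    return pd.DataFrame.from_records(records)


def screen_driver_points(screen: ScreenData) -> pd.DataFrame:
    """Control-corrected (ΔP(wake), ΔP(doze)) per driver x phase.

    Per-fly transition estimates per day and phase, per-fly activation −
    baseline deltas, genotype-role means, then exp − (gal4 + uas)/2 —
    the same reduction as the pipeline's driver_points stage.
    """
    flies = screen.flies
    est = {}
    for role in ("baseline", "activation"):
        day = screen.day_states(role)
        for phase, window in PHASE_WINDOWS.items():
            nw, ow, nd, od = batch_transition_counts(day, window)
            with np.errstate(divide="ignore", invalid="ignore"):
                est[(role, phase, "p_wake")] = np.where(ow > 0, nw / ow, np.nan)
                est[(role, phase, "p_doze")] = np.where(od > 0, nd / od, np.nan)
    records = []
    for phase in ("LP", "DP"):
        delta = {
            p: est[("activation", phase, p)] - est[("baseline", phase, p)]
            for p in ("p_wake", "p_doze")
        }
        frame = pd.DataFrame(
            {
                "driver": flies["driver"],
                "genotype_role": flies["genotype_role"],
                "d_wake": delta["p_wake"],
                "d_doze": delta["p_doze"],
            }
        )
        means = frame.groupby(["driver", "genotype_role"]).mean()
        for driver in flies["driver"].unique():
            rec = {"driver": driver, "phase": phase}
            for col, out in (("d_wake", "d_p_wake"), ("d_doze", "d_p_doze")):
                exp = means.at[(driver, "experimental"), col]
                gal4 = means.at[(driver, "gal4_control"), col]
                uas = means.at[(driver, "uas_control"), col]
                rec[out] = exp - (gal4 + uas) / 2.0
            records.append(rec)
    return pd.DataFrame.from_records(records)
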