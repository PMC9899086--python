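"""Ground-truth synthetic screens: two-state Markov flies in DAM format.

Each fly is a two-state (active/inactive) Markov chain at one-minute
resolution.  Within a phase the chain is homogeneous with per-minute
transition probabilities p_doze (active → inactive) and p_wake
(inactive → active); the first minute is drawn from the chain's stationary
distribution, whose inactive fraction is p_doze/(p_doze + p_wake).

The screen layers effects on the logit scale, so stacked shifts always
yield valid probabilities:

* a temperature effect on the activation day (the 30 °C day), applied to
  every genotype — this is what the genetic-control correction removes;
* subtype effects, X[driver] · weights added per phase, applied only to the
  experimental genotype and only on the activation day (the thermogenetic
  effector fires only when warm).

Per driver the generator emits three genotypes (experimental, GAL4 control,
UAS control) with ``flies_per_genotype`` flies each over the three-day
baseline/activation/recovery design, and can write the result as canonical
DAM monitor files plus channel map, design file and a ground-truth JSON
manifest.  Active minutes emit ``1 + Poisson(λ − 1)`` beam-break counts;
inactive minutes emit 0.  Flies die with a small probability at a uniform
random minute, after which they emit zero counts.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import dam_io
from .dam_io import ExperimentDesign, MonitorReading, MINUTES_PER_DAY
from .subtype_glm import CANONICAL_SUBTYPES

DAY_ROLES = ("baseline", "activation", "recovery")
PHASES = ("LP", "DP")

# Baseline per-minute transition probabilities: modest day sleep, consolidated
# night sleep (stationary inactive fraction 0.375 LP, 0.75 DP).
DEFAULT_BASELINE = {
    ("LP", "p_doze"): 0.15,
    ("LP", "p_wake"): 0.25,
    ("DP", "p_doze"): 0.30,
    ("DP", "p_wake"): 0.10,
}
# Warmth mildly suppresses sleep in every genotype on the 30 degC day.
DEFAULT_TEMPERATURE_EFFECT = {"p_wake": 0.4, "p_doze": -0.2}


def zero_weights(subtypes=CANONICAL_SUBTYPES) -> pd.DataFrame:
    """All-zero subtype weight table: rows = subtypes, columns = the four
    (probability, phase) logit channels."""
    cols = [f"{p}_{ph}" for p in ("p_doze", "p_wake") for ph in PHASES]
    return pd.DataFrame(0.0, index=list(subtypes), columns=cols)


def random_subtype_matrix(
    n_drivers: int, rng: np.random.Generator, subtypes=CANONICAL_SUBTYPES, density: float = 0.25
) -> pd.DataFrame:
    """Random 0/1 driver x subtype matrix; every driver labels >= 1 subtype."""
    X = (rng.random((n_drivers, len(subtypes))) < density).astype(int)
    for i in range(n_drivers):
        if X[i].sum() == 0:
            X[i, rng.integers(len(subtypes))] = 1
    drivers = [f"driver{i + 1:02d}" for i in range(n_drivers)]
    return pd.DataFrame(X, index=drivers, columns=list(subtypes))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen."""

    n_drivers: int = 34
    subtype_matrix: pd.DataFrame | None = None  # default: random at `density`
    subtype_weights: pd.DataFrame | None = None  # default: all zero
    baseline: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    temperature_effect: dict = field(
        default_factory=lambda: dict(DEFAULT_TEMPERATURE_EFFECT)
    )
    flies_per_genotype: int = 16
    count_lambda: float = 2.0  # mean beam-break count of an active minute
    death_prob: float = 0.01
    density: float = 0.25
    seed: int = 0

    def resolve(self, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
        X = (
            self.subtype_matrix
            if self.subtype_matrix is not None
            else random_subtype_matrix(self.n_drivers, rng, density=self.density)
        )
        W = self.subtype_weights if self.subtype_weights is not None else zero_weights()
        missing = set(X.columns) - set(W.index)
        if missing:
            raise ValueError(f"subtype_weights missing rows for subtypes: {sorted(missing)}")
        return X, W


@dataclass
class GroundTruth:
    """What the generator actually used, for estimator-closure checks."""

    rates: pd.DataFrame  # genotype, day_role, phase, p_doze, p_wake
    subtype_matrix: pd.DataFrame
    subtype_weights: pd.DataFrame
    death_minute: dict[str, int | None]

    def to_json(self, path) -> None:
        payload = {
            "rates": self.rates.to_dict(orient="records"),
            "subtype_matrix": self.subtype_matrix.to_dict(orient="index"),
            "subtype_weights": self.subtype_weights.to_dict(orient="index"),
            "death_minute": self.death_minute,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def genotype_rates(
    baseline: dict,
    temperature_effect: dict,
    subtype_shift: dict | None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Per (day_role, phase) -> (p_doze, p_wake) for one genotype.

    ``subtype_shift`` maps the four logit channels (e.g. ``p_wake_DP``) to
    additive shifts; None means a control genotype.  Activation-day rates
    stack the temperature effect and (experimental only) the subtype shifts
    on the logit scale.
    """
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for role in DAY_ROLES:
        for phase in PHASES:
            vals = []
            for p in ("p_doze", "p_wake"):
                x = logit(baseline[(phase, p)])
                if role == "activation":
                    x += temperature_effect.get(p, 0.0)
                    if subtype_shift is not None:
                        x += subtype_shift.get(f"{p}_{phase}", 0.0)
                vals.append(float(expit(x)))
            if not all(0 < v < 1 for v in vals):
                raise ValueError(f"transition probability out of (0,1) for {role}/{phase}")
            out[(role, phase)] = (vals[0], vals[1])
    return out


def stationary_inactive_fraction(p_doze: float, p_wake: float) -> float:
    """Long-run inactive fraction of the two-state chain."""
    return p_doze / (p_doze + p_wake)


def simulate_day_vec(
    p_doze: np.ndarray,
    p_wake: np.ndarray,
    rng: np.random.Generator,
    photoperiod: int = 720,
) -> np.ndarray:
    """Simulate one day (1440 min) for many flies with per-fly rates.

    ``p_doze`` and ``p_wake`` are (n_flies, 2) arrays with columns (LP, DP).
    Minute 0 is drawn from each fly's LP stationary distribution; the
    transition from minute t to t+1 uses the phase of minute t.  Returns
    int8 states (n_flies, 1440): 1 active, 0 inactive.
    """
    p_doze = np.atleast_2d(np.asarray(p_doze, float))
    p_wake = np.atleast_2d(np.asarray(p_wake, float))
    n = p_doze.shape[0]
    states = np.empty((n, MINUTES_PER_DAY), dtype=np.int8)
    pi_inactive = stationary_inactive_fraction(p_doze[:, 0], p_wake[:, 0])
    states[:, 0] = (rng.random(n) >= pi_inactive).astype(np.int8)
    u = rng.random((n, MINUTES_PER_DAY - 1))
    for t in range(MINUTES_PER_DAY - 1):
        col = 0 if t < photoperiod else 1
        cur = states[:, t]
        flip = np.where(cur == 1, u[:, t] < p_doze[:, col], u[:, t] < p_wake[:, col])
        states[:, t + 1] = np.where(flip, 1 - cur, cur)
    return states


def simulate_day_batch(
    n_flies: int,
    rates: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    photoperiod: int = 720,
) -> np.ndarray:
    """Simulate one day for ``n_flies`` flies sharing one set of phase rates."""
    p_doze = np.tile([rates["LP"][0], rates["DP"][0]], (n_flies, 1))
    p_wake = np.tile([rates["LP"][1], rates["DP"][1]], (n_flies, 1))
    return simulate_day_vec(p_doze, p_wake, rng, photoperiod)


def counts_from_states(
    states: np.ndarray, count_lambda: float, rng: np.random.Generator
) -> np.ndarray:
    """Beam-break counts: active minutes emit 1 + Poisson(λ − 1), inactive 0."""
    if count_lambda < 1:
        raise ValueError("count_lambda must be >= 1 (an active minute breaks the beam)")
    extra = rng.poisson(count_lambda - 1.0, size=states.shape)
    return np.where(states == 1, 1 + extra, 0).astype(np.int64)


def simulate_fly(
    rates_by_day: dict[tuple[str, str], tuple[float, float]],
    rng: np.random.Generator,
    count_lambda: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One fly's 3-day (states, counts), days in baseline/activation/recovery order."""
    days = []
    for role in DAY_ROLES:
        rates = {ph: rates_by_day[(role, ph)] for ph in PHASES}
        days.append(simulate_day_batch(1, rates, rng)[0])
    states = np.concatenate(days)
    return states, counts_from_states(states, count_lambda, rng)


@dataclass
class ScreenData:
    """An in-memory simulated screen.

    ``states``/``counts`` are (n_flies, 3*1440) arrays, row-aligned with
    ``flies`` (fly_id, genotype, driver, genotype_role, monitor, channel).
    Minute columns run baseline, activation, recovery, each day starting at
    lights-on (ZT 0).
    """

    flies: pd.DataFrame
    states: np.ndarray
    counts: np.ndarray
    design: ExperimentDesign
    truth: GroundTruth

    def day_states(self, day_role: str) -> np.ndarray:
        i = DAY_ROLES.index(day_role)
        return self.states[:, i * MINUTES_PER_DAY:(i + 1) * MINUTES_PER_DAY]


def simulate_screen(config: SimulationConfig) -> ScreenData:
    """Simulate a full screen in memory (see :func:`write_screen` for files)."""
    rng = np.random.default_rng(config.seed)
    X, W = config.resolve(rng)
    drivers = list(X.index)

    fly_rows = []
    rate_rows = []
    geno_rates: list[dict] = []
    for driver in drivers:
        shift = (X.loc[driver] @ W).to_dict()
        for role_name, geno_suffix, subtype_shift in (
            ("experimental", "xTrpA1", shift),
            ("gal4_control", "xWT", None),
            ("uas_control", "WTxTrpA1", None),
        ):
            genotype = f"{driver}-{geno_suffix}" if role_name != "uas_control" else geno_suffix
            rates = genotype_rates(config.baseline, config.temperature_effect, subtype_shift)
            geno_rates.append({"driver": driver, "genotype_role": role_name, "rates": rates})
            for (role, phase), (pd_, pw_) in rates.items():
                rate_rows.append(
                    {
                        "driver": driver,
                        "genotype": genotype,
                        "genotype_role": role_name,
                        "day_role": role,
                        "phase": phase,
                        "p_doze": pd_,
                        "p_wake": pw_,
                    }
                )
            for f in range(config.flies_per_genotype):
                fly_rows.append(
                    {
                        "fly_id": f"{driver}-{role_name}-{f + 1:02d}",
                        "genotype": genotype,
                        "driver": driver,
                        "genotype_role": role_name,
                    }
                )
    flies = pd.DataFrame(fly_rows)
    n = len(flies)
    flies["monitor"] = [f"M{(i // dam_io.N_CHANNELS) + 1:03d}" for i in range(n)]
    flies["channel"] = [(i % dam_io.N_CHANNELS) + 1 for i in range(n)]

    n_per_geno = config.flies_per_genotype
    states = np.empty((n, 3 * MINUTES_PER_DAY), dtype=np.int8)
    for di, role in enumerate(DAY_ROLES):
        p_doze_arr = np.empty((n, 2))
        p_wake_arr = np.empty((n, 2))
        for gi, g in enumerate(geno_rates):
            rows = slice(gi * n_per_geno, (gi + 1) * n_per_geno)
            for col, ph in enumerate(PHASES):
                dz, wk = g["rates"][(role, ph)]
                p_doze_arr[rows, col] = dz
                p_wake_arr[rows, col] = wk
        states[:, di * MINUTES_PER_DAY:(di + 1) * MINUTES_PER_DAY] = simulate_day_vec(
            p_doze_arr, p_wake_arr, rng
        )
    counts = counts_from_states(states, config.count_lambda, rng)

    death_minute: dict[str, int | None] = {}
    dead = rng.random(n) < config.death_prob
    death_times = rng.integers(0, 3 * MINUTES_PER_DAY, size=n)
    for i, fly_id in enumerate(flies["fly_id"]):
        if dead[i]:
            t = int(death_times[i])
            states[i, t:] = 0
            counts[i, t:] = 0
            death_minute[fly_id] = t
        else:
            death_minute[fly_id] = None

    # Day roles are attributed by calendar date; putting lights-on at
    # midnight makes each simulated zeitgeber day exactly one calendar day,
    # so every design day carries its full 720 LP + 720 DP minutes.
    start = dt.date(2024, 1, 1)
    design = ExperimentDesign(
        lights_on=dt.time(0, 0),
        day_roles={start + dt.timedelta(days=i): role for i, role in enumerate(DAY_ROLES)},
    )
    truth = GroundTruth(
        rates=pd.DataFrame(rate_rows),
        subtype_matrix=X,
        subtype_weights=W,
        death_minute=death_minute,
    )
    return ScreenData(flies=flies, states=states, counts=counts, design=design, truth=truth)


def write_screen(screen: ScreenData, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated screen as canonical DAM monitor files + metadata.

    Emits one monitor file per 32 flies, ``channel_map.csv``,
    ``design.yaml`` and ``ground_truth.json``; returns the monitor
    name -> path mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_minutes = screen.counts.shape[1]
    base_date = min(screen.design.day_roles)
    t0 = dt.datetime.combine(base_date, screen.design.lights_on)
    timestamps = [t0 + dt.timedelta(minutes=m) for m in range(n_minutes)]

    monitor_paths: dict[str, Path] = {}
    for monitor, grp in screen.flies.groupby("monitor", sort=True):
        block = np.zeros((n_minutes, dam_io.N_CHANNELS), dtype=np.int64)
        for i, row in grp.iterrows():
            block[:, int(row["channel"]) - 1] = screen.counts[i]
        readings = [
            MonitorReading(
                timestamps[m], 1, tuple(int(c) for c in block[m]), index=m + 1
            )
            for m in range(n_minutes)
        ]
        path = outdir / f"{monitor}.txt"
        dam_io.write_dam_monitor(readings, path)
        monitor_paths[str(monitor)] = path

    screen.flies[["monitor", "channel", "fly_id", "genotype", "driver", "genotype_role"]].to_csv(
        outdir / "channel_map.csv", index=False
    )
    screen.design.to_yaml(outdir / "design.yaml")
    screen.truth.to_json(outdir / "ground_truth.json")
    return monitor_paths


def expected_scored_sleep_fraction(
    p_doze: float, p_wake: float, min_bout: int = 5
) -> float:
    """Stationary fraction of minutes inside inactive runs of length >= min_bout.

    Alternating-renewal closed form: active runs are geometric with mean
    1/p_doze and inactive runs geometric with mean 1/p_wake, so the fraction
    of time spent in scoreable sleep is E[L; L >= m] / (E[A] + E[L]) with
    E[L; L >= m] = q^(m-1) (m + q/p_wake), q = 1 - p_wake.
    """
    q = 1.0 - p_wake
    tail_mean = q ** (min_bout - 1) * (min_bout + q / p_wake)
    return tail_mean / (1.0 / p_doze + 1.0 / p_wake)


def balanced_fragmentation_shift(
    baseline: dict,
    temperature_effect: dict,
    wake_shift: float,
    phase: str,
    min_bout: int = 5,
) -> float:
    """Doze-logit shift that fragments sleep without changing its total.

    Given a wake-rate increase of ``wake_shift`` logits on the activation
    day, solve for the doze-logit shift that leaves the expected scored
    sleep fraction (runs >= min_bout) equal to the temperature-only value —
    i.e. pure fragmentation: more, shorter bouts, same total sleep.
    """
    from scipy.optimize import brentq

    base_d = logit(baseline[(phase, "p_doze")]) + temperature_effect.get("p_doze", 0.0)
    base_w = logit(baseline[(phase, "p_wake")]) + temperature_effect.get("p_wake", 0.0)
    target = expected_scored_sleep_fraction(expit(base_d), expit(base_w), min_bout)
    pw1 = expit(base_w + wake_shift)

    def gap(d):
        return expected_scored_sleep_fraction(expit(base_d + d), pw1, min_bout) - target

    return float(brentq(gap, 0.0, 10.0))
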