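"""End-to-end orchestration: monitor files in, analysis tables out.

A run loads every mapped fly, applies the dead-fly filter, scores sleep
metrics and transition probabilities, computes per-fly deltas and the
control-corrected per-driver coordinates, clusters drivers in ΔP space per
phase, fits the subtype GLM on change rates, and runs the three-group
significance battery per driver — writing one CSV per stage plus a JSON
manifest (seed, config hash, package version) so identical inputs yield
byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dam_io, deltas, group_stats, sleep_metrics, transitions
from .clustering import DeltaPClusterer
from .subtype_glm import glm_table


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    monitor_paths: dict[str, str]  # monitor name -> file path
    channel_map: str
    design: str
    subtype_matrix: str | None = None
    outdir: str = "results"
    min_bout: int = 5
    alpha: float = 0.05
    k_candidates: tuple[int, ...] = (3, 4, 5)
    gmm_n_init: int = 20
    gmm_reg: float = 1e-6
    min_active_minutes_last_day: int = 1
    straddle: str = "start"
    cluster_drivers: list[str] | None = None  # default: all drivers
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.k_candidates:
            raise ValueError("k_candidates must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "k_candidates" in raw:
            raw["k_candidates"] = tuple(raw["k_candidates"])
        return cls(**raw)

    def canonical_hash(self) -> str:
        # outdir is where results land, not an analysis input
        payload = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self).items()
                if k != "outdir"
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the stage-output path map."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    def load():
        cm = dam_io.read_channel_map(config.channel_map)
        design = dam_io.ExperimentDesign.from_yaml(config.design)
        series = dam_io.load_screen(config.monitor_paths, cm, design)
        decisions = [
            dam_io.filter_dead_flies(s, config.min_active_minutes_last_day) for s in series
        ]
        kept = [s for s, d in zip(series, decisions) if d.keep]
        qc = pd.DataFrame(
            [
                {
                    "fly_id": d.fly_id,
                    "keep": d.keep,
                    "active_minutes_recovery": d.active_minutes_last_day,
                    "reason": d.reason,
                }
                for d in decisions
            ]
        )
        return kept, qc

    series, qc = stage("load", load)
    outputs["fly_qc"] = outdir / "fly_qc.csv"
    _write_csv(qc, outputs["fly_qc"])

    metrics = stage(
        "score",
        lambda: sleep_metrics.metrics_table(
            series, min_bout=config.min_bout, straddle=config.straddle
        ),
    )
    outputs["metrics"] = outdir / "metrics.csv"
    _write_csv(metrics, outputs["metrics"])

    trans = stage("transitions", lambda: transitions.transition_table(series))
    outputs["transitions"] = outdir / "transitions.csv"
    _write_csv(trans, outputs["transitions"])

    def make_deltas():
        sleep_d = deltas.per_fly_delta(metrics, deltas.SLEEP_PARAMETERS, "activation")
        prob_d = deltas.per_fly_delta(trans, deltas.PROB_PARAMETERS, "activation")
        points = deltas.driver_points(prob_d)
        points = points[points["driver"] != ""]
        rates = deltas.driver_change_rates(metrics)
        return sleep_d, prob_d, points, rates

    sleep_d, prob_d, points, rates = stage("deltas", make_deltas)
    outputs["fly_deltas"] = outdir / "fly_deltas.csv"
    _write_csv(pd.concat([sleep_d, prob_d], ignore_index=True), outputs["fly_deltas"])
    outputs["driver_points"] = outdir / "driver_points.csv"
    _write_csv(points, outputs["driver_points"])
    outputs["change_rates"] = outdir / "change_rates.csv"
    _write_csv(rates, outputs["change_rates"])

    def cluster():
        rows = []
        models = {}
        for phase in ("LP", "DP"):
            sub = points[points["phase"] == phase].dropna(subset=["d_p_wake", "d_p_doze"])
            if config.cluster_drivers is not None:
                sub = sub[sub["driver"].isin(config.cluster_drivers)]
            X = sub[["d_p_wake", "d_p_doze"]].to_numpy()
            if len(X) <= min(config.k_candidates):
                continue
            est = DeltaPClusterer(
                k_candidates=config.k_candidates,
                n_init=config.gmm_n_init,
                reg=config.gmm_reg,
                random_state=config.seed,
            ).fit(X)
            for driver, label in zip(sub["driver"], est.labels_):
                rows.append({"driver": driver, "phase": phase, "cluster": int(label)})
            models[phase] = {
                "chosen_k": est.chosen_k_,
                "silhouettes": {str(k): v for k, v in est.silhouettes_.items()},
                "weights": est.model_.weights.tolist(),
                "means": est.model_.means.tolist(),
                "covariances": est.model_.covariances.tolist(),
                "log_likelihood": est.model_.log_likelihood,
            }
        return pd.DataFrame(rows), models

    cluster_df, models = stage("cluster", cluster)
    outputs["clustering"] = outdir / "clustering.csv"
    _write_csv(cluster_df, outputs["clustering"])
    outputs["gmm_models"] = outdir / "gmm_models.json"
    outputs["gmm_models"].write_text(json.dumps(models, indent=1, sort_keys=True))

    def glm():
        if config.subtype_matrix is None:
            return pd.DataFrame()
        X = pd.read_csv(config.subtype_matrix, index_col=0)
        known = set(X.index)
        have = set(rates["driver"]) - {""}
        unknown = have - known
        if unknown:
            raise ValueError(f"change rates name drivers absent from subtype matrix: {sorted(unknown)}")
        return glm_table(X, rates[rates["driver"] != ""], alpha=config.alpha)

    glm_df = stage("glm", glm)
    outputs["glm"] = outdir / "glm_table.csv"
    _write_csv(glm_df, outputs["glm"])

    def stats():
        rows = []
        both = pd.concat([sleep_d, prob_d], ignore_index=True)
        params = list(deltas.SLEEP_PARAMETERS) + list(deltas.PROB_PARAMETERS)
        for (driver, phase), grp in both[both["driver"] != ""].groupby(["driver", "phase"]):
            for param in params:
                if param not in grp.columns:
                    continue
                vals = grp.dropna(subset=[param])
                groups = {
                    role: vals.loc[vals["genotype_role"] == role, param].to_numpy()
                    for role in dam_io.GENOTYPE_ROLES
                }
                if any(len(g) < 2 for g in groups.values()):
                    continue
                res = group_stats.compare_to_controls(
                    groups["experimental"],
                    groups["gal4_control"],
                    groups["uas_control"],
                    alpha=config.alpha,
                )
                row = {
                    "driver": driver,
                    "parameter": param,
                    "phase": phase,
                    "test": res.test_used,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "significant_overall": res.significant_overall,
                }
                for c in res.comparisons:
                    row[f"{c.name}_diff"] = c.mean_difference
                    row[f"{c.name}_p_adj"] = c.p_adjusted
                rows.append(row)
        return pd.DataFrame(rows)

    stats_df = stage("stats", stats)
    outputs["group_stats"] = outdir / "group_stats.csv"
    _write_csv(stats_df, outputs["group_stats"])

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.canonical_hash(),
        "n_flies_loaded": int(len(qc)),
        "n_flies_kept": int(qc["keep"].sum()),
        "outputs": {k: p.name for k, p in sorted(outputs.items())},
    }
    outputs["manifest"] = outdir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outputs
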