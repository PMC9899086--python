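# sleepscreen

Analysis stack for *Drosophila* thermogenetic sleep screens recorded on
Trikinetics DAM2 activity monitors, built around the transition-probability
view of fly sleep: **P(doze)**, the per-minute probability that an active fly
becomes inactive (a proxy for sleep pressure), and **P(wake)**, the reverse
transition (a proxy for sleep depth / arousability).

It is written for labs running GAL4 × UAS-dTrpA1 activation screens on a
three-day baseline / activation / recovery design (21 °C / 30 °C / 21 °C,
12 h:12 h light–dark) and covers the whole path from raw monitor text files
to subtype-level statistics:

* **dam_io** — DAM2 monitor parsing, 1-minute binning (missing minutes stay
  missing, never imputed as zero), day-role/phase/ZT annotation, dead-fly QC.
* **sleep_metrics** — sleep bouts as maximal runs of ≥ 5 min inactivity;
  total sleep, episode count and maximum episode length per light phase.
* **transitions** — P(wake) and P(doze) as transition frequencies on raw
  1-minute activity states, per fly × day × phase, with opportunity counts.
* **deltas** — per-fly activation − baseline changes, the genetic-control
  correction `Δ_exp − (Δ_GAL4 + Δ_UAS)/2` that removes the pure temperature
  effect, and per-driver change rates `(activation − baseline)/baseline`.
* **clustering** — `DeltaPClusterer`, a full-covariance Gaussian-mixture
  clusterer over per-driver (ΔP(wake), ΔP(doze)) points with silhouette-based
  choice of k ∈ {3, 4, 5} and per-cluster σ ellipses.
* **subtype_glm** — `SubtypeEffectsGLM`, ordinary least squares of driver
  change rates on the 0/1 ring-neuron subtype design matrix
  (R1, R2, R3a, R3d, R3m, R3p, R3w, R4d, R4m, R5, R6), with sign + p < 0.05
  effect classification. Both estimators follow the scikit-learn API.
* **group_stats** — normality triage (D'Agostino–Pearson), one-way ANOVA
  with Bonferroni planned comparisons or Kruskal–Wallis with Dunn's
  tie-corrected comparisons, the both-controls significance rule, and
  noncentral-t power analysis.
* **simulate** — a ground-truth generator: every fly is a two-state Markov
  chain with phase-, day- and genotype-dependent rates on the logit scale,
  written out as genuine DAM2 files.
* **pipeline / cli** — an end-to-end `sleepscreen` command with one
  subcommand per stage and a reproducible `run`.

## Worked example

Simulate a small screen and push it through the pipeline:

```sh
sleepscreen simulate --n-drivers 14 --flies-per-genotype 8 --seed 1 --outdir screen
sleepscreen score --monitor-dir screen --channel-map screen/channel_map.csv \
    --design screen/design.yaml --out metrics.csv
```

or, from Python, estimate transition probabilities for simulated flies with
known rates:

```python
>>> import numpy as np, sleepscreen as ss
>>> from sleepscreen.simulate import simulate_day_batch
>>> rng = np.random.default_rng(0)
>>> states = simulate_day_batch(32, {"LP": (0.30, 0.10), "DP": (0.30, 0.10)}, rng)
>>> pooled = ss.pool([ss.estimate(s) for s in states])
>>> round(pooled.p_doze, 3), round(pooled.p_wake, 3)
(0.299, 0.102)
>>> ss.power_ttest(30, 30, mean0=0.0, sd0=1.0, mean1=1.0).power
0.9677082582419323
```

The pooled estimates sit within binomial error of the configured
(p_doze, p_wake) = (0.30, 0.10), and the analytic two-sample power at
effect/SD = 1 with n = 30 per group is 0.968 — the probability that a
control-vs-experimental comparison of that size detects a one-SD sleep
change.

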