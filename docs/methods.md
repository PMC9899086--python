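# Methods

## The screen and its effect sizes

The package analyzes three-day thermogenetic activation screens: one
baseline day at 21 °C, one activation day at 30 °C (the warmth-gated
channel dTrpA1 fires the GAL4-labeled neurons), one recovery day at 21 °C,
all under 12 h:12 h light–dark. Each driver contributes three genotypes:
the experimental cross (driver × effector) and two genetic controls
(driver × wild type, wild type × effector) that undergo the same
temperature step without effector expression.

Because warmth itself alters fly sleep, raw activation − baseline changes
confound neuronal activation with temperature. The screen's effect size is
therefore doubly differenced: per-fly paired differences against the
baseline day, averaged per genotype, then corrected as

    Δ_corrected = Δ_exp − (Δ_GAL4 + Δ_UAS) / 2.

The correction is linear and invariant to adding any constant to all three
genotypes, which is exactly the model of a shared temperature effect; the
simulator validates this by construction (a temperature-only screen yields
biased raw deltas and zero-centered corrected deltas).

## Sleep scoring

Activity is binarized per minute (active iff any beam break); sleep is a
maximal run of at least `min_bout` = 5 consecutive inactive minutes, the
standard fly-sleep convention. Three metrics are reported per fly × day ×
light phase: total sleep minutes, episode count, maximum episode length.

Scoring rules in corner cases, all configurable or documented:

* **Missing minutes** (gaps, invalid monitor status) break runs and are
  excluded from all denominators. Zero-imputation would fabricate sleep.
* **Phase-straddling bouts** contribute their minutes to the phase they
  occur in; the episode is counted once, in the phase containing its start
  (`straddle="start"`). The `"both"` dialect counts it in both phases.
  Under the default dialect a phase can therefore hold sleep minutes from
  a bout that started in the other phase while counting zero episodes.
* **Day boundaries**: days are scored independently (they differ in role
  and temperature); bouts do not continue across days. Day role is keyed
  by calendar date, with ZT 0 at lights-on and LP = ZT [0, 720).

## Transition probabilities

P(wake) = #(inactive→active) / #(inactive minutes with an observed
successor); P(doze) analogously with the roles reversed. The estimator
operates on raw 1-minute states, not on 5-min sleep-scored states: the two
probabilities are meant to capture sleep pressure and depth at the
resolution the monitor provides. A pair (t, t+1) is attributed to the
phase of minute t; the successor may cross the phase boundary. Estimates
with zero opportunities are undefined (NaN) and propagate — 0/0 is never
reported as 0. Per-driver coordinates are computed per fly, averaged per
genotype, then control-corrected (pooled-count estimation is also
available via `pool`).

For a stationary two-state chain the estimator is the maximum-likelihood
transition frequency and is validated against the generator's ground truth
and the closed-form stationary inactive fraction p_doze/(p_doze + p_wake).

## Gaussian-mixture clustering of drivers

Drivers are clustered in the 2-D (ΔP(wake), ΔP(doze)) plane, one point per
driver per phase. The mixture is full-covariance, fit by EM with
k-means++ seeding, `n_init` = 20 seeded restarts (best final
log-likelihood kept), covariance regularization 1e-6·I, tolerance 1e-6,
max 500 iterations. The per-iteration log-likelihood trace is retained and
checked non-decreasing — the EM monotonicity guarantee — on every fit.
k is chosen among {3, 4, 5} (screen-sized inputs are ~14 points) by
maximal mean silhouette over hard maximum-posterior labels; silhouette is
bounded above by one, so "closest to one" is the maximum. Singleton
clusters contribute silhouette 0; ties prefer the smaller k. Cluster
extent is reported as n·σ ellipses from the eigendecomposition of each
component covariance.

The EM is implemented in-package because the trace, the per-component σ
ellipses and the seeded-restart protocol are all part of the analysis
contract; tests cross-check the attained likelihood and the silhouette
values against scikit-learn's independent implementations.

## Subtype GLM

The response for each sleep parameter and phase is the driver's mean
change rate (activation − baseline)/baseline over its experimental flies,
with zero-baseline flies excluded and counted. The design is the 0/1
driver × subtype membership matrix over the canonical eleven ring-neuron
subtypes. The model is OLS with an intercept — the identity-link,
normal-error GLM, the default of standard GLM-fitting routines — with
two-sided t tests on the coefficients at residual degrees
of freedom. All drivers enter the fit, not only the individually
significant ones: the point of the model is to pool weak per-driver
evidence across overlapping expression patterns.

Exactly collinear columns are dropped (later column loses) with a warning;
condition numbers above 1e8 warn without dropping. Raw p-values are
reported by default, mirroring how such tables are printed; a
Benjamini–Hochberg option exists but is off. A subtype is classified
positive/negative for a parameter when its weight has that sign with
p < α = 0.05.

## Group statistics and the both-controls rule

Per driver × parameter × phase, the per-fly deltas of the three genotypes
are compared: D'Agostino–Pearson normality triage per group (all groups
must pass at α = 0.05 and have n ≥ 8, the omnibus test's validity floor),
then either one-way ANOVA with two planned pooled-variance comparisons
(experimental vs each control, Bonferroni factor 2 — the control-vs-control
contrast is never tested) or Kruskal–Wallis with Dunn's z on tie-corrected
mean ranks, adjusted p = min(1, 2·p_raw). Because tables built on ranks
report differences in rank units while readers think in raw units, both the
raw-mean and mean-rank differences are carried.

An effect is called only when the experimental group differs from **both**
controls — under the global null this compound rule fires at roughly α²
(slightly above, since both contrasts share the experimental group), which
the calibration tests measure directly.

Power follows the screen convention: null at the control group's mean and
SD, alternative at the experimental mean, two-sample two-sided t power via
the noncentral t distribution. At zero effect the power equals α exactly.

## The synthetic-data generator

Each fly is a two-state (active/inactive) Markov chain at 1-minute
resolution, homogeneous within a phase, first minute drawn from the LP
stationary distribution. Effects stack additively on the logit scale so
any combination of shifts keeps probabilities in (0, 1):

* baseline rates (p_doze, p_wake) = (0.15, 0.25) in LP and (0.30, 0.10) in
  DP — modest, fragmented day sleep (stationary inactive fraction 0.375)
  and consolidated night sleep (0.75), typical of mated females;
* a temperature effect on the activation day for **all** genotypes:
  +0.4 logit on p_wake, −0.2 on p_doze (warmth mildly suppresses sleep);
* subtype effects X[driver]·W, applied only to the experimental genotype
  and only on the activation day (the effector fires only when warm);
  the recovery day returns to baseline rates — homeostatic rebound is
  deliberately not modeled.

Defaults: 34 drivers, 16 flies per genotype, subtype-membership density
0.25 (every driver labels at least one subtype), active minutes emit
1 + Poisson(λ − 1) counts with λ = 2, death probability 0.01 per fly at a
uniform random minute (zero counts afterwards). Screens are written as
canonical DAM2 monitor files plus channel map, design YAML and a
ground-truth JSON, byte-reproducible from the seed.

For fragmentation scenarios the generator provides an alternating-renewal
closed form for the expected scored-sleep fraction
(E[L; L ≥ m]/(E[A] + E[L]) with geometric run lengths) and solves for the
doze shift that holds it constant while the wake rate rises — more,
shorter bouts at unchanged total sleep. The balance equation has no
solution for large wake shifts in the light phase (the ceiling at
p_doze → 1 falls below the target), which bounds how hard sleep can be
fragmented without losing total sleep; scenario checks use +0.5 logit,
where a balancing shift exists in both phases.

What the simulator does **not** emulate: within-phase circadian ramps,
inter-fly rate heterogeneity beyond genotype, homeostatic rebound,
temperature transients at the day boundaries, and monitor artifacts other
than whole-minute dropouts. Passing recovery tests therefore demonstrate
estimator correctness under the stated chain model, not robustness to
every feature of real recordings.

## Validation design and problem sizes

Monte-Carlo checks run at sizes chosen to keep the full suite in a few
minutes while leaving Monte-Carlo error well below the asserted margins:
bout scoring against a brute-force enumerator (1000 random vectors);
transition recovery with 32 flies/day; GMM selection over 100 seeded
replicates of 3 clusters at 10 SD separation; GLM calibration with 500
noise replicates on one fixed 34 × 11 design (redrawing ill-conditioned
binary designs per replicate produces heavy-tailed weight distributions
that say nothing about the estimator); the both-controls rule over 1000
null screens; power against a 100 000-replicate Monte-Carlo; and 100
end-to-end screens for the nighttime wake-promoting scenario, via
vectorized metric/transition kernels tested element-equal to the per-fly
paths. Statistical assertions use explicit error bands (binomial or
Monte-Carlo SE) rather than fixed decimals, with per-family multiplicity
taken into account when many coefficients are checked at once.

## Known limitations

* The DAM reader handles single-beam DAM2 text; multi-beam monitors and
  environmental sensor channels are out of scope.
* Pooled-vs-per-fly transition estimation defaults to per-fly-then-average;
  the pooled path is exposed but not the default.
* The subtype design matrix is user-supplied; the package does not infer
  expression patterns.
* Cluster-membership for the ΔP clustering is a user decision (all drivers
  by default); no significance pre-filter is applied automatically.
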