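"""The synthetic screen generator: chain law, closures, determinism, format."""

import numpy as np
import pandas as pd
import pytest

import sleepscreen as ss
from sleepscreen.simulate import (
    SimulationConfig,
    genotype_rates,
    random_subtype_matrix,
    simulate_day_batch,
    simulate_fly,
    simulate_screen,
    stationary_inactive_fraction,
    zero_weights,
)


class TestChain:
    def test_pdoze_zero_means_never_inactive(self, rng):
        states = simulate_day_batch(5, {"LP": (1e-12, 0.3), "DP": (1e-12, 0.3)}, rng)
        # the active state is (numerically) absorbing once entered
        assert states.sum() >= states.size - 5  # at most the initial minutes inactive
        scored = [ss.score_bouts(s) for s in states]
        assert all(len(b) == 0 for b in scored)

    def test_symmetric_chain_half_inactive(self, rng):
        states = simulate_day_batch(30, {"LP": (0.5, 0.5), "DP": (0.5, 0.5)}, rng)
        frac = 1 - states.mean()
        se = 0.5 / np.sqrt(states.size)  # conservative: treats minutes as independent
        assert abs(frac - 0.5) < 5 * se

    def test_longrun_inactive_fraction_matches_closed_form(self, rng):
        for _ in range(5):
            p_doze = rng.uniform(0.05, 0.6)
            p_wake = rng.uniform(0.05, 0.6)
            states = simulate_day_batch(
                10, {"LP": (p_doze, p_wake), "DP": (p_doze, p_wake)}, rng
            )
            expected = stationary_inactive_fraction(p_doze, p_wake)
            frac = 1 - states.mean()
            # autocorrelated chain: effective n is reduced by (1+rho)/(1-rho)
            rho = 1 - p_doze - p_wake
            n_eff = states.size * (1 - rho) / (1 + rho)
            se = np.sqrt(expected * (1 - expected) / n_eff)
            assert abs(frac - expected) < 4 * se

    def test_estimator_closure(self, rng):
        """transitions.estimate recovers the configured probabilities."""
        p_doze, p_wake = 0.22, 0.14
        states = simulate_day_batch(64, {"LP": (p_doze, p_wake), "DP": (p_doze, p_wake)}, rng)
        pooled = ss.pool([ss.estimate(s) for s in states])
        se_d = np.sqrt(p_doze * (1 - p_doze) / pooled.n_doze_opportunities)
        se_w = np.sqrt(p_wake * (1 - p_wake) / pooled.n_wake_opportunities)
        assert abs(pooled.p_doze - p_doze) < 3 * se_d
        assert abs(pooled.p_wake - p_wake) < 3 * se_w

    def test_counts_positive_iff_active(self, rng):
        states, counts = simulate_fly(
            genotype_rates(dict(ss.simulate.DEFAULT_BASELINE), {}, None), rng
        )
        assert np.array_equal(counts > 0, states == 1)
        assert len(states) == 3 * 1440


class TestGenotypeRates:
    def test_controls_get_temperature_shift_only_on_activation(self):
        base = dict(ss.simulate.DEFAULT_BASELINE)
        rates = genotype_rates(base, {"p_wake": 0.4, "p_doze": -0.2}, None)
        assert rates[("baseline", "LP")] == rates[("recovery", "LP")]
        assert rates[("activation", "LP")][1] > rates[("baseline", "LP")][1]  # p_wake up
        assert rates[("activation", "LP")][0] < rates[("baseline", "LP")][0]  # p_doze down

    def test_subtype_shift_applies_to_experimental_activation_only(self):
        base = dict(ss.simulate.DEFAULT_BASELINE)
        shift = {"p_wake_DP": 2.0}
        rates = genotype_rates(base, {}, shift)
        assert rates[("activation", "DP")][1] > rates[("baseline", "DP")][1]
        assert rates[("activation", "LP")] == rates[("baseline", "LP")]
        assert rates[("recovery", "DP")] == rates[("baseline", "DP")]

    def test_invalid_probability_raises(self):
        base = {("LP", "p_doze"): 0.15, ("LP", "p_wake"): 0.25,
                ("DP", "p_doze"): 0.30, ("DP", "p_wake"): 0.10}
        with pytest.raises(ValueError, match="out of"):
            genotype_rates(base, {"p_wake": np.inf}, None)


class TestScreen:
    def test_seeded_determinism_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_drivers=2, flies_per_genotype=2, seed=11)
        a = simulate_screen(cfg)
        b = simulate_screen(cfg)
        ss.write_screen(a, tmp_path / "a")
        ss.write_screen(b, tmp_path / "b")
        for pa in sorted((tmp_path / "a").iterdir()):
            pb = tmp_path / "b" / pa.name
            assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_screen(SimulationConfig(n_drivers=1, flies_per_genotype=2, seed=0))
        b = simulate_screen(SimulationConfig(n_drivers=1, flies_per_genotype=2, seed=1))
        assert not np.array_equal(a.states, b.states)

    def test_three_genotypes_per_driver(self):
        scr = simulate_screen(SimulationConfig(n_drivers=4, flies_per_genotype=3, seed=2))
        per_driver = scr.flies.groupby("driver")["genotype_role"].nunique()
        assert (per_driver == 3).all()
        assert len(scr.flies) == 4 * 3 * 3

    def test_ground_truth_consistent_with_config(self):
        scr = simulate_screen(SimulationConfig(n_drivers=3, flies_per_genotype=2, seed=3))
        rates = scr.truth.rates
        base = rates[rates["day_role"] == "baseline"]
        assert np.allclose(
            base.loc[base["phase"] == "LP", "p_doze"].unique(), [0.15]
        )
        controls = rates[rates["genotype_role"] != "experimental"]
        # with zero subtype weights, controls and experimentals share rates
        exp = rates[rates["genotype_role"] == "experimental"]
        merged = exp.merge(controls, on=["driver", "day_role", "phase"], suffixes=("_e", "_c"))
        assert np.allclose(merged["p_doze_e"], merged["p_doze_c"])

    def test_files_round_trip_through_dam_io(self, tmp_path, small_screen):
        paths = ss.write_screen(small_screen, tmp_path)
        cm = ss.read_channel_map(tmp_path / "channel_map.csv")
        design = ss.ExperimentDesign.from_yaml(tmp_path / "design.yaml")
        series = ss.dam_io.load_screen(paths, cm, design)
        assert len(series) == len(small_screen.flies)
        # every fly's re-read counts equal the simulated counts
        for i, fas in enumerate(series[:5]):
            assert np.array_equal(fas.counts, small_screen.counts[i])

    def test_dead_flies_recorded_and_zeroed(self):
        scr = simulate_screen(
            SimulationConfig(n_drivers=2, flies_per_genotype=8, death_prob=0.5, seed=5)
        )
        dead = [f for f, t in scr.truth.death_minute.items() if t is not None]
        assert dead  # at 50% death probability some flies must die
        idx = scr.flies.set_index("fly_id").index
        for fly_id in dead:
            i = idx.get_loc(fly_id)
            t = scr.truth.death_minute[fly_id]
            assert scr.counts[i, t:].sum() == 0

    def test_weight_table_validation(self, rng):
        X = random_subtype_matrix(4, rng)
        W = zero_weights().drop("R5")
        cfg = SimulationConfig(n_drivers=4, subtype_matrix=X, subtype_weights=W)
        with pytest.raises(ValueError, match="R5"):
            simulate_screen(cfg)


class TestNullAndTemperatureClosures:
    def test_null_screen_corrected_deltas_center_on_zero(self):
        """Temperature effect only: raw deltas biased, corrected deltas ~0."""
        cfg = SimulationConfig(n_drivers=12, flies_per_genotype=12, death_prob=0.0, seed=21)
        scr = simulate_screen(cfg)
        from sleepscreen.transitions import batch_transition_counts

        d_raw, d_cor = [], []
        for phase, window in (("LP", slice(0, 720)), ("DP", slice(720, 1439))):
            est = {}
            for role in ("baseline", "activation"):
                nw, ow, nd, od = batch_transition_counts(scr.day_states(role), window)
                with np.errstate(invalid="ignore"):
                    est[role] = np.where(ow > 0, nw / ow, np.nan)
            delta = est["activation"] - est["baseline"]
            flies = scr.flies
            for driver, grp in flies.groupby("driver"):
                by_role = {
                    role: np.nanmean(delta[grp.index[grp["genotype_role"] == role]])
                    for role in ("experimental", "gal4_control", "uas_control")
                }
                d_raw.append(by_role["experimental"])
                d_cor.append(
                    ss.control_correct(
                        by_role["experimental"], by_role["gal4_control"], by_role["uas_control"]
                    )
                )
        d_raw, d_cor = np.array(d_raw), np.array(d_cor)
        # the temperature effect biases the raw deltas upward (p_wake shift +0.4 logit)
        assert d_raw.mean() > 3 * d_raw.std() / np.sqrt(len(d_raw))
        # ... but the genetic-control correction removes it
        assert abs(d_cor.mean()) < 3 * d_cor.std() / np.sqrt(len(d_cor))
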