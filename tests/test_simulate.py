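"""Behavioral simulator: allocation optima, noise/censoring, MGT choices."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ctblab import (
    AgentParams,
    DesignConfig,
    StudyConfig,
    TreatmentEffect,
    demand_mean,
    draw_population,
    optimal_allocation,
    simulate_mcg_allocation,
    simulate_mgt_choice,
    simulate_study,
)
from ctblab.design import default_mgt_payoffs
from ctblab.simulate import _simulate_mcg_table, reduced_study_config

from oracles import grid_argmax_allocation


def mcg_trial(t=0, k=35, d=0.9):
    return {"trial_id": 1, "t_days": t, "k_days": k, "discount_factor": d}


def mgt_trial(n_pink=3):
    pp, pb = default_mgt_payoffs()[n_pink]
    return {"trial_id": 1, "n_pink": n_pink, "token_color": "pink",
            "payoff_pink": pp, "payoff_blue": pb}


class TestOptimalAllocation:
    def test_linear_utility_corner(self):
        # B = 0.99^35 ~ 0.703 < d = 0.99: risk-neutral agent goes all-in early
        params = AgentParams(alpha=1.0, beta=1.0, delta=0.99)
        assert optimal_allocation(params, mcg_trial(t=0, k=35, d=0.99)) == 100.0

    def test_linear_utility_corner_later(self):
        # delta = 1 so B = 1 > d: everything later
        params = AgentParams(alpha=1.0, beta=1.0, delta=1.0)
        assert optimal_allocation(params, mcg_trial(t=35, k=35, d=0.9)) == 0.0

    def test_foc_closed_form_when_b_equals_d(self):
        # delta^k = d and t > 0 makes B = d, so the FOC ratio is 1 and the
        # allocation is endowment/(1 + d)
        delta = 0.8 ** (1 / 35)
        params = AgentParams(alpha=0.5, beta=1.3, delta=delta)
        a = optimal_allocation(params, mcg_trial(t=35, k=35, d=0.8))
        assert a == pytest.approx(100 / 1.8, abs=1e-9)

    @pytest.mark.parametrize("alpha,beta,delta,t,k,d", [
        (0.9, 1.05, 0.995, 0, 35, 0.9),
        (0.5, 1.3, 0.8 ** (1 / 35), 35, 35, 0.8),
        (0.7, 0.9, 0.999, 0, 90, 0.6),
        (0.95, 1.0, 0.99, 35, 72, 0.975),
    ])
    def test_matches_grid_maximization(self, alpha, beta, delta, t, k, d):
        params = AgentParams(alpha=alpha, beta=beta, delta=delta)
        a = optimal_allocation(params, mcg_trial(t=t, k=k, d=d))
        oracle = grid_argmax_allocation(alpha, beta, delta, t, k, d)
        assert a == pytest.approx(oracle, abs=1e-4)

    def test_known_interior_value(self):
        params = AgentParams(alpha=0.9, beta=1.05, delta=0.995)
        a = optimal_allocation(params, mcg_trial(t=0, k=35, d=0.9))
        assert a == pytest.approx(57.8896, abs=0.05)

    def test_monotone_in_discount_factor_and_delta(self):
        base = dict(alpha=0.85, beta=1.0, delta=0.995)
        a_prev = -1.0
        for d in np.linspace(0.5, 0.99, 12):
            a = float(demand_mean(**base, t_days=35, k_days=72, discount_factor=d))
            assert a >= a_prev  # more generous early rate, never less early
            a_prev = a
        late_prev = -1.0
        for delta in np.linspace(0.985, 0.999, 10):
            a = float(demand_mean(0.85, 1.0, delta, 35, 72, 0.8))
            late = 100 - a
            assert late >= late_prev  # more patient, never less later
            late_prev = late


class TestMCGSimulation:
    def test_noiseless_equals_optimum(self, rng):
        params = AgentParams(alpha=0.9, beta=1.05, delta=0.995, sigma_alloc=0.0)
        rec = simulate_mcg_allocation(params, mcg_trial(), rng)
        assert rec["tokens_early"] == pytest.approx(
            optimal_allocation(params, mcg_trial()), abs=1e-12)

    def test_grid_rounding_snaps_to_boxes(self, rng):
        params = AgentParams(alpha=0.9, sigma_alloc=0.0)
        rec = simulate_mcg_allocation(params, mcg_trial(), rng, rounding="grid10")
        assert rec["tokens_early"] % 10 == 0

    def test_endowment_conserved_exactly(self, rng):
        params = AgentParams(sigma_alloc=8.0)
        design = pd.DataFrame([mcg_trial(d=d) for d in (0.5, 0.7, 0.9, 0.99)] * 50)
        table = _simulate_mcg_table(params, design, rng, 100.0, "continuous",
                                    10, "indicator")
        assert (table["tokens_early"] + table["tokens_late"] == 100.0).all()
        assert np.allclose(table["x_t"],
                           table["discount_factor"] * table["tokens_early"])

    def test_censoring_rate_matches_normal_tail(self, rng):
        # latent mean g with large noise: P(censored at 100) = 1 - Phi((100-g)/sigma)
        params = AgentParams(alpha=0.9, beta=1.0, delta=0.9999, sigma_alloc=10.0)
        trial = mcg_trial(t=35, k=35, d=0.99)
        g = optimal_allocation(params, trial)
        design = pd.DataFrame([trial] * 8000)
        table = _simulate_mcg_table(params, design, rng, 100.0, "continuous",
                                    10, "indicator")
        expected = norm.sf((100.0 - g) / params.sigma_alloc)
        observed = (table["tokens_early"] >= 100.0).mean()
        mc_se = np.sqrt(expected * (1 - expected) / 8000)
        assert abs(observed - expected) < 4 * mc_se


class TestMGTSimulation:
    def test_greedy_limit_prefers_safe_color(self, rng):
        params = AgentParams(alpha=0.8, temp=1e-3)
        trial = mgt_trial(n_pink=5)  # pink is the safe majority color
        choices = [simulate_mgt_choice(params, trial, rng)["choice"]
                   for _ in range(200)]
        assert all(ch == "pink" for ch in choices)

    def test_uniform_limit_is_coin_flip(self, rng):
        params = AgentParams(alpha=0.8, temp=1e6)
        trial = mgt_trial(n_pink=5)
        picks = np.array([simulate_mgt_choice(params, trial, rng)["choice"]
                          for _ in range(2000)])
        assert abs((picks == "pink").mean() - 0.5) < 0.05

    def test_risk_neutral_indifferent_on_ev_constant_payoffs(self, rng):
        params = AgentParams(alpha=1.0, temp=0.05)
        trial = mgt_trial(n_pink=4)
        picks = np.array([simulate_mgt_choice(params, trial, rng)["choice"]
                          for _ in range(2000)])
        assert abs((picks == "pink").mean() - 0.5) < 0.05

    def test_points_follow_outcome(self, rng):
        params = AgentParams()
        rec = simulate_mgt_choice(params, mgt_trial(3), rng)
        if rec["won"]:
            assert rec["points"] > 0
        else:
            assert rec["points"] == 0


class TestPopulation:
    def test_default_population_counts(self):
        pop = draw_population(StudyConfig(), seed=1)
        s1 = pop[pop["session"] == 1]
        assert len(s1) == 57
        assert (s1["group"] == "probiotics").sum() == 29

    def test_zero_sd_gives_exact_means(self):
        cfg = StudyConfig(param_sds={k: 0.0 for k in
                                     ("alpha", "beta", "delta", "sigma_alloc", "temp")})
        pop = draw_population(cfg, seed=1)
        s1 = pop[pop["session"] == 1]
        for name, mean in cfg.param_means.items():
            assert (s1[name] == mean).all()

    def test_seed_reproducible(self):
        a = draw_population(StudyConfig(), seed=9)
        b = draw_population(StudyConfig(), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_treatment_shift_applies_to_probiotics_only(self):
        cfg = StudyConfig(
            param_sds={k: 0.0 for k in ("alpha", "beta", "delta", "sigma_alloc", "temp")},
            treatment=TreatmentEffect(d_beta=0.2))
        pop = draw_population(cfg, seed=2)
        s2 = pop[pop["session"] == 2]
        assert np.allclose(s2.loc[s2["group"] == "probiotics", "beta"], 1.21)
        assert np.allclose(s2.loc[s2["group"] == "placebo", "beta"], 1.01)

    def test_out_of_range_shift_clipped_and_logged(self, caplog):
        cfg = StudyConfig(treatment=TreatmentEffect(d_alpha=-5.0))
        with caplog.at_level(logging.WARNING, logger="ctblab.simulate"):
            pop = draw_population(cfg, seed=3)
        assert (pop[pop["session"] == 2].query("group == 'probiotics'")["alpha"]
                > 0).all()
        assert any("clipped" in r.message for r in caplog.records)


class TestStudySimulation:
    def test_row_counts_tiny_study(self, tiny_study_config):
        mcg, mgt, pay = simulate_study(tiny_study_config, seed=5)
        assert len(mcg) == 4 * 60 * 2
        assert len(mgt) == 4 * 20 * 2
        assert len(pay) == 4
        assert (pay["participation_eur"] > 0).all()
        assert (pay["payment_eur"] >= 0).all()

    def test_single_participant_single_trial(self):
        cfg = StudyConfig(
            n_probiotics=1, n_placebo=0,
            design=DesignConfig(earlier_dates=(0,), delays=(35,),
                                discount_factors=(0.8,), repeats=1, n_blocks=1,
                                mgt_n_trials=1))
        mcg, mgt, pay = simulate_study(cfg, seed=1)
        assert len(mcg) == 2 and len(mgt) == 2 and len(pay) == 1

    def test_seed_determinism_end_to_end(self, tiny_study_config):
        a = simulate_study(tiny_study_config, seed=77)
        b = simulate_study(tiny_study_config, seed=77)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_house_money_raises_session2_risk_appetite(self):
        cfg = reduced_study_config(payment_risk_slope=0.004)
        mcg, mgt, pay = simulate_study(cfg, seed=3)
        # curvature shifts toward risk neutrality, so more minority-color picks
        from ctblab import score_trials
        scored = score_trials(mgt)
        m = scored.groupby("session")["risk_sd"].mean()
        assert m[2] > m[1]
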