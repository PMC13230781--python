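import numpy as np
import pandas as pd
import pytest

from chickenlearn.models import GO_STRAIGHT, SWERVE, ParamSet, get_model
from chickenlearn.task import (
    HCO,
    LCO,
    CohortSpec,
    PayoffMatrix,
    block_cooperation_rates,
    generate_cohort,
    make_design,
    opponent_schedule,
    payoff,
    sample_opponent_choice,
    simulate_session,
)


class TestDesignPresets:
    def test_study1_has_80_blocked_trials(self, study1):
        assert study1.total_trials == 80
        assert study1.trials_per_opponent == 40
        assert study1.schedule == "blocked_counterbalanced"

    def test_study2_has_100_interleaved_trials(self, study2):
        assert study2.total_trials == 100
        assert study2.trials_per_opponent == 50
        assert study2.schedule == "interleaved_random"

    def test_study1_matrix_ordering_and_values(self, study1):
        m = study1.payoff
        assert (m.gs, m.ss, m.sg, m.gg) == (3, 1, 1, 0)
        assert m.gs > m.ss == m.sg > m.gg

    def test_study2_matrix_ordering_and_crash_cost(self, study2):
        m = study2.payoff
        assert m.gs > m.ss > m.sg > m.gg
        assert m.gg == -30

    def test_unknown_study_rejected(self):
        with pytest.raises(ValueError, match="unknown study"):
            make_design("study3")


class TestSchedules:
    def test_blocked_counterbalance(self, study1):
        sched = opponent_schedule(study1, hco_first=True)
        assert sched[:40] == ["HCO"] * 40 and sched[40:] == ["LCO"] * 40
        sched = opponent_schedule(study1, hco_first=False)
        assert sched[:40] == ["LCO"] * 40

    def test_interleaved_counts_and_determinism(self, study2):
        a = opponent_schedule(study2, seed=5)
        b = opponent_schedule(study2, seed=5)
        assert a == b
        assert a.count("HCO") == 50 and a.count("LCO") == 50
        assert a != opponent_schedule(study2, seed=6)

    def test_interleaving_is_exchangeable_across_seeds(self, study2):
        # each trial position should be HCO in about half of the schedules
        hco = np.array(
            [
                [lab == "HCO" for lab in opponent_schedule(study2, seed=s)]
                for s in range(200)
            ],
            dtype=float,
        )
        frac = hco.mean(axis=0)
        assert np.all(frac > 0.35) and np.all(frac < 0.65)


class TestOpponentsAndPayoffs:
    def test_degenerate_policy_always_goes_straight(self):
        from chickenlearn.task import OpponentPolicy

        rng = np.random.default_rng(0)
        pol = OpponentPolicy("X", 1.0)
        assert all(sample_opponent_choice(pol, rng) == GO_STRAIGHT for _ in range(50))

    @pytest.mark.parametrize("policy,expected", [(HCO, 0.70), (LCO, 0.30)])
    def test_go_straight_frequency_matches_policy(self, policy, expected):
        rng = np.random.default_rng(1234)
        draws = np.array([sample_opponent_choice(policy, rng) for _ in range(10_000)])
        freq = np.mean(draws == GO_STRAIGHT)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(freq - expected) < 3 * se

    def test_payoff_lookup(self, study1, study2):
        assert payoff(study1.payoff, GO_STRAIGHT, SWERVE) == 3
        assert payoff(study1.payoff, GO_STRAIGHT, GO_STRAIGHT) == 0
        assert payoff(study1.payoff, SWERVE, GO_STRAIGHT) == 1
        assert payoff(study2.payoff, GO_STRAIGHT, GO_STRAIGHT) == -30


class TestSimulateSession:
    def test_deterministic_given_seed(self, study2):
        model = get_model("M2-3")
        params = ParamSet(alpha_h=0.3, alpha_l=0.2, beta=1.5, theta=0.1)
        s1 = simulate_session(model, params, study2, seed=9)
        s2 = simulate_session(model, params, study2, seed=9)
        assert s1.trials == s2.trials

    def test_rewards_reproducible_from_choices(self, study2):
        model = get_model("M1-2")
        params = ParamSet(alpha_h=0.4, alpha_l=0.3, beta=2.0)
        s = simulate_session(model, params, study2, seed=3)
        for t in s.trials:
            assert t.reward == study2.payoff.payoff(t.choice, t.opponent_choice)

    def test_nonlearning_agent_chooses_at_chance(self, study1):
        # M0 has P(Swerve) = 0.5 on every trial regardless of history
        model = get_model("M0")
        rates = [
            np.mean([t.choice for t in simulate_session(model, ParamSet(beta=5.0), study1, seed=s).trials])
            for s in range(40)
        ]
        assert abs(np.mean(rates) - 0.5) < 0.03

    def test_full_learning_agent_tracks_deterministic_opponent(self, study1):
        # alpha = 1 copies the opponent's last action into the belief
        model = get_model("M2-2")
        params = ParamSet(alpha_h=1.0, alpha_l=1.0, beta=2.0)
        always_swerve = [SWERVE] * study1.total_trials
        s = simulate_session(
            model, params, study1, seed=4, opponent_choices=always_swerve
        )
        # replay the belief: after trial 1 of each opponent, p = 1
        from chickenlearn.models import belief_update, init_state, opponent_index

        state = init_state(model)
        for t in s.trials[:2]:
            belief_update(state, t.opponent, t.opponent_choice, 1.0)
        assert state.p[opponent_index(s.trials[0].opponent)] == 1.0


class TestCohorts:
    def test_zero_sd_gives_identical_subjects(self, study1):
        spec = CohortSpec.from_natural_means(
            4, study1, get_model("M1-1"), {"alpha": 0.3, "beta": 2.0},
            raw_sds={"alpha": 0.0, "beta": 0.0}, seed=0,
        )
        _, truth = generate_cohort(spec)
        assert truth["alpha"].nunique() == 1 and truth["beta"].nunique() == 1

    def test_cohort_shape_and_bounds(self, study1):
        spec = CohortSpec.from_natural_means(
            52, study1, get_model("M1-3"),
            {"alpha_h": 0.32, "alpha_l": 0.20, "beta": 0.37, "theta": 0.09},
            seed=2,
        )
        sessions, truth = generate_cohort(spec)
        assert len(sessions) == 52
        assert all(len(s) == 80 for s in sessions)
        assert truth["alpha_h"].between(0, 1).all()
        assert truth["alpha_l"].between(0, 1).all()
        assert truth["beta"].between(0, 10).all()

    def test_counterbalancing_alternates(self, study1):
        spec = CohortSpec.from_natural_means(
            4, study1, get_model("M0"), {"beta": 1.0}, seed=3
        )
        sessions, _ = generate_cohort(spec)
        firsts = [s.trials[0].opponent for s in sessions]
        assert firsts == ["HCO", "LCO", "HCO", "LCO"]

    def test_seed_determinism(self, study2):
        spec = CohortSpec.from_natural_means(
            3, study2, get_model("M2-1"), {"alpha": 0.2, "beta": 1.0}, seed=11
        )
        s1, t1 = generate_cohort(spec)
        s2, t2 = generate_cohort(spec)
        assert t1.equals(t2)
        assert all(a.trials == b.trials for a, b in zip(s1, s2))


class TestCooperationRates:
    def test_all_swerve_rates_are_one(self, study1):
        spec = CohortSpec.from_natural_means(
            2, study1, get_model("M4-1"), {"beta": 1.0, "theta": 30.0},
            raw_sds={"beta": 0.0, "theta": 0.0}, seed=0,
        )
        sessions, _ = generate_cohort(spec)
        rates = block_cooperation_rates(sessions)
        assert (rates.dropna()["swerve_rate"] == 1.0).all()

    def test_rate_is_direct_proportion(self, study1):
        model = get_model("M0")
        s = simulate_session(model, ParamSet(beta=1.0), study1, seed=5)
        rates = block_cooperation_rates([s]).dropna()
        row = rates.iloc[0]
        manual = np.mean(
            [
                t.choice
                for t in s.trials
                if t.opponent == row["opponent"] and t.block == row["block"]
            ]
        )
        assert row["swerve_rate"] == pytest.approx(manual)

    def test_blocked_design_emits_missing_combinations(self, study1):
        model = get_model("M0")
        s = simulate_session(model, ParamSet(beta=1.0), study1, seed=6, hco_first=True)
        rates = block_cooperation_rates([s])
        lco_early = rates[(rates.opponent == "LCO") & (rates.block <= 4)]
        assert lco_early["swerve_rate"].isna().all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            block_cooperation_rates([])
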