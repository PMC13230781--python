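import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chickenlearn.models import (
    GO_STRAIGHT,
    MODEL_BANK,
    SWERVE,
    LearnerState,
    ParamSet,
    belief2_update,
    belief_ev_coeffs,
    belief_update,
    choice_prob,
    expected_value,
    get_model,
    init_state,
    reward_update,
    second_order_q,
    session_loglik,
)
from chickenlearn.task import STUDY1_PAYOFF, STUDY2_PAYOFF, simulate_session


class TestBank:
    def test_bank_enumerates_twelve_models(self):
        assert len(MODEL_BANK) == 12
        param_counts = {name: len(m.free_params) for name, m in MODEL_BANK.items()}
        assert param_counts == {
            "M0": 1, "M1-1": 2, "M1-2": 3, "M1-3": 4,
            "M2-1": 2, "M2-2": 3, "M2-3": 4,
            "M3-1": 3, "M3-2": 4, "M3-3": 5,
            "M4-1": 2, "M4-2": 2,
        }

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError, match="outside declared range"):
            ParamSet(alpha=1.5, beta=1.0).validate(get_model("M1-1"))
        with pytest.raises(ValueError, match="requires parameter"):
            ParamSet(beta=1.0).validate(get_model("M1-1"))


class TestUpdates:
    def test_reward_update_moves_chosen_value_only(self):
        state = init_state(get_model("M1-1"))
        reward_update(state, "HCO", SWERVE, reward=1.0, alpha=0.5)
        assert state.v[0, SWERVE] == 0.5
        assert state.v[0, GO_STRAIGHT] == 0.0
        assert np.all(state.v[1] == 0.0)  # other opponent untouched

    def test_reward_update_fixed_points(self):
        state = init_state(get_model("M1-1"))
        reward_update(state, "LCO", GO_STRAIGHT, reward=2.0, alpha=0.0)
        assert np.all(state.v == 0.0)
        state.v[1, GO_STRAIGHT] = 2.0
        reward_update(state, "LCO", GO_STRAIGHT, reward=2.0, alpha=0.7)
        assert state.v[1, GO_STRAIGHT] == 2.0  # zero prediction error

    def test_belief_update_hand_value(self):
        state = init_state(get_model("M2-1"))
        belief_update(state, "HCO", 1, alpha=0.2)
        assert state.p[0] == pytest.approx(0.6)
        belief_update(state, "LCO", 0, alpha=1.0)
        assert state.p[1] == 0.0  # full update copies the observation

    def test_belief2_update_hand_value(self):
        # p=0.5, O=1, Q=1, alpha=0.2, kappa=0.1: q=1/3, p' = 0.6 + 0.1*(2/3)
        state = init_state(get_model("M3-3"))
        belief2_update(state, "HCO", 1, 1, alpha=0.2, kappa=0.1, beta=2.0,
                       matrix=STUDY1_PAYOFF)
        assert state.p[0] == pytest.approx(0.6 + 0.1 * (1 - 1 / 3))

    def test_belief2_with_zero_kappa_equals_plain_belief(self):
        s1 = init_state(get_model("M3-1"))
        s2 = init_state(get_model("M2-1"))
        for o_t in [1, 0, 0, 1]:
            belief2_update(s1, "LCO", o_t, 1, alpha=0.3, kappa=0.0, beta=1.0,
                           matrix=STUDY1_PAYOFF)
            belief_update(s2, "LCO", o_t, alpha=0.3)
        assert s1.p[1] == pytest.approx(s2.p[1])

    @given(
        p=st.floats(0.0, 1.0),
        o_t=st.integers(0, 1),
        q_t=st.integers(0, 1),
        alpha=st.floats(0.0, 1.0),
        kappa=st.floats(0.0, 1.0),
        beta=st.floats(0.05, 10.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_belief2_keeps_belief_interior(self, p, o_t, q_t, alpha, kappa, beta):
        state = LearnerState()
        state.p[0] = p
        belief2_update(state, "HCO", o_t, q_t, alpha, kappa, beta, STUDY2_PAYOFF)
        assert 0.0 < state.p[0] < 1.0


class TestSecondOrderInference:
    def test_neutral_belief_maps_to_one_third(self):
        for beta in [0.1, 0.5, 2.0, 9.0]:
            assert second_order_q(0.5, beta, STUDY1_PAYOFF) == pytest.approx(1 / 3)

    def test_generic_inversion_matches_closed_form_on_grid(self):
        # q = 1/3 + log((1-p)/p) / (3*beta) under the simplified matrix
        grid = np.linspace(0.01, 0.99, 197)
        for beta in [0.3, 1.0, 4.0]:
            for p in grid:
                closed = 1 / 3 + math.log((1 - p) / p) / (3 * beta)
                assert second_order_q(p, beta, STUDY1_PAYOFF) == pytest.approx(
                    closed, abs=1e-12
                )

    def test_round_trip_through_softmax(self):
        A, B = belief_ev_coeffs(STUDY2_PAYOFF)
        for beta in [0.5, 2.0]:
            for p in np.linspace(0.05, 0.95, 19):
                q = second_order_q(p, beta, STUDY2_PAYOFF)
                back = 1 / (1 + math.exp(-beta * (A + B * q)))
                assert back == pytest.approx(p, abs=1e-10)

    def test_degenerate_matrix_rejected(self):
        from chickenlearn.task import PayoffMatrix

        flat = PayoffMatrix(ss=1, sg=1, gs=1, gg=1)
        with pytest.raises(ValueError, match="degenerate"):
            second_order_q(0.4, 1.0, flat)


class TestExpectedValueAndChoice:
    def test_belief_ev_reduces_to_study1_closed_form(self):
        model = get_model("M2-1")
        state = init_state(model)
        for p in np.linspace(0.0, 1.0, 101):
            state.p[0] = p
            ev = expected_value(model, state, STUDY1_PAYOFF, "HCO")
            assert abs(ev - (1 - 3 * p)) < 1e-12

    def test_belief_ev_matches_symbolic_expansion(self):
        # V_swerve - V_go expanded from the matrix entries directly
        model = get_model("M2-2")
        state = init_state(model)
        m = STUDY2_PAYOFF
        for p in np.linspace(0.0, 1.0, 41):
            state.p[1] = p
            ev = expected_value(model, state, m, "LCO")
            direct = (p * m.ss + (1 - p) * m.sg) - (p * m.gs + (1 - p) * m.gg)
            assert ev == pytest.approx(direct, abs=1e-12)

    def test_choice_prob_values(self):
        m = get_model("M1-1")
        assert choice_prob(m, 0.0, beta=3.0) == 0.5
        assert choice_prob(m, 1.0, beta=1.0) == pytest.approx(0.73106, abs=1e-5)
        mt = get_model("M1-3")
        assert choice_prob(mt, 0.0, beta=1.0, theta=50.0) == pytest.approx(1.0)

    def test_initial_state_gives_chance_probability(self):
        for name in ["M0", "M1-1", "M1-2"]:
            model = get_model(name)
            state = init_state(model)
            ev = expected_value(model, state, STUDY1_PAYOFF, "HCO")
            assert choice_prob(model, ev, beta=4.0) == 0.5


class TestSessionLoglik:
    def test_nonlearning_model_is_coinflip(self, study1):
        model = get_model("M0")
        s = simulate_session(model, ParamSet(beta=3.0), study1, seed=0)
        total, pointwise = session_loglik(model, ParamSet(beta=3.0), s)
        assert total == pytest.approx(80 * math.log(0.5))
        assert np.allclose(pointwise, math.log(0.5))

    @pytest.mark.parametrize(
        "full,reduced,tie",
        [
            ("M1-2", "M1-1", {"alpha_h": 0.3, "alpha_l": 0.3, "beta": 2.0}),
            ("M2-2", "M2-1", {"alpha_h": 0.4, "alpha_l": 0.4, "beta": 1.0}),
            ("M1-3", "M1-2", {"alpha_h": 0.3, "alpha_l": 0.1, "beta": 2.0, "theta": 0.0}),
            ("M3-3", "M3-2", {"alpha_h": 0.3, "alpha_l": 0.1, "beta": 2.0,
                              "kappa": 0.2, "theta": 0.0}),
        ],
    )
    def test_nested_models_agree_at_shared_points(self, study2, full, reduced, tie):
        """A richer model at its nesting point reproduces the reduced model."""
        gen = get_model("M2-3")
        s = simulate_session(
            gen, ParamSet(alpha_h=0.3, alpha_l=0.2, beta=1.5, theta=0.2), study2, seed=21
        )
        full_m, red_m = get_model(full), get_model(reduced)
        full_ll, _ = session_loglik(full_m, ParamSet.from_dict(tie), s)
        red_vals = {
            k: v for k, v in tie.items() if k in red_m.free_params
        }
        if red_m.n_alphas == 1:
            red_vals["alpha"] = tie["alpha_h"]
        red_ll, _ = session_loglik(red_m, ParamSet.from_dict(red_vals), s)
        assert full_ll == pytest.approx(red_ll, abs=1e-10)

    @pytest.mark.parametrize("name,alpha0", [("M4-1", "M1-3"), ("M4-2", "M2-3")])
    def test_preference_baselines_equal_zero_learning(self, study1, name, alpha0):
        gen = get_model("M1-1")
        s = simulate_session(gen, ParamSet(alpha=0.3, beta=2.0), study1, seed=13)
        base_ll, _ = session_loglik(
            get_model(name), ParamSet(beta=1.5, theta=0.4), s
        )
        learn_ll, _ = session_loglik(
            get_model(alpha0),
            ParamSet(alpha_h=0.0, alpha_l=0.0, beta=1.5, theta=0.4),
            s,
        )
        assert base_ll == pytest.approx(learn_ll, abs=1e-12)

    def test_opponent_states_are_independent_of_interleaving(self, study2):
        """Permuting trials across opponents while preserving each opponent's
        own subsequence leaves the likelihood contributions unchanged."""
        model = get_model("M2-2")
        params = ParamSet(alpha_h=0.5, alpha_l=0.3, beta=2.0)
        s = simulate_session(model, params, study2, seed=8)
        _, pointwise = session_loglik(model, params, s)
        # move all HCO trials first, preserving within-opponent order
        order = [i for i, t in enumerate(s.trials) if t.opponent == "HCO"]
        order += [i for i, t in enumerate(s.trials) if t.opponent == "LCO"]
        from chickenlearn.task import Session, TrialRecord

        reordered = Session(
            s.subject_id,
            s.group,
            s.design,
            [
                TrialRecord(
                    t.subject_id, j + 1, t.block, t.opponent, t.choice,
                    t.opponent_choice, t.reward,
                )
                for j, t in enumerate(s.trials[i] for i in order)
            ],
        )
        _, pw2 = session_loglik(model, params, reordered)
        assert np.allclose(np.sort(pointwise), np.sort(pw2))
        assert np.allclose(pointwise[order], pw2)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_loglik_is_finite_and_negative(self, study2, seed):
        rng = np.random.default_rng(seed)
        name = list(MODEL_BANK)[seed % 12]
        from conftest import random_paramset

        params = random_paramset(name, rng)
        model = get_model(name)
        s = simulate_session(model, params, study2, seed=seed)
        total, pointwise = session_loglik(model, params, s)
        assert np.isfinite(total)
        assert np.all(pointwise < 0)
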