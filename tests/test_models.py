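"""RL model semantics: choice rule, value updates, sequence likelihoods."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prlkit as pk
from prlkit.models import (AgentParams, LatentState, ModelId, choice_logits,
                           choice_probs, sequence_loglik,
                           sequence_loglik_naive, update_state,
                           update_values_ewa, update_values_rp)

M2 = ModelId.M2_rp_stick


class TestChoiceRule:
    def test_symmetric_start_is_uniform(self):
        p = choice_probs(LatentState(), AgentParams(model=M2, tau_reinf=3.0))
        assert np.allclose(p, [0.5, 0.5])

    def test_value_difference_softmax(self):
        params = AgentParams(model=M2, tau_reinf=1.0, tau_stick=0.0)
        p = choice_probs(LatentState(values=(1.0, 0.0)), params)
        assert p[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-12)

    def test_pure_stickiness(self):
        params = AgentParams(model=M2, tau_reinf=0.0, tau_stick=5.0)
        p = choice_probs(LatentState(values=(0.3, -0.2), last_choice=0), params)
        assert p[0] == pytest.approx(1 / (1 + math.exp(-5)), abs=1e-12)

    def test_m1_has_no_stickiness_term(self):
        params = AgentParams(model=ModelId.M1_rp, tau_reinf=2.0, tau_stick=9.9)
        logits = choice_logits(LatentState(values=(0.5, -0.5), last_choice=0), params)
        assert logits[0] == pytest.approx(1.0)

    @given(st.floats(-3, 3), st.floats(-3, 3), st.floats(0, 10), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_probabilities_sum_to_one(self, v0, v1, tau, stick):
        params = AgentParams(model=M2, tau_reinf=tau, tau_stick=stick)
        p = choice_probs(LatentState(values=(v0, v1), last_choice=1), params)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()

    @given(st.floats(-2, 2), st.floats(-2, 2))
    @settings(max_examples=30, deadline=None)
    def test_more_stickiness_never_reduces_repeat_probability(self, s1, s2):
        lo, hi = sorted([s1, s2])
        state = LatentState(values=(0.2, -0.4), last_choice=1)
        p_lo = choice_probs(state, AgentParams(model=M2, tau_reinf=2.0, tau_stick=lo))
        p_hi = choice_probs(state, AgentParams(model=M2, tau_reinf=2.0, tau_stick=hi))
        assert p_hi[1] >= p_lo[1] - 1e-12


class TestValueUpdates:
    def test_reward_update_arithmetic(self):
        params = AgentParams(model=M2, alpha_rew=0.5, alpha_pun=0.1)
        s = update_values_rp(LatentState(), 0, +1, params)
        assert s.values[0] == pytest.approx(0.5)
        assert s.values[1] == 0.0
        assert s.last_choice == 0

    @pytest.mark.parametrize("alpha,expected", [(1e-9, 0.0), (1 - 1e-9, -1.0)])
    def test_learning_rate_limits(self, alpha, expected):
        params = AgentParams(model=M2, alpha_rew=0.3, alpha_pun=alpha)
        s = update_values_rp(LatentState(), 1, -1, params)
        assert s.values[1] == pytest.approx(expected, abs=1e-6)

    def test_punishment_uses_punishment_rate(self):
        params = AgentParams(model=M2, alpha_rew=0.9, alpha_pun=0.2)
        s = update_values_rp(LatentState(), 0, -1, params)
        assert s.values[0] == pytest.approx(-0.2)

    def test_single_rate_model_ignores_valence(self):
        params = AgentParams(model=ModelId.M3_single_stick, alpha_reinf=0.3)
        up = update_values_rp(LatentState(), 0, +1, params).values[0]
        down = update_values_rp(LatentState(), 0, -1, params).values[0]
        assert up == pytest.approx(0.3) and down == pytest.approx(-0.3)

    def test_invalid_outcome_rejected(self):
        with pytest.raises(ValueError, match="outcome"):
            update_values_rp(LatentState(), 0, 0, AgentParams(model=M2))

    def test_ewa_first_update(self):
        # phi=rho=1, V=0, n=1, reward: n'=2, V'(choice)=1/2
        params = AgentParams(model=ModelId.M4_ewa, ewa_phi=1 - 1e-12,
                             ewa_rho=1 - 1e-12, tau_reinf=1.0)
        s = update_values_ewa(LatentState(), 0, +1, params)
        assert s.ewa_n == pytest.approx(2.0)
        assert s.values[0] == pytest.approx(0.5)
        assert s.values[1] == pytest.approx(0.0)

    def test_ewa_no_experience_accumulation(self):
        # rho=0: n stays 1; update collapses to V' = phi*V + outcome
        params = AgentParams(model=ModelId.M4_ewa, ewa_phi=0.7, ewa_rho=1e-12)
        s = LatentState(values=(0.4, -0.1), ewa_n=1.0)
        s2 = update_values_ewa(s, 0, +1, params)
        assert s2.ewa_n == pytest.approx(1.0)
        assert s2.values[0] == pytest.approx(0.7 * 0.4 + 1.0)

    def test_ewa_full_payoff_decay_erases_history(self):
        params = AgentParams(model=ModelId.M4_ewa, ewa_phi=1e-12, ewa_rho=0.5)
        s = LatentState(values=(0.9, 0.9), ewa_n=2.0)
        s2 = update_values_ewa(s, 1, -1, params)
        assert s2.values[1] == pytest.approx(-1.0 / (0.5 * 2 + 1))
        assert s2.values[0] == pytest.approx(0.0, abs=1e-10)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_values_bounded_for_rp_models(self, seed):
        rng = np.random.default_rng(seed)
        params = AgentParams(model=M2, alpha_rew=rng.uniform(.01, .99),
                             alpha_pun=rng.uniform(.01, .99))
        s = LatentState()
        for _ in range(100):
            s = update_state(s, int(rng.integers(2)),
                             float(rng.choice([1, -1])), params)
        assert all(-1.0 <= v <= 1.0 for v in s.values)


class TestSequenceLoglik:
    def test_first_trial_is_coin_flip(self, random_trials):
        df = random_trials(n_trials=1, seed=3)
        params = AgentParams(model=M2, tau_reinf=7.0, tau_stick=2.0)
        assert sequence_loglik(df, params) == pytest.approx(math.log(0.5))

    @pytest.mark.parametrize("model", list(ModelId))
    def test_kernel_matches_stepwise_rederivation(self, model, random_trials):
        params = AgentParams(model=model, alpha_rew=0.35, alpha_pun=0.15,
                             alpha_reinf=0.25, tau_reinf=2.5, tau_stick=-0.7,
                             ewa_phi=0.8, ewa_rho=0.3)
        for seed in range(5):
            df = random_trials(n_trials=50, seed=seed)
            assert sequence_loglik(df, params) == pytest.approx(
                sequence_loglik_naive(df, params), abs=1e-10)

    def test_m2_with_equal_rates_equals_m3(self, random_trials):
        df = random_trials(n_trials=80, seed=11)
        m2 = AgentParams(model=M2, alpha_rew=0.3, alpha_pun=0.3,
                         tau_reinf=4.0, tau_stick=1.2)
        m3 = AgentParams(model=ModelId.M3_single_stick, alpha_reinf=0.3,
                         tau_reinf=4.0, tau_stick=1.2)
        assert sequence_loglik(df, m2) == pytest.approx(
            sequence_loglik(df, m3), abs=1e-14)

    def test_unsorted_input_rejected(self, random_trials):
        df = random_trials(n_trials=10).iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            sequence_loglik(df, AgentParams(model=M2))

    def test_state_carries_across_sessions(self, random_trials):
        # two sessions concatenated != two independent sequences
        df = random_trials(n_trials=40, seed=2)
        df2 = df.copy()
        df2.loc[20:, "session"] = 1
        df2.loc[20:, "trial"] = np.arange(20)
        params = AgentParams(model=M2, alpha_rew=0.4, alpha_pun=0.2,
                             tau_reinf=3.0, tau_stick=0.5)
        joint = sequence_loglik(df2, params)
        split = (sequence_loglik(df.iloc[:20], params)
                 + sequence_loglik(df.iloc[20:].assign(trial=np.arange(20)), params))
        assert joint == pytest.approx(sequence_loglik(df, params), abs=1e-12)
        assert joint != pytest.approx(split, abs=1e-6)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            AgentParams(model=M2, alpha_rew=1.5)
        with pytest.raises(ValueError):
            AgentParams(model=M2, tau_reinf=-1.0)
        # negative stickiness is legal (anti-perseveration)
        AgentParams(model=M2, tau_stick=-2.0)
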