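"""Hybrid MF/MB model: values, choice probabilities, updates, likelihood."""

import itertools
import math

import numpy as np
import pytest

from twostep.hybrid import (
    ModelParams,
    QState,
    TrialRecord,
    apply_updates,
    mb_stage1_values,
    session_loglik,
    simulate_agent,
    stage1_probs,
    stage2_probs,
    trials_from_frame,
    trials_to_frame,
)
from twostep.task import TransitionStructure

from conftest import random_params


def make_params(**kw) -> ModelParams:
    base = dict(beta1=1.0, beta2=1.0, alpha1=0.5, alpha2=0.5, lam=0.5,
                persev=0.0, w=0.5)
    base.update(kw)
    return ModelParams(**base)


class TestModelBasedValues:
    def test_zero_q2_gives_zero(self, structure):
        assert np.allclose(mb_stage1_values(np.zeros((2, 2)), structure), 0.0)

    def test_direct_arithmetic(self, structure):
        q2 = np.array([[1.0, 0.0], [0.0, 0.0]])
        vals = mb_stage1_values(q2, structure)
        # action 0's common state is B where the best option is worth 1
        assert vals[0] == pytest.approx(0.7 * 1 + 0.3 * 0)
        assert vals[1] == pytest.approx(0.3 * 1 + 0.7 * 0)

    def test_symmetric_structure_equalizes_actions(self):
        # a 0.5/0.5 structure carries no action information
        s = TransitionStructure(common_prob=0.5)
        rng = np.random.default_rng(0)
        q2 = rng.normal(size=(2, 2))
        vals = mb_stage1_values(q2, s)
        assert vals[0] == pytest.approx(vals[1])


class TestChoiceProbabilities:
    def test_symmetric_values_give_half(self):
        p = stage1_probs(make_params(), np.zeros(2), np.zeros(2), None)
        assert np.allclose(p, 0.5)

    def test_zero_beta_ignores_values(self):
        p = stage1_probs(make_params(beta1=0.0), np.array([10.0, -3.0]),
                         np.array([5.0, 0.0]), None)
        assert np.allclose(p, 0.5)

    def test_unit_value_gap_is_logistic(self):
        # net value difference of 1 at beta1 = 1 -> 1/(1+e^-1)
        p = stage1_probs(make_params(beta1=1.0, w=0.0),
                         np.array([1.0, 0.0]), np.zeros(2), None)
        assert p[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-9)

    def test_stage2_logistic_evaluation(self):
        q2 = np.array([[0.5, 0.0], [0.0, 0.0]])
        p = stage2_probs(make_params(beta2=2.0), q2, 0)
        assert p[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-9)

    def test_stage2_limit_is_deterministic(self):
        q2 = np.array([[0.8, 0.2], [0.0, 0.0]])
        p = stage2_probs(make_params(beta2=500.0), q2, 0)
        assert p[0] > 0.999999

    def test_stage2_invalid_state(self):
        with pytest.raises(ValueError, match="state2"):
            stage2_probs(make_params(), np.zeros((2, 2)), 2)

    def test_probabilities_sum_to_one_over_random_params(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            params = random_params(rng)
            q_mf, q_mb = rng.normal(size=2), rng.normal(size=2)
            p1 = stage1_probs(params, q_mf, q_mb, int(rng.integers(2)))
            p2 = stage2_probs(params, rng.normal(size=(2, 2)), 0)
            for p in (p1, p2):
                assert np.all(p > 0) and np.all(p < 1)
                assert p.sum() == pytest.approx(1.0)

    def test_perseveration_dominates_at_large_rate(self):
        p = stage1_probs(make_params(persev=50.0), np.zeros(2), np.zeros(2), 1)
        assert p[1] > 0.999999


class TestUpdates:
    def test_zero_learning_rate_freezes_values(self):
        q = QState.initial()
        q.q_mf[:] = [0.2, 0.4]
        trial = TrialRecord(0, 0, 1, 1, True)
        new, trace = apply_updates(make_params(alpha1=0.0, alpha2=0.0), q, trial)
        assert np.allclose(new.q_mf, q.q_mf) and np.allclose(new.q2, q.q2)
        assert trace.delta2 == 1.0  # errors still computed

    def test_hand_traced_full_learning(self):
        # alpha1 = alpha2 = lam = 1 from an all-zero state with reward
        q = QState.initial()
        trial = TrialRecord(choice1=0, state2=1, choice2=1, reward=1, common=False)
        new, trace = apply_updates(
            make_params(alpha1=1.0, alpha2=1.0, lam=1.0), q, trial
        )
        assert trace.delta1 == 0.0
        assert trace.delta2 == 1.0
        assert new.q2[1, 1] == 1.0
        assert new.q_mf[0] == 1.0
        # untouched entries stay zero
        assert new.q2[0, 0] == new.q2[0, 1] == new.q2[1, 0] == 0.0
        assert new.q_mf[1] == 0.0

    def test_invalid_trial_is_a_no_op(self):
        q = QState.initial()
        q.q_mf[:] = [0.3, 0.1]
        invalid = TrialRecord(-1, -1, -1, -1, False, valid=False)
        new, trace = apply_updates(make_params(), q, invalid)
        assert np.allclose(new.q_mf, q.q_mf)
        assert trace.empty


class TestSessionLoglik:
    def test_uniform_model_single_trial(self, structure):
        trial = TrialRecord(0, 0, 0, 1, True)
        ll = session_loglik(make_params(beta1=0.0, beta2=0.0), [trial], structure)
        assert ll == pytest.approx(2 * math.log(0.5), abs=1e-9)

    def test_empty_session_is_zero(self, structure):
        assert session_loglik(make_params(), [], structure) == 0.0
        invalid = TrialRecord(-1, -1, -1, -1, False, valid=False)
        assert session_loglik(make_params(), [invalid], structure) == 0.0

    def test_nonfinite_params_rejected(self, structure):
        with pytest.raises(ValueError):
            ModelParams(beta1=math.nan, beta2=1, alpha1=.5, alpha2=.5,
                        lam=.5, persev=0, w=.5)

    @pytest.mark.parametrize("n_trials", [1, 2])
    def test_likelihood_conservation_by_enumeration(self, structure, n_trials):
        """exp(loglik) summed over every choice sequence equals 1 for any
        fixed state/reward path (chain-rule conservation)."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            params = random_params(rng)
            states = rng.integers(2, size=n_trials)
            rewards = rng.integers(2, size=n_trials)
            total = 0.0
            for choices in itertools.product([0, 1], repeat=2 * n_trials):
                trials = [
                    TrialRecord(choices[2 * t], int(states[t]),
                                choices[2 * t + 1], int(rewards[t]),
                                common=bool(choices[2 * t] == states[t]))
                    for t in range(n_trials)
                ]
                total += math.exp(session_loglik(params, trials, structure))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_perseveration_keyed_to_last_valid_choice(self, structure):
        params = make_params(persev=50.0)
        trials = [
            TrialRecord(1, 1, 0, 0, True),
            TrialRecord(-1, -1, -1, -1, False, valid=False),
            TrialRecord(1, 1, 0, 0, True),  # repeats last *valid* choice
        ]
        ll_repeat = session_loglik(params, trials, structure)
        trials_switch = trials[:2] + [TrialRecord(0, 0, 0, 0, True)]
        ll_switch = session_loglik(params, trials_switch, structure)
        assert ll_repeat > ll_switch


class TestSimulation:
    def test_seed_reproducibility(self, default_params, session_env):
        a = simulate_agent(default_params, session_env, seed=1)
        b = simulate_agent(default_params, session_env, seed=1)
        assert a == b

    def test_transition_labels_consistent(self, default_params, session_env):
        for tr in simulate_agent(default_params, session_env, seed=2):
            assert tr.common == session_env.structure.is_common(tr.choice1, tr.state2)

    def test_miss_rate_marks_invalid_trials(self, default_params, session_env):
        trials = simulate_agent(default_params, session_env, seed=3, miss_rate=0.2)
        n_invalid = sum(not t.valid for t in trials)
        assert 0 < n_invalid < len(trials)


class TestTrialTableRoundTrip:
    def test_frame_round_trip(self, simulated_trials):
        df = trials_to_frame(simulated_trials, subject="S01", condition="control",
                             session_order=1)
        back = trials_from_frame(df)
        assert len(back) == len(simulated_trials)
        for a, b in zip(back, simulated_trials):
            for f in ("choice1", "state2", "choice2", "reward", "common", "valid"):
                assert getattr(a, f) == getattr(b, f)
            assert (a.rt2_ms == b.rt2_ms) or (
                math.isnan(a.rt2_ms) and math.isnan(b.rt2_ms)
            )

    def test_bad_state_label_rejected(self, simulated_trials):
        df = trials_to_frame(simulated_trials)
        df.loc[0, "state2"] = "Z"
        with pytest.raises(ValueError, match="state"):
            trials_from_frame(df)
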