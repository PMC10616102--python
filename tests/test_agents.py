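import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trustgame import agents
from trustgame.agents import (BETA_GRID, OMEGA_GRID,
                              AgentParams, BeliefState, IrritationState,
                              TrustAgent, action_values, choice_probabilities,
                              expected_partner_value, investor_utility,
                              trustee_utility, update_inequality_belief,
                              update_irritation)
from trustgame.game import INVESTOR_ACTIONS, trustee_actions_coins
from trustgame.cohort import simulate_game


def inv(alpha=0.0, omega=1.0, tom=0, plan=1, zeta=0.0, q=0, beta=1.0):
    return AgentParams("investor", alpha, omega, tom, plan, zeta, q, beta)


def tru(alpha=0.0, tom=0, plan=1, zeta=0.0, q=0, beta=1.0):
    return AgentParams("trustee", alpha, 1.0, tom, plan, zeta, q, beta)


# ----------------------------------------------------------------- utilities

@pytest.mark.parametrize("params,a_I,a_T,expected", [
    (inv(alpha=0.0, omega=1.0), 10, 15.0, 25.0),
    (inv(alpha=0.0, omega=1.8), 0, 0.0, 36.0),
    (inv(alpha=1.0, omega=0.4), 20, 40.0, 20.0),
])
def test_investor_utility(params, a_I, a_T, expected):
    assert investor_utility(params, a_I, a_T) == pytest.approx(expected)


@pytest.mark.parametrize("alpha,a_I,a_T,expected", [
    (1.0, 20, 30.0, 30.0),
    (1.0, 20, 0.0, 0.0),
    (0.0, 10, 5.0, 25.0),
])
def test_trustee_utility(alpha, a_I, a_T, expected):
    assert trustee_utility(tru(alpha=alpha), a_I, a_T) == pytest.approx(expected)


def test_utility_role_checks():
    with pytest.raises(ValueError):
        investor_utility(tru(), 10, 5.0)
    with pytest.raises(ValueError):
        trustee_utility(inv(), 10, 5.0)


def test_fully_averse_trustee_equalizes_payoffs():
    """For alpha=1 the myopic best repayment minimizes |chi_T - chi_I|."""
    for a_I in (5, 10, 15, 20):
        acts = trustee_actions_coins(a_I)
        utils = [trustee_utility(tru(alpha=1.0), a_I, a) for a in acts]
        best = acts[int(np.argmax(utils))]
        gaps = [abs((3 * a_I - a) - (20 - a_I + a)) for a in acts]
        assert best == acts[int(np.argmin(gaps))]


# ------------------------------------------------------------------- beliefs

def test_belief_update_arithmetic():
    b = BeliefState((1.0, 1.0, 1.0))
    b2 = update_inequality_belief(b, (0.2, 0.5, 0.9))
    assert b2.alpha_counts == (1.2, 1.5, 1.9)
    # total added mass equals the sum of likelihoods
    assert sum(b2.alpha_counts) - sum(b.alpha_counts) == pytest.approx(1.6)


def test_belief_update_equal_likelihoods_keeps_probs():
    b = BeliefState((1.0, 1.0, 1.0))
    b2 = update_inequality_belief(b, (0.4, 0.4, 0.4))
    assert np.allclose(b2.alpha_probs(), b.alpha_probs())


def test_belief_update_gated_at_small_investments():
    b = BeliefState((1.0, 1.0, 1.0))
    assert update_inequality_belief(b, (0.2, 0.5, 0.9), investment=5) is b
    assert update_inequality_belief(b, (0.2, 0.5, 0.9), investment=0) is b
    b2 = update_inequality_belief(b, (0.2, 0.5, 0.9), investment=10)
    assert b2.alpha_counts != b.alpha_counts


def test_belief_update_rejects_bad_likelihood():
    with pytest.raises(ValueError):
        update_inequality_belief(BeliefState(), (0.2, 1.5, 0.9))


def test_belief_counts_monotone_through_game():
    agent = TrustAgent(inv(tom=1, q=2, plan=1))
    prev = np.array(agent.belief().alpha_counts)
    prev_z = np.array(agent.belief().zeta_counts)
    for t, (a_I, a_T) in enumerate([(10, 0.0), (20, 30.0), (5, 2.5),
                                    (0, 0.0), (15, 7.5)]):
        agent.observe_round(a_I, a_T)
        cur = np.array(agent.belief().alpha_counts)
        cur_z = np.array(agent.belief().zeta_counts)
        assert np.all(cur >= prev - 1e-12)
        assert np.all(cur_z >= prev_z - 1e-12)
        assert abs(sum(agent.belief().alpha_probs()) - 1) < 1e-12
        prev, prev_z = cur, cur_z


# ---------------------------------------------------------------- irritation

def test_irritation_additive_and_clamped():
    s = IrritationState(0.0)
    s = update_irritation(s, 0.25, "below")
    assert s.w == 0.25
    for _ in range(5):
        s = update_irritation(s, 0.25, "below")
    assert s.w == 1.0
    assert update_irritation(IrritationState(1.0), 0.5, "above").w == 0.5
    assert update_irritation(IrritationState(0.0), 0.0, "below").w == 0.0
    assert update_irritation(IrritationState(0.3), 0.25, "tie").w == 0.3


def test_expected_partner_value():
    assert expected_partner_value([1.0], [[0.0, 1.0]], [0, 10]) == 10
    assert expected_partner_value([0.5, 0.5], [[1, 0], [0, 1]], [10, 20]) == 15
    assert expected_partner_value([0.2, 0.3, 0.5],
                                  [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
                                  [0, 10, 20]) == pytest.approx(13.0)
    with pytest.raises(ValueError):
        expected_partner_value([], [], [0, 10])


def test_zero_irritability_agent_never_irritated():
    """zeta=0 keeps the mixture weight at zero through unfair rounds."""
    agent = TrustAgent(inv(zeta=0.0, q=2))
    for a_I, a_T in [(20, 0.0), (20, 0.0), (15, 0.0)]:
        agent.observe_round(a_I, a_T)
        assert agent.w == 0.0
    probs = agent.action_probabilities()
    rational = agents.softmax(agent.q_values(), 1.0)
    assert np.allclose(probs, rational)


# ------------------------------------------------------------- choice probs

def test_choice_probabilities_uniform_for_equal_q():
    p = choice_probabilities([3.0] * 5, inv(beta=0.5))
    assert np.allclose(p, 0.2)


def test_choice_probabilities_softmax_closed_form():
    p = choice_probabilities([1.0, 0, 0, 0, 0], inv(beta=1.0))
    assert p[0] == pytest.approx(math.e / (math.e + 4), abs=1e-12)


def test_choice_probabilities_fully_irritated():
    params = inv(omega=1.4, zeta=1.0, beta=1.0)
    p = choice_probabilities([0, 5, 1, 2, 3], params, irritation=1.0)
    irr = agents._irritated_policy("investor", 1.4, 1.0, None)
    assert np.allclose(p, irr)


@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=5, max_size=5),
       st.sampled_from(BETA_GRID),
       st.floats(min_value=0, max_value=1))
def test_choice_probabilities_simplex(qs, beta, w):
    params = inv(omega=1.0, beta=beta)
    p = choice_probabilities(qs, params, irritation=w)
    assert abs(p.sum() - 1) < 1e-12
    assert np.all(p > 0) and np.all(p < 1)


def test_beta_concentrates_on_argmax():
    qs = [1.0, 0.4, 0.2, 0.0, -1.0]
    probs = [choice_probabilities(qs, inv(beta=b))[0] for b in BETA_GRID]
    assert all(b2 >= b1 for b1, b2 in zip(probs, probs[1:]))


# ------------------------------------------------------- planning / recursion

def test_final_round_q_is_immediate_expected_utility(example_pairs):
    """At round 10 there is no future term for any planning horizon."""
    for plan in (1, 4):
        agents.clear_caches()
        params = inv(alpha=0.4, omega=0.8, plan=plan, q=2)
        agent = TrustAgent(params)
        for a_I, a_T in example_pairs[:9]:
            agent.observe_round(a_I, a_T)
        qv = agent.q_values()
        for i, a_I in enumerate(INVESTOR_ACTIONS):
            mix = agent.partner_prediction(a_I)
            acts = np.array(trustee_actions_coins(a_I))
            exp_u = float(mix @ np.array(
                [investor_utility(params, a_I, a) for a in acts]))
            assert qv[i] == pytest.approx(exp_u, abs=1e-9)


def test_risk_averse_myopic_investor_keeps_coins():
    """With omega=1.8 and no partner repaying more than invested on
    average, keeping everything maximizes Q."""
    agents.clear_caches()
    agent = TrustAgent(inv(omega=1.8, plan=1))
    qv = agent.q_values()
    assert np.argmax(qv) == 0


def test_expected_first_investment_nonincreasing_in_omega():
    values = np.array(INVESTOR_ACTIONS, dtype=float)
    exp = []
    for om in OMEGA_GRID:
        agents.clear_caches()
        agent = TrustAgent(inv(omega=om, plan=1))
        exp.append(float(agent.action_probabilities() @ values))
    assert all(b <= a + 1e-9 for a, b in zip(exp, exp[1:]))


def test_action_values_validate_parameters():
    with pytest.raises(ValueError):
        AgentParams("investor", 0.0, 1.0, -1, 1, 0.0, 0, 1.0)
    with pytest.raises(ValueError):
        AgentParams("investor", 0.0, 1.0, 0, 0, 0.0, 0, 1.0)


def test_caching_does_not_change_probabilities(example_traj):
    """Warm-cache evaluations match cold ones to 1e-12."""
    from trustgame.inference import trajectory_nll
    p1 = inv(alpha=0.4, omega=0.6, tom=1, plan=2, zeta=0.5, q=2)
    p2 = inv(alpha=1.0, omega=1.0, tom=1, plan=2, zeta=0.0, q=2)
    agents.clear_caches()
    cold1 = trajectory_nll(p1, example_traj)
    agents.clear_caches()
    cold2 = trajectory_nll(p2, example_traj)
    agents.clear_caches()
    warm2 = trajectory_nll(p2, example_traj)  # shares caches with next call
    warm1 = trajectory_nll(p1, example_traj)
    assert warm1 == pytest.approx(cold1, abs=1e-12)
    assert warm2 == pytest.approx(cold2, abs=1e-12)


def test_simulation_reproducible_and_zero_zeta_consistent():
    params = inv(alpha=0.4, omega=0.6, zeta=0.0, q=2, beta=1.0)
    sched = [0.0, 0.5, 1 / 3, 0.0, 0.5, 1 / 3, 0.5, 0.5, 1 / 6, 0.5]
    t1 = simulate_game(params, sched, 42)
    t2 = simulate_game(params, sched, 42)
    assert t1.action_pairs() == t2.action_pairs()
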