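"""Generative agents for the multi-round trust game.

The subject is modelled as an interactive POMDP agent with a seven
parameter vector ``(alpha, omega, k, P, zeta, q, beta)``:

* ``alpha``  - Fehr-Schmidt style inequality aversion (disutility from
  advantageous payoff differences), also the latent "trustworthiness"
  type inferred about the partner;
* ``omega``  - social risk aversion, a multiplier valuing coins kept
  over coins exposed to the partner's discretion (investor only; the
  trustee carries a static assumption ``b_T(omega)`` about it);
* ``k``      - theory-of-mind level: a level-k agent models its partner
  as a level k-1 agent, down to a static non-learning "level -1";
* ``P``      - planning horizon, the number of future rounds folded
  into action values by a finite-horizon Bellman backup;
* ``zeta``   - irritability, the additive shift toward a retaliatory
  myopic policy after below-expectation partner actions;
* ``q``      - irritation awareness, the prior placed on the partner's
  irritability level;
* ``beta``   - softmax inverse temperature.

Beliefs about the partner's inequality-aversion type and irritability
level are Dirichlet pseudo-counts updated with the approximate rule
``A_new = A_old + p(o | type)``; an investor only updates the
inequality belief from trustee responses to investments greater
than 5 (responses to an investment of 5 leave both players with equal
payoffs under every fraction, so they carry no inequality signal).

Two deliberate structural choices (documented in docs/methods.md):
nested partner models plan exactly one round ahead while learning, and
agents do not anticipate their own future irritation while planning -
the irritated mixture is applied at choice time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .game import (ENDOWMENT, INVESTOR_ACTIONS, MULTIPLIER, N_ROUNDS,
                   trustee_actions_coins)

# ---------------------------------------------------------------------------
# parameter grids

ALPHA_GRID: tuple[float, ...] = (0.0, 0.4, 1.0)
OMEGA_GRID: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8)
TOM_GRID: tuple[int, ...] = (0, 1, 2, 3, 4)
PLAN_GRID: tuple[int, ...] = (1, 2, 3, 4)
ZETA_GRID: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
AWARENESS_GRID: tuple[int, ...] = (0, 1, 2, 3, 4)
BETA_GRID: tuple[float, ...] = (1 / 4, 1 / 3, 1 / 2, 1.0)

#: risk aversion ascribed to investor models nested below the top level
NESTED_RISK = 1.0
#: planning depth of nested partner models (the subject plans min(P, rounds left))
PARTNER_PLAN_DEPTH = 1

_OTHER = {"investor": "trustee", "trustee": "investor"}

# Dirichlet prior counts over the partner's irritability level for
# q = 1..4 ("irritation unlikely" ... "irritation certain"): counts
# proportional to r**j over the five zeta levels, total count 5.
# q = 0 ("irritation ignorant") pins the belief to zeta = 0, no updating.
_AWARENESS_RATI = {1: 1 / 3, 2: 1.0, 3: 3.0, 4: 9.0}


def awareness_prior(q: int) -> tuple[float, ...] | None:
    """Initial zeta-belief pseudo-counts for awareness level q (None if q=0)."""
    if q == 0:
        return None
    r = _AWARENESS_RATI[q]
    w = np.array([r ** j for j in range(len(ZETA_GRID))])
    w = w / w.sum() * 5.0
    return tuple(float(x) for x in w)


# ---------------------------------------------------------------------------
# parameters and public state containers


@dataclass(frozen=True)
class AgentParams:
    """Seven-parameter agent specification plus role and trustee risk belief."""

    role: str
    alpha: float
    omega: float
    tom: int
    plan: int
    zeta: float
    awareness: int
    beta: float
    partner_risk: float = 1.0  # b_T(omega); used when role == "trustee"

    def __post_init__(self) -> None:
        if self.role not in _OTHER:
            raise ValueError(f"role must be investor/trustee, got {self.role!r}")
        if self.tom < 0:
            raise ValueError("theory-of-mind level k must be >= 0 for a planning agent")
        if self.plan < 1:
            raise ValueError("planning horizon P must be >= 1")
        if not 0 <= self.zeta <= 1:
            raise ValueError("irritability zeta must lie in [0, 1]")
        if self.awareness not in AWARENESS_GRID:
            raise ValueError(f"irritation awareness q must be in {AWARENESS_GRID}")
        if self.beta <= 0:
            raise ValueError("inverse temperature beta must be positive")

    def as_dict(self) -> dict:
        return {"alpha": self.alpha, "omega": self.omega, "tom": self.tom,
                "plan": self.plan, "zeta": self.zeta, "awareness": self.awareness,
                "beta": self.beta}


@dataclass(frozen=True)
class BeliefState:
    """Dirichlet pseudo-counts over partner inequality-aversion and irritability."""

    alpha_counts: tuple[float, float, float] = (1.0, 1.0, 1.0)
    zeta_counts: tuple[float, ...] | None = None

    def alpha_probs(self) -> np.ndarray:
        a = np.asarray(self.alpha_counts, dtype=float)
        return a / a.sum()

    def zeta_probs(self) -> np.ndarray:
        if self.zeta_counts is None:  # irritation-ignorant: point mass on zeta=0
            out = np.zeros(len(ZETA_GRID))
            out[0] = 1.0
            return out
        z = np.asarray(self.zeta_counts, dtype=float)
        return z / z.sum()


@dataclass(frozen=True)
class IrritationState:
    """Mixture weight w in [0, 1] on the irritated (retaliatory) policy."""

    w: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("irritation weight must lie in [0, 1]")


# ---------------------------------------------------------------------------
# payoff / utility primitives (precomputed per investment)

_RESP: dict[int, np.ndarray] = {a: np.array(trustee_actions_coins(a))
                                for a in INVESTOR_ACTIONS}
_CHI_I = {a: (ENDOWMENT - a) + _RESP[a] for a in INVESTOR_ACTIONS}
_CHI_T = {a: MULTIPLIER * a - _RESP[a] for a in INVESTOR_ACTIONS}
_POS_I = {a: np.maximum(_CHI_I[a] - _CHI_T[a], 0.0) for a in INVESTOR_ACTIONS}
_POS_T = {a: np.maximum(_CHI_T[a] - _CHI_I[a], 0.0) for a in INVESTOR_ACTIONS}
# uniform-fraction means used by the static level -1 investor model
_MEAN_RESP = {a: float(_RESP[a].mean()) for a in INVESTOR_ACTIONS}
_MEAN_POS_I = {a: float(_POS_I[a].mean()) for a in INVESTOR_ACTIONS}


def investor_utility(params: AgentParams, a_I: int, a_T: float) -> float:
    """omega*(20 - a_I) + a_T - alpha*max(chi_I - chi_T, 0)."""
    if params.role != "investor":
        raise ValueError("investor_utility requires an investor-role parameter set")
    return _u_inv(params.alpha, params.omega, a_I, float(a_T))


def trustee_utility(params: AgentParams, a_I: int, a_T: float) -> float:
    """chi_T - alpha*max(chi_T - chi_I, 0)."""
    if params.role != "trustee":
        raise ValueError("trustee_utility requires a trustee-role parameter set")
    chi_i = (ENDOWMENT - a_I) + a_T
    chi_t = MULTIPLIER * a_I - a_T
    return chi_t - params.alpha * max(chi_t - chi_i, 0.0)


def _u_inv(alpha: float, omega: float, a_I: int, a_T: float) -> float:
    chi_i = (ENDOWMENT - a_I) + a_T
    chi_t = MULTIPLIER * a_I - a_T
    return omega * (ENDOWMENT - a_I) + a_T - alpha * max(chi_i - chi_t, 0.0)


def _u_inv_vec(alpha: float, omega: float, a_I: int) -> np.ndarray:
    return omega * (ENDOWMENT - a_I) + _RESP[a_I] - alpha * _POS_I[a_I]


def _u_tr_vec(alpha: float, a_I: int) -> np.ndarray:
    return _CHI_T[a_I] - alpha * _POS_T[a_I]


def softmax(x: Sequence[float], beta: float = 1.0) -> np.ndarray:
    z = beta * np.asarray(x, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# public belief / irritation operations


def update_inequality_belief(belief: BeliefState,
                             likelihoods: Sequence[float],
                             investment: int | None = None,
                             role: str = "investor") -> BeliefState:
    """Add p(o | alpha) to the pseudo-counts (approximate Dirichlet rule).

    Investor-side updates are gated: trustee responses to investments of
    5 or fewer carry no inequality signal and leave the belief unchanged.
    """
    lik = np.asarray(likelihoods, dtype=float)
    if lik.shape != (len(ALPHA_GRID),):
        raise ValueError(f"need one likelihood per alpha level {ALPHA_GRID}")
    if np.any(lik < 0) or np.any(lik > 1):
        raise ValueError(f"likelihoods must lie in [0, 1], got {likelihoods!r}")
    if role == "investor" and investment is not None and investment <= 5:
        return belief
    new = tuple(float(c + p) for c, p in zip(belief.alpha_counts, lik))
    return replace(belief, alpha_counts=new)


def update_irritation(state: IrritationState, zeta: float,
                      event: str) -> IrritationState:
    """Shift the mixture weight additively by zeta toward/away from irritation."""
    if event not in ("below", "above", "tie"):
        raise ValueError("event must be 'below', 'above' or 'tie'")
    if event == "below":
        return IrritationState(min(state.w + zeta, 1.0))
    if event == "above":
        return IrritationState(max(state.w - zeta, 0.0))
    return state


def expected_partner_value(belief_probs: Sequence[float],
                           policies: Sequence[Sequence[float]],
                           action_values: Sequence[float]) -> float:
    """Belief-weighted expected monetary value of the partner's next action."""
    b = np.asarray(belief_probs, dtype=float)
    if b.size == 0 or b.sum() <= 0:
        raise ValueError("belief support is empty")
    pol = np.asarray(policies, dtype=float)
    vals = np.asarray(action_values, dtype=float)
    return float(b @ (pol @ vals))


# ---------------------------------------------------------------------------
# recursive interactive state
#
# The engine state is a nested tuple  S = (A, Z, Wp, child):
#   A     3-tuple   pseudo-counts over the partner's alpha type
#   Z     5-tuple   pseudo-counts over the partner's zeta level (None if q=0)
#   Wp    5-tuple   partner irritation weight per hypothesised zeta level
#   child nested state of the level k-1 partner model (None at k=0)
# The agent's own irritation weight w is carried outside S: action values
# are independent of it, and it steps from the per-round event sign.

State = tuple

_static_cache: dict = {}
_policy_cache: dict = {}
_mix_cache: dict = {}
_step_cache: dict = {}
_q_cache: dict = {}
_sv_cache: dict = {}
_myo_trustee: dict = {}
_cache_stats = {"hits": 0, "misses": 0}


def clear_caches() -> None:
    for c in (_static_cache, _policy_cache, _mix_cache, _step_cache, _q_cache,
              _sv_cache):
        c.clear()


def cache_hit_rate() -> float:
    total = _cache_stats["hits"] + _cache_stats["misses"]
    return _cache_stats["hits"] / total if total else 0.0


def cache_sizes() -> dict:
    return {"static": len(_static_cache), "policy": len(_policy_cache),
            "mixture": len(_mix_cache), "step": len(_step_cache),
            "q": len(_q_cache)}


def initial_state(k: int, q: int) -> State:
    child = initial_state(k - 1, q) if k >= 1 else None
    return ((1.0, 1.0, 1.0), awareness_prior(q), (0.0,) * len(ZETA_GRID), child)


def _static_policy(role: str, alpha: float, omega: float, beta: float,
                   a_I: int | None) -> np.ndarray:
    """Level -1 policy: softmax over immediate utility, no learning.

    The static investor evaluates each investment against a uniform
    assumption over the five repayment fractions.
    """
    key = (role, alpha, omega, beta, a_I)
    out = _static_cache.get(key)
    if out is not None:
        return out
    if role == "trustee":
        if a_I == 0:
            out = np.array([1.0])
        else:
            out = softmax(_u_tr_vec(alpha, a_I), beta)
    else:
        u = np.array([omega * (ENDOWMENT - a) + _MEAN_RESP[a] - alpha * _MEAN_POS_I[a]
                      for a in INVESTOR_ACTIONS])
        out = softmax(u, beta)
    out.setflags(write=False)
    _static_cache[key] = out
    return out


def _irritated_policy(role: str, omega: float, beta: float,
                      a_I: int | None) -> np.ndarray:
    """Retaliatory policy: myopic, alpha=0, level -1, omega raised to >= 1."""
    return _static_policy(role, 0.0, max(omega, 1.0), beta, a_I)


def _model_policy(level: int, role: str, alpha: float, omega: float, beta: float,
                  q: int, state: State | None, a_I: int | None,
                  rl: int) -> np.ndarray:
    """Choice probabilities of a nested partner model (level >= -1)."""
    if level < 0:
        return _static_policy(role, alpha, omega, beta, a_I)
    key = (level, role, alpha, omega, beta, q, state, a_I, rl)
    out = _policy_cache.get(key)
    if out is None:
        depth = min(PARTNER_PLAN_DEPTH, rl)
        qv = _q_values(role, level, alpha, omega, beta, q, NESTED_RISK,
                       state, a_I, depth, rl)
        out = softmax(qv, beta)
        out.setflags(write=False)
        _policy_cache[key] = out
    return out


def _softmax_value(qn: tuple, beta: float) -> float:
    """Softmax-policy expectation of a Q tuple (continuation value)."""
    key = (qn, beta)
    v = _sv_cache.get(key)
    if v is None:
        pi = softmax(qn, beta)
        v = float(pi @ np.asarray(qn))
        _sv_cache[key] = v
    return v


class _Mix:
    __slots__ = ("probs", "per_alpha", "per_zeta", "values", "expected")

    def __init__(self, probs, per_alpha, per_zeta, values):
        self.probs = probs
        self.per_alpha = per_alpha
        self.per_zeta = per_zeta
        self.values = values
        self.expected = float(probs @ values)


def _partner_mixture(role: str, k: int, beta: float, q: int, partner_risk: float,
                     state: State, a_I: int | None, rl: int) -> _Mix:
    """Belief-weighted predictive distribution over the partner's next action.

    Mixes the rational level k-1 model per alpha type with the irritated
    policy, weighted by the current irritability belief and the tracked
    partner irritation weights.
    """
    key = (role, k, beta, q, partner_risk, state, a_I, rl)
    out = _mix_cache.get(key)
    if out is not None:
        return out
    A, Z, Wp, child = state
    other = _OTHER[role]
    omega_p = partner_risk if other == "investor" else NESTED_RISK
    if other == "trustee":
        values = _RESP[a_I] if a_I > 0 else np.array([0.0])
    else:
        values = np.array(INVESTOR_ACTIONS, dtype=float)

    rat = np.vstack([
        _model_policy(k - 1, other, alpha_p, omega_p, beta, q, child, a_I, rl)
        for alpha_p in ALPHA_GRID])
    irr = _irritated_policy(other, omega_p, beta, a_I)

    pA = np.asarray(A) / sum(A)
    if Z is None:
        pZ = np.zeros(len(ZETA_GRID))
        pZ[0] = 1.0
    else:
        pZ = np.asarray(Z) / sum(Z)
    Wp_arr = np.asarray(Wp)
    wbar = float(pZ @ Wp_arr)
    ratbar = pA @ rat
    probs = (1.0 - wbar) * ratbar + wbar * irr
    per_alpha = (1.0 - wbar) * rat + wbar * irr[None, :]
    per_zeta = None
    if Z is not None:
        per_zeta = (1.0 - Wp_arr[:, None]) * ratbar[None, :] + Wp_arr[:, None] * irr[None, :]
    out = _Mix(probs, per_alpha, per_zeta, values)
    _mix_cache[key] = out
    return out


def _step(role: str, k: int, beta: float, q: int, partner_risk: float,
          state: State, a_I: int, a_T: float, rl: int) -> tuple[State, int]:
    """Advance the nested state after a completed round (a_I, a_T).

    Returns the new state and the agent's own irritation event:
    +1 partner action below expectation, -1 above, 0 tie.
    Belief updates happen at the end of each complete round.
    """
    key = (role, k, beta, q, partner_risk, state, a_I, a_T, rl)
    out = _step_cache.get(key)
    if out is not None:
        return out
    A, Z, Wp, child = state
    mix = _partner_mixture(role, k, beta, q, partner_risk, state,
                           a_I if role == "investor" else None, rl)
    if role == "investor":
        acts = _RESP[a_I] if a_I > 0 else np.array([0.0])
        obs_idx = int(np.argmin(np.abs(acts - a_T)))
        if acts[obs_idx] != a_T:
            raise ValueError(f"repayment {a_T} illegal for investment {a_I}")
        obs_val = float(a_T)
    else:
        obs_idx = INVESTOR_ACTIONS.index(a_I)
        obs_val = float(a_I)

    # own irritation event: observed partner action vs belief-based expectation
    if obs_val < mix.expected:
        event = 1
    elif obs_val > mix.expected:
        event = -1
    else:
        event = 0

    allow_alpha = (role == "trustee") or (a_I > 5)
    allow_zeta = (Z is not None) and ((role == "trustee") or (a_I > 0))
    A2 = tuple(float(c + p) for c, p in zip(A, mix.per_alpha[:, obs_idx])) \
        if allow_alpha else A
    Z2 = tuple(float(c + p) for c, p in zip(Z, mix.per_zeta[:, obs_idx])) \
        if allow_zeta else Z

    # partner irritation: the partner model's own event from its viewpoint
    if k >= 1:
        child2, ev_p = _step(_OTHER[role], k - 1, beta, q, NESTED_RISK,
                             child, a_I, a_T, rl)
    else:
        child2 = None
        if role == "investor":
            own_val, exp_static = float(a_I), float(np.mean(INVESTOR_ACTIONS))
        else:
            own_val, exp_static = float(a_T), float(a_I)
        ev_p = 1 if own_val < exp_static else (-1 if own_val > exp_static else 0)
    Wp2 = tuple(float(min(max(w + z * ev_p, 0.0), 1.0))
                for w, z in zip(Wp, ZETA_GRID))

    out = ((A2, Z2, Wp2, child2), event)
    _step_cache[key] = out
    return out


def _q_values(role: str, k: int, alpha: float, omega: float, beta: float,
              q: int, partner_risk: float, state: State, a_I: int | None,
              depth: int, rl: int) -> tuple[float, ...]:
    """Finite-horizon Bellman backup of expected utilities.

    ``depth`` future rounds are included; partner responses come from the
    belief-weighted level k-1 model mixture, belief transitions follow the
    pseudo-count and irritation-weight rules, and continuation values are
    softmax-policy expectations of the next round's Q values.
    """
    if role == "trustee" and (depth == 0 or rl == 0):
        # myopic trustee values are state-free: immediate inequality-averse utility
        mkey = (alpha, a_I)
        out = _myo_trustee.get(mkey)
        if out is None:
            acts0 = _RESP[a_I] if a_I > 0 else np.array([0.0])
            out = tuple(float(x) for x in
                        (MULTIPLIER * a_I - acts0)
                        - alpha * np.maximum((MULTIPLIER * a_I - acts0)
                                             - ((ENDOWMENT - a_I) + acts0), 0.0))
            _myo_trustee[mkey] = out
        return out
    key = (role, k, alpha, omega, beta, q, partner_risk, state, a_I, depth, rl)
    out = _q_cache.get(key)
    if out is not None:
        _cache_stats["hits"] += 1
        return out
    _cache_stats["misses"] += 1
    if role == "investor":
        qs = []
        for a in INVESTOR_ACTIONS:
            mix = _partner_mixture(role, k, beta, q, partner_risk, state, a, rl)
            u = _u_inv_vec(alpha, omega, a)
            val = float(mix.probs @ u)
            if depth > 0 and rl > 0:
                acts = _RESP[a] if a > 0 else np.array([0.0])
                for o, p_o in zip(acts, mix.probs):
                    s2, _ = _step(role, k, beta, q, partner_risk, state,
                                  a, float(o), rl)
                    qn = _q_values(role, k, alpha, omega, beta, q, partner_risk,
                                   s2, None, depth - 1, rl - 1)
                    val += p_o * _softmax_value(qn, beta)
            qs.append(val)
        out = tuple(qs)
    else:
        acts = _RESP[a_I] if a_I > 0 else np.array([0.0])
        qs = []
        for a_T in acts:
            chi_t = MULTIPLIER * a_I - a_T
            chi_i = (ENDOWMENT - a_I) + a_T
            val = chi_t - alpha * max(chi_t - chi_i, 0.0)
            if depth > 0 and rl > 0:
                s2, _ = _step(role, k, beta, q, partner_risk, state,
                              a_I, float(a_T), rl)
                nxt = _partner_mixture(role, k, beta, q, partner_risk, s2,
                                       None, rl - 1)
                for a2, p2 in zip(INVESTOR_ACTIONS, nxt.probs):
                    qn = _q_values(role, k, alpha, omega, beta, q, partner_risk,
                                   s2, a2, depth - 1, rl - 1)
                    val += p2 * _softmax_value(qn, beta)
            qs.append(float(val))
        out = tuple(qs)
    _q_cache[key] = out
    return out


# ---------------------------------------------------------------------------
# public agent


class TrustAgent:
    """Stateful interactive-POMDP agent for one game.

    Tracks the nested belief state and the agent's own irritation weight;
    exposes choice probabilities, partner predictions and per-round
    observation updates.
    """

    def __init__(self, params: AgentParams, n_rounds: int = N_ROUNDS):
        self.params = params
        self.n_rounds = n_rounds
        self.reset()

    def reset(self) -> None:
        self._state: State = initial_state(self.params.tom, self.params.awareness)
        self.w = 0.0
        self.round = 1

    @property
    def rounds_left(self) -> int:
        return self.n_rounds - self.round

    @property
    def state(self) -> State:
        return self._state

    def belief(self) -> BeliefState:
        A, Z, _, _ = self._state
        return BeliefState(alpha_counts=A, zeta_counts=Z)

    def q_values(self, a_I: int | None = None) -> np.ndarray:
        p = self.params
        if p.role == "trustee" and a_I is None:
            raise ValueError("trustee action values require the current investment")
        rl = self.rounds_left
        depth = min(p.plan, rl)
        return np.array(_q_values(p.role, p.tom, p.alpha, p.omega, p.beta,
                                  p.awareness, p.partner_risk, self._state,
                                  a_I, depth, rl))

    def action_probabilities(self, a_I: int | None = None) -> np.ndarray:
        """Irritation mixture of planning softmax and retaliatory policy."""
        p = self.params
        qv = self.q_values(a_I)
        rational = softmax(qv, p.beta)
        if self.w == 0.0:
            return rational
        irr = _irritated_policy(p.role, p.omega, p.beta, a_I)
        return (1.0 - self.w) * rational + self.w * irr

    def partner_prediction(self, a_I: int | None = None) -> np.ndarray:
        p = self.params
        if p.role == "investor" and a_I is None:
            raise ValueError("predicting a repayment requires the investment")
        return np.array(_partner_mixture(p.role, p.tom, p.beta, p.awareness,
                                         p.partner_risk, self._state, a_I,
                                         self.rounds_left).probs)

    def expected_partner_action(self, a_I: int | None = None) -> float:
        p = self.params
        return _partner_mixture(p.role, p.tom, p.beta, p.awareness,
                                p.partner_risk, self._state, a_I,
                                self.rounds_left).expected

    def observe_round(self, a_I: int, a_T: float) -> None:
        p = self.params
        self._state, event = _step(p.role, p.tom, p.beta, p.awareness,
                                   p.partner_risk, self._state, a_I, float(a_T),
                                   self.rounds_left)
        if p.zeta > 0.0 and event != 0:
            self.w = min(max(self.w + p.zeta * event, 0.0), 1.0)
        self.round += 1


def action_values(params: AgentParams,
                  history: Iterable[tuple[int, float]],
                  n_rounds: int = N_ROUNDS,
                  current_investment: int | None = None) -> np.ndarray:
    """Q values at the round following ``history`` (completed rounds)."""
    agent = TrustAgent(params, n_rounds=n_rounds)
    for a_I, a_T in history:
        agent.observe_round(a_I, a_T)
    if agent.round > n_rounds:
        raise ValueError("history already covers the whole game")
    return agent.q_values(current_investment)


def choice_probabilities(q_values_: Sequence[float], params: AgentParams,
                         irritation: IrritationState | float = 0.0,
                         current_investment: int | None = None) -> np.ndarray:
    """Mixture softmax of Eq.-style choice probabilities.

    ``(1-w) * softmax(beta*Q) + w * irritated`` where the irritated policy
    is myopic, inequality-blind, level -1, with risk aversion >= 1.
    """
    w = irritation.w if isinstance(irritation, IrritationState) else float(irritation)
    if not 0.0 <= w <= 1.0:
        raise ValueError("irritation weight must lie in [0, 1]")
    qv = np.asarray(q_values_, dtype=float)
    if not np.all(np.isfinite(qv)):
        raise ValueError("action values must be finite")
    rational = softmax(qv, params.beta)
    if w == 0.0:
        return rational
    irr = _irritated_policy(params.role, params.omega, params.beta,
                            current_investment)
    return (1.0 - w) * rational + w * irr
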