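"""Brute-force reference implementation of the trust-game likelihood.

Computes trajectory negative log likelihoods by explicitly enumerating
every action/response/belief path with plain Python floats and lists:
no caching, no vectorization, no shared subtrees.  Written directly from
the model definition in docs/methods.md as an independent check of the
recursive engine.  Only usable for short games and small k/P.
"""

import math

FRACS = [0.0, 1 / 6, 1 / 3, 1 / 2, 2 / 3]
ACTS = [0, 5, 10, 15, 20]
ZETAS = [0.0, 0.25, 0.5, 0.75, 1.0]
ALPHAS = [0.0, 0.4, 1.0]
NESTED_RISK = 1.0
MODEL_DEPTH = 1  # planning depth of nested partner models


def responses(a_I):
    return [0.0] if a_I == 0 else [f * 3 * a_I for f in FRACS]


def u_inv(alpha, omega, a_I, a_T):
    chi_i = (20 - a_I) + a_T
    chi_t = 3 * a_I - a_T
    return omega * (20 - a_I) + a_T - alpha * max(chi_i - chi_t, 0.0)


def u_tr(alpha, a_I, a_T):
    chi_i = (20 - a_I) + a_T
    chi_t = 3 * a_I - a_T
    return chi_t - alpha * max(chi_t - chi_i, 0.0)


def softmax(us, beta):
    m = max(us)
    es = [math.exp(beta * (u - m)) for u in us]
    s = sum(es)
    return [e / s for e in es]


def static_policy(role, alpha, omega, beta, a_I=None):
    """Level -1: softmax over immediate utility, uniform-fraction assumption."""
    if role == "trustee":
        if a_I == 0:
            return [1.0]
        return softmax([u_tr(alpha, a_I, a_T) for a_T in responses(a_I)], beta)
    us = [sum(u_inv(alpha, omega, a, f * 3 * a) for f in FRACS) / len(FRACS)
          for a in ACTS]
    return softmax(us, beta)


def irritated_policy(role, omega, beta, a_I=None):
    return static_policy(role, 0.0, max(omega, 1.0), beta, a_I)


def awareness_prior(q):
    if q == 0:
        return None
    r = {1: 1 / 3, 2: 1.0, 3: 3.0, 4: 9.0}[q]
    w = [r ** j for j in range(5)]
    s = sum(w)
    return [x / s * 5.0 for x in w]


def init_state(k, q):
    return {"A": [1.0, 1.0, 1.0], "Z": awareness_prior(q),
            "Wp": [0.0] * 5,
            "child": init_state(k - 1, q) if k >= 1 else None}


def other(role):
    return "trustee" if role == "investor" else "investor"


def model_policy(level, role, alpha, omega, beta, q, state, a_I, rl):
    if level < 0:
        return static_policy(role, alpha, omega, beta, a_I)
    depth = min(MODEL_DEPTH, rl)
    qs = q_vals(role, level, alpha, omega, beta, q, NESTED_RISK,
                state, a_I, depth, rl)
    return softmax(qs, beta)


def mixture(role, k, beta, q, partner_risk, state, a_I, rl):
    """Belief-weighted predictive mixture over the partner's next action."""
    part = other(role)
    omega_p = partner_risk if part == "investor" else NESTED_RISK
    if part == "trustee":
        values = responses(a_I)
    else:
        values = [float(a) for a in ACTS]
    rat = [model_policy(k - 1, part, a_p, omega_p, beta, q,
                        state["child"], a_I, rl)
           for a_p in ALPHAS]
    irr = irritated_policy(part, omega_p, beta, a_I)
    sA = sum(state["A"])
    pA = [c / sA for c in state["A"]]
    if state["Z"] is None:
        pZ = [1.0, 0.0, 0.0, 0.0, 0.0]
    else:
        sZ = sum(state["Z"])
        pZ = [c / sZ for c in state["Z"]]
    wbar = sum(p * w for p, w in zip(pZ, state["Wp"]))
    n = len(values)
    ratbar = [sum(pA[i] * rat[i][j] for i in range(3)) for j in range(n)]
    mix = [(1 - wbar) * ratbar[j] + wbar * irr[j] for j in range(n)]
    per_alpha = [[(1 - wbar) * rat[i][j] + wbar * irr[j] for j in range(n)]
                 for i in range(3)]
    per_zeta = [[(1 - state["Wp"][z]) * ratbar[j] + state["Wp"][z] * irr[j]
                 for j in range(n)] for z in range(5)]
    expected = sum(mix[j] * values[j] for j in range(n))
    return mix, per_alpha, per_zeta, values, expected


def step(role, k, beta, q, partner_risk, state, a_I, a_T, rl):
    """End-of-round belief/irritation update; returns (state', own event)."""
    mix, per_alpha, per_zeta, values, expected = mixture(
        role, k, beta, q, partner_risk, state,
        a_I if role == "investor" else None, rl)
    if role == "investor":
        obs_idx = min(range(len(values)), key=lambda j: abs(values[j] - a_T))
        obs_val = a_T
    else:
        obs_idx = ACTS.index(a_I)
        obs_val = float(a_I)
    event = 1 if obs_val < expected else (-1 if obs_val > expected else 0)

    new = {"A": list(state["A"]),
           "Z": None if state["Z"] is None else list(state["Z"]),
           "Wp": list(state["Wp"]), "child": None}
    if role == "trustee" or a_I > 5:
        new["A"] = [c + per_alpha[i][obs_idx]
                    for i, c in enumerate(state["A"])]
    if state["Z"] is not None and (role == "trustee" or a_I > 0):
        new["Z"] = [c + per_zeta[z][obs_idx]
                    for z, c in enumerate(state["Z"])]
    if k >= 1:
        child2, ev_p = step(other(role), k - 1, beta, q, NESTED_RISK,
                            state["child"], a_I, a_T, rl)
        new["child"] = child2
    else:
        if role == "investor":
            own_val, exp_static = float(a_I), sum(ACTS) / len(ACTS)
        else:
            own_val, exp_static = float(a_T), float(a_I)
        ev_p = 1 if own_val < exp_static else (-1 if own_val > exp_static else 0)
    new["Wp"] = [min(max(w + z * ev_p, 0.0), 1.0)
                 for w, z in zip(state["Wp"], ZETAS)]
    return new, event


def q_vals(role, k, alpha, omega, beta, q, partner_risk, state, a_I, depth, rl):
    """Finite-horizon action values by explicit path enumeration."""
    if role == "investor":
        out = []
        for a in ACTS:
            mix, _, _, values, _ = mixture(role, k, beta, q, partner_risk,
                                           state, a, rl)
            val = sum(p * u_inv(alpha, omega, a, o)
                      for p, o in zip(mix, values))
            if depth > 0 and rl > 0:
                for p_o, o in zip(mix, values):
                    s2, _ = step(role, k, beta, q, partner_risk, state,
                                 a, o, rl)
                    qn = q_vals(role, k, alpha, omega, beta, q, partner_risk,
                                s2, None, depth - 1, rl - 1)
                    pi = softmax(qn, beta)
                    val += p_o * sum(x * y for x, y in zip(pi, qn))
            out.append(val)
        return out
    out = []
    for a_T in responses(a_I):
        val = u_tr(alpha, a_I, a_T)
        if depth > 0 and rl > 0:
            s2, _ = step(role, k, beta, q, partner_risk, state, a_I, a_T, rl)
            mix, _, _, _, _ = mixture(role, k, beta, q, partner_risk, s2,
                                      None, rl - 1)
            for p2, a2 in zip(mix, ACTS):
                qn = q_vals(role, k, alpha, omega, beta, q, partner_risk,
                            s2, a2, depth - 1, rl - 1)
                pi = softmax(qn, beta)
                val += p2 * sum(x * y for x, y in zip(pi, qn))
        out.append(val)
    return out


def nll(role, alpha, omega, tom, plan, zeta, awareness, beta, pairs,
        scope="both_players", partner_risk=1.0):
    """Trajectory NLL by forward enumeration, natural logs."""
    state = init_state(tom, awareness)
    w = 0.0
    total = 0.0
    T = len(pairs)
    for t, (a_I, a_T) in enumerate(pairs, start=1):
        rl = T - t
        depth = min(plan, rl)
        if role == "investor":
            qv = q_vals(role, tom, alpha, omega, beta, awareness, partner_risk,
                        state, None, depth, rl)
            rational = softmax(qv, beta)
            irr = irritated_policy("investor", omega, beta)
            probs = [(1 - w) * r + w * i for r, i in zip(rational, irr)]
            total -= math.log(probs[ACTS.index(a_I)])
            if scope == "both_players" and a_I > 0:
                mix, _, _, values, _ = mixture(role, tom, beta, awareness,
                                               partner_risk, state, a_I, rl)
                j = min(range(len(values)), key=lambda j: abs(values[j] - a_T))
                total -= math.log(mix[j])
        else:
            qv = q_vals(role, tom, alpha, omega, beta, awareness, partner_risk,
                        state, a_I, depth, rl)
            rational = softmax(qv, beta)
            irr = irritated_policy("trustee", NESTED_RISK, beta, a_I)
            probs = [(1 - w) * r + w * i for r, i in zip(rational, irr)]
            values = responses(a_I)
            j = min(range(len(values)), key=lambda j: abs(values[j] - a_T))
            total -= math.log(probs[j])
            if scope == "both_players":
                mix, _, _, _, _ = mixture(role, tom, beta, awareness,
                                          partner_risk, state, None, rl)
                total -= math.log(mix[ACTS.index(a_I)])
        state, event = step(role, tom, beta, awareness, partner_risk,
                            state, a_I, a_T, rl)
        if zeta > 0.0 and event != 0:
            w = min(max(w + zeta * event, 0.0), 1.0)
    return total
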