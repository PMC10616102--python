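"""Synthetic cohorts: simulated games, longitudinal tables, recovery runs.

This module stands in for the study-style raw data: an accelerated
longitudinal design with two task visits about 1.5 years apart, ages
14-25, a standardized family-adversity factor, and three waves of
friendship-questionnaire (CFQ-like) scores.  The generator encodes the
statistical structure the downstream analyses assume:

* social risk aversion (omega) decreases with both cross-sectional and
  longitudinal age, so simulated trust increases over adolescence;
* higher adversity shifts probability mass toward higher irritability
  (ordered-categorical softmax link over the zeta grid);
* CFQ scores follow a linear mixed structure in wave, baseline round-1
  investment, adversity and their interactions, with a subject random
  intercept.

All draws flow through a single seeded ``numpy.random.Generator``;
identical seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import agents
from .agents import (ALPHA_GRID, BETA_GRID, OMEGA_GRID, ZETA_GRID,
                     AgentParams, TrustAgent)
from .game import (GameTrajectory, INVESTOR_ACTIONS, N_ROUNDS, Round,
                   TRUSTEE_FRACTIONS, trustee_actions_coins)
from .inference import (M1, ModelSpec, fit_subject, grid_points,
                        recovery_grid)


def default_trustee_params() -> AgentParams:
    """Default synthetic trustee: trustworthy but irritable.

    Full inequality aversion makes the myopic repayment the
    payoff-equalizing fraction (a reliable reciprocator, like the adult
    trustees the task emulates), while zeta = 0.25 lets repeated
    below-expectation investments trigger retaliatory repayments.  A
    level-0 learner keeps whole-cohort simulation tractable; any
    parameter set (or a replay schedule) can be substituted.
    """
    return AgentParams("trustee", alpha=1.0, omega=1.0, tom=0, plan=1,
                       zeta=0.25, awareness=2, beta=1 / 3, partner_risk=1.0)


@dataclass
class TrusteeConfig:
    """How the synthetic trustee behaves: a full agent or a replayed schedule."""

    mode: str = "replay"  # "replay" | "agent"
    params: AgentParams = field(default_factory=default_trustee_params)
    #: replay mode: repayment fractions per round (floats from {0,1/6,1/3,1/2,2/3});
    #: None lets the cohort generator draw a fresh schedule per game, emulating
    #: heterogeneous adult-trustee behaviour
    schedule: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("agent", "replay"):
            raise ValueError("trustee mode must be 'agent' or 'replay'")


@dataclass
class CohortConfig:
    """Study-condition settings for the synthetic longitudinal cohort."""

    n_subjects: int = 40
    seed: int = 0
    n_rounds: int = N_ROUNDS
    # enrolment ages and inter-visit interval (years)
    age_range: tuple[float, float] = (14.0, 24.0)
    interval_mean: float = 1.48
    interval_sd: float = 0.29
    interval_range: tuple[float, float] = (0.99, 2.6)
    # risk-aversion age structure: latent omega before snapping to the grid
    omega_base: float = 0.8
    omega_cross_slope: float = -0.03   # per year of cross-sectional age
    omega_long_slope: float = -0.08    # per year of longitudinal age
    omega_sd: float = 0.15
    # adversity -> irritability ordered-categorical link
    zeta_adversity: float = 0.8        # softmax shift per SD of adversity
    zeta_base_weights: tuple[float, ...] = (3.0, 1.5, 0.8, 0.4, 0.2)
    # other true-parameter distributions
    alpha_probs: tuple[float, ...] = (0.3, 0.4, 0.3)
    tom_values: tuple[int, ...] = (0, 1)
    tom_probs: tuple[float, ...] = (0.6, 0.4)
    plan_values: tuple[int, ...] = (1, 2)
    plan_probs: tuple[float, ...] = (0.6, 0.4)
    beta_values: tuple[float, ...] = BETA_GRID
    awareness_values: tuple[int, ...] = (0, 1, 2)
    # CFQ generator: 3 waves, linear mixed structure
    cfq_intercept: float = 50.0
    cfq_wave_slope: float = 1.0
    cfq_trust_slope: float = 0.3       # per coin of (round-1 investment - 10)
    cfq_adversity_slope: float = -2.0
    cfq_trust_wave: float = 0.15       # trust x wave
    cfq_trust_wave_adversity: float = 0.10  # trust x wave x adversity
    cfq_subject_sd: float = 5.0
    cfq_noise_sd: float = 3.0
    sex_trust_effect: float = 0.0      # latent omega shift for sex = +0.5
    dropout: float = 0.0               # probability of a missing second visit
    trustee: TrusteeConfig = field(default_factory=TrusteeConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        for name in ("interval_sd", "omega_sd", "cfq_subject_sd", "cfq_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age range must be increasing")


def simulate_game(investor: AgentParams | TrustAgent,
                  trustee: AgentParams | TrustAgent | TrusteeConfig | Sequence[float],
                  rng: np.random.Generator | int,
                  subject_id: str = "sim", timepoint: str = "T1",
                  n_rounds: int = N_ROUNDS) -> GameTrajectory:
    """Simulate one game by alternate sampling from the agents' policies.

    ``trustee`` may be a parameter set (full interactive agent) or a
    replay schedule of repayment fractions.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    inv = investor if isinstance(investor, TrustAgent) else \
        TrustAgent(investor, n_rounds=n_rounds)
    inv.reset()
    schedule = None
    tru = None
    if isinstance(trustee, TrusteeConfig):
        if trustee.mode == "replay":
            if trustee.schedule is None:
                schedule = sample_trustee_schedule(rng, n_rounds)
            else:
                schedule = list(trustee.schedule)
        else:
            tru = TrustAgent(trustee.params, n_rounds=n_rounds)
    elif isinstance(trustee, (AgentParams, TrustAgent)):
        tru = trustee if isinstance(trustee, TrustAgent) else \
            TrustAgent(trustee, n_rounds=n_rounds)
    else:
        schedule = list(trustee)
    if tru is not None:
        tru.reset()
    if schedule is not None and len(schedule) < n_rounds:
        raise ValueError("replay schedule shorter than the game")

    rounds = []
    for t in range(1, n_rounds + 1):
        p_inv = inv.action_probabilities()
        a_I = int(rng.choice(INVESTOR_ACTIONS, p=p_inv))
        if a_I == 0:
            a_T = 0.0
        elif schedule is not None:
            frac = schedule[t - 1]
            legal = trustee_actions_coins(a_I)
            a_T = min(legal, key=lambda x: abs(x - float(frac) * 3 * a_I))
        else:
            p_tru = tru.action_probabilities(a_I)
            acts = trustee_actions_coins(a_I)
            a_T = float(acts[int(rng.choice(len(acts), p=p_tru))])
        rounds.append(Round(t, a_I, a_T))
        inv.observe_round(a_I, a_T)
        if tru is not None:
            tru.observe_round(a_I, a_T)
    return GameTrajectory(subject_id, timepoint, rounds, n_rounds=n_rounds)


def sample_trustee_schedule(rng: np.random.Generator,
                            n_rounds: int = N_ROUNDS) -> list[float]:
    """Replay schedule emulating a mostly-reciprocating adult trustee.

    Fractions are drawn leaning on the fair repayments (1/3, 1/2) with
    occasional exploitative (0, 1/6) and generous (2/3) rounds, so both
    below- and above-expectation events occur.
    """
    fracs = [float(f) for f in TRUSTEE_FRACTIONS]
    probs = [0.10, 0.15, 0.30, 0.30, 0.15]
    return [fracs[i] for i in rng.choice(len(fracs), size=n_rounds, p=probs)]


def _snap(value: float, grid: Sequence[float]) -> float:
    arr = np.asarray(grid, dtype=float)
    return float(arr[int(np.argmin(np.abs(arr - value)))])


def _draw_zeta(rng: np.random.Generator, adversity: float,
               cfg: CohortConfig) -> float:
    logits = np.log(np.asarray(cfg.zeta_base_weights, dtype=float))
    logits = logits + cfg.zeta_adversity * adversity * np.arange(len(ZETA_GRID))
    p = np.exp(logits - logits.max())
    p /= p.sum()
    return float(ZETA_GRID[int(rng.choice(len(ZETA_GRID), p=p))])


def generate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, list[GameTrajectory]]:
    """Draw a longitudinal cohort and simulate its trust games.

    Returns a long-format subject x visit table (ages, sex, adversity,
    true parameters, CFQ waves) and the simulated trajectories.
    """
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    trajs: list[GameTrajectory] = []
    sample_mid = float(np.mean(cfg.age_range)) + cfg.interval_mean / 2.0
    for i in range(cfg.n_subjects):
        sid = f"S{i:04d}"
        age1 = float(rng.uniform(*cfg.age_range))
        interval = float(np.clip(rng.normal(cfg.interval_mean, cfg.interval_sd),
                                 *cfg.interval_range))
        ages = [age1, age1 + interval]
        has_t2 = rng.uniform() >= cfg.dropout
        sex = float(rng.choice((-0.5, 0.5)))
        adversity = float(rng.normal())
        alpha = float(ALPHA_GRID[int(rng.choice(len(ALPHA_GRID),
                                                p=cfg.alpha_probs))])
        tom = int(rng.choice(cfg.tom_values, p=cfg.tom_probs))
        plan = int(rng.choice(cfg.plan_values, p=cfg.plan_probs))
        beta = float(rng.choice(cfg.beta_values))
        awareness = int(rng.choice(cfg.awareness_values))
        zeta = _draw_zeta(rng, adversity, cfg)
        mean_age = float(np.mean(ages))
        cfq_re = rng.normal(0.0, cfg.cfq_subject_sd)
        visit_rows = []
        for j, (tp, age) in enumerate(zip(("T1", "T2"), ages)):
            if tp == "T2" and not has_t2:
                continue
            cs_age = mean_age - sample_mid
            long_age = age - mean_age
            latent = (cfg.omega_base + cfg.omega_cross_slope * cs_age
                      + cfg.omega_long_slope * long_age
                      + cfg.sex_trust_effect * sex
                      + rng.normal(0.0, cfg.omega_sd))
            omega = _snap(latent, OMEGA_GRID)
            params = AgentParams("investor", alpha, omega, tom, plan, zeta,
                                 awareness, beta)
            agents.clear_caches()
            traj = simulate_game(params, cfg.trustee, rng, subject_id=sid,
                                 timepoint=tp, n_rounds=cfg.n_rounds)
            trajs.append(traj)
            visit_rows.append({
                "subject_id": sid, "timepoint": tp, "age": age, "sex": sex,
                "adversity": adversity, "true_alpha": alpha,
                "true_omega": omega, "true_tom": tom, "true_plan": plan,
                "true_zeta": zeta, "true_awareness": awareness,
                "true_beta": beta,
                "a_priori_trust": traj.investments[0],
            })
        t1_trust = visit_rows[0]["a_priori_trust"] - 10.0
        for w in (1, 2, 3):
            wave = w - 2.0  # centred wave index
            cfq = (cfg.cfq_intercept + cfg.cfq_wave_slope * wave
                   + cfg.cfq_trust_slope * t1_trust
                   + cfg.cfq_adversity_slope * adversity
                   + cfg.cfq_trust_wave * t1_trust * wave
                   + cfg.cfq_trust_wave_adversity * t1_trust * wave * adversity
                   + cfq_re + rng.normal(0.0, cfg.cfq_noise_sd))
            for row in visit_rows:
                row[f"cfq_wave{w}"] = float(cfq)
        rows.extend(visit_rows)
    columns = ["subject_id", "timepoint", "age", "sex", "adversity",
               "true_alpha", "true_omega", "true_tom", "true_plan",
               "true_zeta", "true_awareness", "true_beta", "a_priori_trust",
               "cfq_wave1", "cfq_wave2", "cfq_wave3"]
    table = pd.DataFrame(rows, columns=columns)
    return table, trajs


# ---------------------------------------------------------------------------
# parameter recovery


def recovery_experiment(n_agents: int, grid: dict | None = None,
                        specs: Sequence[ModelSpec] = (M1,),
                        seed: int = 0,
                        trustee: TrusteeConfig | None = None,
                        scope: str = "both_players",
                        n_rounds: int = N_ROUNDS) -> dict:
    """Simulate agents at known grid points and refit them.

    Returns a dict with the long-format fits table (one row per agent and
    model spec), per-parameter exact and adjacent recovery rates, and
    confusion matrices.  By default the partner is a replayed
    adult-trustee-style schedule drawn per agent.
    """
    if grid is None:
        grid = recovery_grid()
    rng = np.random.default_rng(seed)
    points = list(grid_points(grid))
    truth_idx = rng.integers(0, len(points), size=n_agents)
    rows = []
    for i, idx in enumerate(truth_idx):
        truth = points[int(idx)]
        agents.clear_caches()
        tru = trustee if trustee is not None else \
            TrusteeConfig(mode="replay",
                          schedule=sample_trustee_schedule(rng, n_rounds))
        traj = simulate_game(truth, tru, rng, subject_id=f"A{i:03d}",
                             n_rounds=n_rounds)
        for spec in specs:
            fit = fit_subject(traj, spec, grid, scope, clear_caches=False)
            row = {"agent": f"A{i:03d}", "model": spec.name}
            row.update({f"true_{k}": v for k, v in truth.as_dict().items()})
            row.update(fit.as_row())
            rows.append(row)
    fits = pd.DataFrame(rows)
    report = {"fits": fits, "n_agents": n_agents,
              "n_models": len(specs), "grid_size": len(points)}
    main = fits[fits["model"] == specs[0].name]
    for name in ("alpha", "omega", "tom", "plan", "zeta", "awareness", "beta"):
        axis = tuple(sorted(grid[name]))
        if len(axis) < 2:
            continue
        true_i = main[f"true_{name}"].map(lambda v: axis.index(v))
        fit_i = main[name].map(lambda v: axis.index(v))
        report[f"{name}_exact"] = float((true_i == fit_i).mean())
        report[f"{name}_adjacent"] = float(((true_i - fit_i).abs() <= 1).mean())
        conf = pd.crosstab(true_i, fit_i).reindex(
            index=range(len(axis)), columns=range(len(axis)), fill_value=0)
        report[f"{name}_confusion"] = conf
    if len(grid.get("zeta", ())) > 1:
        report["zeta_detection_accuracy"] = float(
            ((main["true_zeta"] > 0) == (main["zeta"] > 0)).mean())
    return report


# ---------------------------------------------------------------------------
# direct linear-mixed-model generator (for estimator calibration)


def simulate_lmm_cohort(n_subjects: int, rng: np.random.Generator | int,
                        long_age_slope: float = 0.27,
                        cross_age_slope: float = 0.2,
                        interaction: float = 0.0,
                        sex_effect: float = 0.0,
                        intercept: float = 10.0,
                        subject_sd: float = 2.0,
                        noise_sd: float = 1.5,
                        cfg: CohortConfig | None = None) -> pd.DataFrame:
    """Cohort table whose outcome follows a known linear mixed model.

    The design (two visits, ages, sex) matches the trust cohort, but the
    outcome is drawn directly as
    ``intercept + b_long*long_age + b_cross*cross_age + b_int*long*cross
    + b_sex*sex + u_subject + noise`` so estimator recovery and CI
    coverage can be checked against the injected coefficients.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cfg = cfg or CohortConfig()
    rows = []
    sample_mid = float(np.mean(cfg.age_range)) + cfg.interval_mean / 2.0
    for i in range(n_subjects):
        age1 = float(rng.uniform(*cfg.age_range))
        interval = float(np.clip(rng.normal(cfg.interval_mean, cfg.interval_sd),
                                 *cfg.interval_range))
        ages = (age1, age1 + interval)
        sex = float(rng.choice((-0.5, 0.5)))
        u = rng.normal(0.0, subject_sd)
        mean_age = float(np.mean(ages))
        for tp, age in zip(("T1", "T2"), ages):
            cs, lg = mean_age - sample_mid, age - mean_age
            y = (intercept + long_age_slope * lg + cross_age_slope * cs
                 + interaction * lg * cs + sex_effect * sex
                 + u + rng.normal(0.0, noise_sd))
            rows.append({"subject_id": f"S{i:04d}", "timepoint": tp,
                         "age": age, "sex": sex, "outcome": y})
    return pd.DataFrame(rows)
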