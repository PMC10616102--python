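"""Trajectory likelihoods, exhaustive grid-search fitting and model comparison.

Estimation is a full search over a discrete parameter grid; the reported
fit is the grid point with the smallest negative log likelihood (NLL,
natural logs throughout).  By default the likelihood covers the whole
game trajectory - 10 investor actions under the subject model plus 10
trustee actions under the subject's belief-weighted partner-model
mixture - which is what makes the uniform-random benchmark model score
an average Draper BIC of 20*ln(5) ~= 32.19 on games without zero
investments.

Model variants:

====  ===========================================================  =
name  fixed parameters                                             p
====  ===========================================================  =
M1    none (full model)                                            7
M2    zeta = 0, q = 0                                              5
M3    M2 + omega = 1, beta = 1/3                                   3
M4    M3 + k = 0                                                   2
M5    uniform-random policy                                        0
====  ===========================================================  =

Draper BIC = NLL + (p/2) * (ln 10 - ln 2*pi).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agents
from .agents import (ALPHA_GRID, AWARENESS_GRID, BETA_GRID, OMEGA_GRID,
                     PLAN_GRID, TOM_GRID, ZETA_GRID, AgentParams, TrustAgent)
from .game import GameTrajectory, INVESTOR_ACTIONS

logger = logging.getLogger(__name__)

#: BIC penalty slope per free parameter (natural logs, n = 10 actions-per-role)
BIC_SLOPE = 0.5 * (math.log(10.0) - math.log(2.0 * math.pi))

_PARAM_ORDER = ("alpha", "omega", "tom", "plan", "zeta", "awareness", "beta")


@dataclass(frozen=True)
class ModelSpec:
    """Named model variant: a map of fixed parameters and a free-parameter count."""

    name: str
    fixed: dict = field(default_factory=dict)
    random_policy: bool = False

    @property
    def n_free(self) -> int:
        if self.random_policy:
            return 0
        return len(_PARAM_ORDER) - len(self.fixed)


M1 = ModelSpec("M1")
M2 = ModelSpec("M2", {"zeta": 0.0, "awareness": 0})
M3 = ModelSpec("M3", {"zeta": 0.0, "awareness": 0, "omega": 1.0, "beta": 1 / 3})
M4 = ModelSpec("M4", {"zeta": 0.0, "awareness": 0, "omega": 1.0, "beta": 1 / 3,
                      "tom": 0})
M5 = ModelSpec("M5", random_policy=True)
DEFAULT_SPECS = (M1, M2, M3, M4, M5)


def full_grid() -> dict:
    """The complete parameter grid (3*8*5*4*5*5*4 = 48,000 points)."""
    return {"alpha": ALPHA_GRID, "omega": OMEGA_GRID, "tom": TOM_GRID,
            "plan": PLAN_GRID, "zeta": ZETA_GRID, "awareness": AWARENESS_GRID,
            "beta": BETA_GRID}


def reduced_grid() -> dict:
    """Desk-scale grid (k <= 1, P <= 2) that still nests M2..M4's fixed values."""
    return {"alpha": (0.0, 1.0), "omega": (0.6, 1.0, 1.4), "tom": (0, 1),
            "plan": (1, 2), "zeta": (0.0, 0.5), "awareness": (0, 2),
            "beta": (1 / 3, 1.0)}


def recovery_grid() -> dict:
    """Grid for parameter-recovery experiments (low-stochasticity agents).

    omega spans the range over which simulated investment varies from
    high to near zero, so risk aversion is identifiable from behaviour;
    agents are irritation-aware (q=2), which keeps theory of mind
    non-degenerate (a level-0 trustee model differs from the static one
    through the partner-irritation channel).
    """
    return {"alpha": (0.0, 1.0), "omega": (0.4, 0.6, 0.8, 1.0), "tom": (0, 1),
            "plan": (1, 2), "zeta": (0.0, 0.5), "awareness": (2,),
            "beta": (1.0,)}


def mini_grid() -> dict:
    """Toy grid for smoke runs and demos (seconds per subject)."""
    return {"alpha": (0.0, 1.0), "omega": (0.6, 1.0), "tom": (0,),
            "plan": (1,), "zeta": (0.0, 0.5), "awareness": (0,),
            "beta": (1.0,)}


def grid_points(grid: dict, spec: ModelSpec = M1, role: str = "investor",
                partner_risk: float = 1.0):
    """Grid points after applying the spec's fixed values.

    Iterates in ascending lexicographic order over
    (alpha, omega, k, P, zeta, q, beta), which is also the tie-break order.
    """
    if spec.random_policy:
        return
    axes = []
    for name in _PARAM_ORDER:
        if name in spec.fixed:
            axes.append((spec.fixed[name],))
        else:
            axes.append(tuple(sorted(grid[name])))
    for combo in itertools.product(*axes):
        yield AgentParams(role, *combo, partner_risk=partner_risk)


def grid_size(grid: dict, spec: ModelSpec = M1) -> int:
    if spec.random_policy:
        return 1
    n = 1
    for name in _PARAM_ORDER:
        if name not in spec.fixed:
            n *= len(grid[name])
    return n


def draper_bic(nll: float, p: int) -> float:
    """NLL + (p/2)*(ln 10 - ln 2*pi)."""
    if p < 0:
        raise ValueError("parameter count p must be non-negative")
    return nll + p * BIC_SLOPE


def random_model_nll(traj: GameTrajectory, scope: str = "both_players") -> float:
    """NLL of the uniform-random policy (M5).

    Every 5-option choice contributes ln 5; a forced trustee response to a
    zero investment contributes ln 1 = 0.
    """
    _check_scope(scope)
    n_choices = len(traj.rounds)
    if scope == "both_players":
        n_choices += sum(1 for r in traj.rounds if r.a_I > 0)
    return n_choices * math.log(len(INVESTOR_ACTIONS))


def trajectory_nll(params: AgentParams, traj: GameTrajectory,
                   spec: ModelSpec = M1, scope: str = "both_players") -> float:
    """Negative log likelihood of an observed game under a parameter set.

    ``both_players`` (default) scores the subject's own actions under the
    subject model and the partner's actions under the subject's
    belief-weighted partner-model mixture; ``investor_only`` scores only
    the subject's actions.  A zero-probability observation yields +inf.
    """
    _check_scope(scope)
    if spec.random_policy:
        return random_model_nll(traj, scope)
    for name, value in spec.fixed.items():
        if getattr(params, name) != value:
            raise ValueError(f"{spec.name} fixes {name}={value}, "
                             f"got {getattr(params, name)}")
    agent = TrustAgent(params, n_rounds=len(traj.rounds))
    nll = 0.0
    for rnd in traj.rounds:
        a_I, a_T = rnd.a_I, rnd.a_T
        if params.role == "investor":
            probs = agent.action_probabilities()
            p_own = probs[INVESTOR_ACTIONS.index(a_I)]
            nll -= _safe_log(p_own)
            if scope == "both_players" and a_I > 0:
                pred = agent.partner_prediction(a_I)
                acts = agents._RESP[a_I]
                nll -= _safe_log(pred[int(np.argmin(np.abs(acts - a_T)))])
        else:
            probs = agent.action_probabilities(a_I)
            acts = agents._RESP[a_I] if a_I > 0 else np.array([0.0])
            nll -= _safe_log(probs[int(np.argmin(np.abs(acts - a_T)))])
            if scope == "both_players":
                pred = agent.partner_prediction()
                nll -= _safe_log(pred[INVESTOR_ACTIONS.index(a_I)])
        agent.observe_round(a_I, a_T)
    return float(nll)


@dataclass
class FitResult:
    """Best-fitting grid point with its NLL, Draper BIC and tie diagnostics."""

    subject_id: str
    timepoint: str
    model: str
    params: AgentParams | None
    nll: float
    n_params: int
    bic: float
    n_ties: int
    grid_searched: int

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id, "timepoint": self.timepoint,
               "model": self.model}
        if self.params is not None:
            row.update(self.params.as_dict())
        else:
            row.update({k: np.nan for k in _PARAM_ORDER})
        row.update({"nll": self.nll, "p": self.n_params, "bic": self.bic,
                    "n_ties": self.n_ties, "grid_size": self.grid_searched})
        return row


#: ties in NLL closer than this are counted and broken lexicographically
TIE_TOL = 1e-9


def fit_subject(traj: GameTrajectory, spec: ModelSpec = M1,
                grid: dict | None = None, scope: str = "both_players",
                clear_caches: bool = True) -> FitResult:
    """Exhaustive grid search; argmin NLL with fixed lexicographic tie-break."""
    if grid is None:
        grid = reduced_grid()
    if clear_caches:
        agents.clear_caches()
    if spec.random_policy:
        nll = random_model_nll(traj, scope)
        return FitResult(traj.subject_id, traj.timepoint, spec.name, None,
                         nll, 0, draper_bic(nll, 0), 1, 1)
    points = list(grid_points(grid, spec))
    nlls = np.array([trajectory_nll(p, traj, spec, scope) for p in points])
    if not np.any(np.isfinite(nlls)):
        logger.warning("subject %s/%s unfittable under %s (all NLL infinite)",
                       traj.subject_id, traj.timepoint, spec.name)
        return FitResult(traj.subject_id, traj.timepoint, spec.name, None,
                         math.inf, spec.n_free, math.inf, 0, len(points))
    best_idx = int(np.argmin(nlls))  # argmin returns the first (lexicographic) min
    best = nlls[best_idx]
    n_ties = int(np.sum(nlls <= best + TIE_TOL))
    return FitResult(traj.subject_id, traj.timepoint, spec.name,
                     points[best_idx], float(best), spec.n_free,
                     draper_bic(float(best), spec.n_free), n_ties, len(points))


def fit_cohort(trajs, spec: ModelSpec = M1, grid: dict | None = None,
               scope: str = "both_players") -> pd.DataFrame:
    """Fit one spec to every trajectory; one row per subject-session."""
    rows = []
    for traj in trajs:
        agents.clear_caches()
        rows.append(fit_subject(traj, spec, grid, scope,
                                clear_caches=False).as_row())
    return pd.DataFrame(rows)


def compare_models(trajs, specs=DEFAULT_SPECS, grid: dict | None = None,
                   scope: str = "both_players") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every spec to every trajectory and rank models by average BIC.

    Returns (summary, per_subject): the summary has one row per model with
    mean NLL, mean BIC and rank (lower BIC wins); per_subject holds every
    individual fit.  Unfittable subjects are excluded with a log warning.
    """
    per_rows = []
    for traj in trajs:
        agents.clear_caches()  # states are trajectory-specific; share across specs
        for spec in specs:
            per_rows.append(fit_subject(traj, spec, grid, scope,
                                        clear_caches=False).as_row())
    per_subject = pd.DataFrame(per_rows)
    ok = per_subject[np.isfinite(per_subject["nll"])]
    dropped = per_subject[~np.isfinite(per_subject["nll"])]
    for _, row in dropped.iterrows():
        logger.warning("excluding unfittable subject %s/%s from %s average",
                       row["subject_id"], row["timepoint"], row["model"])
    summary = (ok.groupby("model")
                 .agg(mean_nll=("nll", "mean"), mean_bic=("bic", "mean"),
                      n_subjects=("bic", "size"))
                 .reset_index())
    summary["rank"] = summary["mean_bic"].rank(method="min").astype(int)
    return summary.sort_values("mean_bic").reset_index(drop=True), per_subject


def _safe_log(p: float) -> float:
    return math.log(p) if p > 0 else -math.inf


def _check_scope(scope: str) -> None:
    if scope not in ("both_players", "investor_only"):
        raise ValueError("scope must be 'both_players' or 'investor_only'")
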