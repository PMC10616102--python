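"""Model-free behavioural indices of a trust-game trajectory.

a-priori trust (round-1 investment), mean trust, reciprocity (tit-for-tat
slope), a retaliation marker (mean post-unfairness investment change) and
total winnings.  Reciprocity and the retaliation marker admit alternative
operationalizations; the chosen formula is echoed into output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .game import GameTrajectory, total_payoff_investor


@dataclass(frozen=True)
class MetricsConfig:
    """Formula variants for the SI-style indices."""

    #: "delta_fraction" regresses investment changes on the previous change in
    #: repayment fraction; "delta_repayment" uses the raw repayment change.
    reciprocity_variant: str = "delta_fraction"
    #: a repayment fraction strictly below this is an unfair trustee action
    #: (1/3 = the trustee returns less than was invested)
    fairness_threshold: float = 1 / 3

    def __post_init__(self) -> None:
        if self.reciprocity_variant not in ("delta_fraction", "delta_repayment"):
            raise ValueError("unknown reciprocity variant "
                             f"{self.reciprocity_variant!r}")


DEFAULT_METRICS = MetricsConfig()


def a_priori_trust(traj: GameTrajectory) -> float:
    """Round-1 (unconditional) investment in coins."""
    if not traj.rounds:
        raise ValueError("empty trajectory")
    return float(traj.rounds[0].a_I)


def mean_trust(traj: GameTrajectory) -> float:
    """Arithmetic mean investment over the game."""
    return float(np.mean(traj.investments))


def reciprocity(traj: GameTrajectory,
                config: MetricsConfig = DEFAULT_METRICS) -> float:
    """OLS slope of investment change on the previous change in repayment.

    Repayment is expressed as the fraction of the tripled investment
    (default variant); rounds with a zero investment have no defined
    fraction and are skipped.  Returns NaN when the predictor has no
    variance or fewer than two usable pairs exist.
    """
    inv = traj.investments
    fr = [float(f) if f is not None else np.nan for f in traj.fractions]
    rep = traj.repayments
    x, y = [], []
    for t in range(2, len(inv)):
        if config.reciprocity_variant == "delta_fraction":
            if math.isnan(fr[t - 1]) or math.isnan(fr[t - 2]):
                continue
            dx = fr[t - 1] - fr[t - 2]
        else:
            dx = rep[t - 1] - rep[t - 2]
        x.append(dx)
        y.append(inv[t] - inv[t - 1])
    if len(x) < 2 or np.var(x) == 0:
        return float("nan")
    return float(stats.linregress(x, y).slope)


def retaliation_index(traj: GameTrajectory,
                      config: MetricsConfig = DEFAULT_METRICS) -> float:
    """Mean next-round investment change after an unfair trustee action.

    An unfair action is a repayment fraction strictly below the fairness
    threshold on a round with a positive investment.  Negative values
    indicate retaliation; NaN when no qualifying event occurred.
    """
    inv = traj.investments
    changes = []
    for t, rnd in enumerate(traj.rounds[:-1]):
        f = rnd.fraction
        if f is not None and float(f) < config.fairness_threshold:
            changes.append(inv[t + 1] - inv[t])
    if not changes:
        return float("nan")
    return float(np.mean(changes))


def total_winnings(traj: GameTrajectory) -> float:
    """Sum of the investor's round payoffs (independent 20-coin endowments)."""
    return total_payoff_investor(traj)


def trust_indices(traj: GameTrajectory,
                  config: MetricsConfig = DEFAULT_METRICS) -> dict:
    return {
        "a_priori_trust": a_priori_trust(traj),
        "mean_trust": mean_trust(traj),
        "reciprocity": reciprocity(traj, config),
        "retaliation_index": retaliation_index(traj, config),
        "total_winnings": total_winnings(traj),
    }


def metrics_table(trajs, config: MetricsConfig = DEFAULT_METRICS
                  ) -> tuple[pd.DataFrame, dict]:
    """Per-session indices plus a metadata record of the formulas used."""
    rows = []
    for traj in trajs:
        row = {"subject_id": traj.subject_id, "timepoint": traj.timepoint}
        row.update(trust_indices(traj, config))
        rows.append(row)
    meta = {"formulas": asdict(config),
            "reciprocity": "OLS slope of d(investment)_t on d(predictor)_{t-1}",
            "retaliation": "mean investment change after repayment fraction "
                           f"< {config.fairness_threshold:.4g}"}
    return pd.DataFrame(rows), meta
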