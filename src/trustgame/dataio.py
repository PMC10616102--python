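"""Reading and writing the package's delimited-text schemas.

Trial-level CSV: subject_id, timepoint, round, investment_raw,
investment_bin, repayment (UTF-8, header required).  Raw investments are
binned on ingestion; repayments are stored exactly (multiples of 2.5
coins) so written-then-read trajectories round-trip bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .game import (GameTrajectory, Round, discretize_investment,
                   trustee_actions_coins)

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["subject_id", "timepoint", "round", "investment_raw",
                 "investment_bin", "repayment"]


def write_trials(trajs, path) -> Path:
    rows = []
    for traj in trajs:
        for rnd in traj.rounds:
            rows.append({"subject_id": traj.subject_id,
                         "timepoint": traj.timepoint,
                         "round": rnd.index,
                         "investment_raw": rnd.a_I,
                         "investment_bin": rnd.a_I,
                         "repayment": rnd.a_T})
    path = Path(path)
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)
    return path


def read_trials(path, n_rounds: int = 10
                ) -> tuple[list[GameTrajectory], pd.DataFrame]:
    """Load and validate trajectories; malformed sessions go to a report.

    Returns (trajectories, errors) where errors has one diagnostic row per
    rejected session or row.
    """
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - {"investment_bin"} - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    trajs: list[GameTrajectory] = []
    errors: list[dict] = []
    for (sid, tp), grp in df.groupby(["subject_id", "timepoint"], sort=True):
        grp = grp.sort_values("round")
        problems = []
        rounds = []
        for _, row in grp.iterrows():
            try:
                raw = row["investment_raw"]
                if float(raw) != int(raw):
                    raise ValueError(f"non-integer investment {raw!r}")
                a_I = discretize_investment(int(raw))
                a_T = float(row["repayment"])
                legal = trustee_actions_coins(a_I)
                if a_T not in legal:
                    raise ValueError(
                        f"repayment {a_T} illegal for investment bin {a_I}; "
                        f"legal set {legal}")
                rounds.append(Round(int(row["round"]), a_I, a_T))
            except (ValueError, TypeError) as exc:
                problems.append({"subject_id": sid, "timepoint": tp,
                                 "round": row.get("round"), "error": str(exc)})
        if not problems and len(rounds) != n_rounds:
            problems.append({"subject_id": sid, "timepoint": tp, "round": None,
                             "error": f"expected {n_rounds} rounds, "
                                      f"got {len(rounds)}"})
        if problems:
            errors.extend(problems)
            logger.warning("rejected session %s/%s (%d problem rows)",
                           sid, tp, len(problems))
            continue
        trajs.append(GameTrajectory(str(sid), str(tp), rounds,
                                    n_rounds=n_rounds))
    return trajs, pd.DataFrame(errors,
                               columns=["subject_id", "timepoint", "round",
                                        "error"])


def write_manifest(path, config: dict, seed: int, extra: dict | None = None
                   ) -> Path:
    from . import __version__
    manifest = {"package": "trustgame", "version": __version__,
                "seed": seed, "config": config}
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
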