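"""End-to-end analysis pipeline over a (synthetic or loaded) cohort.

Stages: generate-or-read trajectories -> behavioural metrics -> grid-search
fits -> model comparison -> age decomposition -> adversity factor ->
longitudinal mixed models.  Every stage writes a CSV; a manifest echoes
the resolved configuration so each run is regenerable from seed alone.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import agents, config as config_mod, dataio, inference, metrics
from .cohort import generate_cohort
from .config import RunConfig
from .inference import (DEFAULT_SPECS, full_grid, mini_grid, recovery_grid,
                        reduced_grid)
from .longitudinal import decompose_age, fit_longitudinal_model

logger = logging.getLogger(__name__)

_GRIDS = {"full": full_grid, "reduced": reduced_grid,
          "recovery": recovery_grid, "mini": mini_grid}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("trustgame")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings = {}
    try:
        cfg = cfg.resolved()
        grid = _GRIDS[cfg.grid]()

        t0 = time.perf_counter()
        table, trajs = generate_cohort(cfg.cohort)
        table.to_csv(out / "cohort.csv", index=False)
        dataio.write_trials(trajs, out / "trials.csv")
        timings["simulate"] = time.perf_counter() - t0
        logger.info("simulated %d sessions", len(trajs))

        t0 = time.perf_counter()
        metrics_df, meta = metrics.metrics_table(trajs, cfg.metrics)
        metrics_df.to_csv(out / "metrics.csv", index=False)
        timings["metrics"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        specs = [s for s in DEFAULT_SPECS if s.name in cfg.fit_models]
        summary, per_subject = inference.compare_models(
            trajs, specs, grid, cfg.likelihood_scope)
        per_subject.to_csv(out / "fits.csv", index=False)
        summary.to_csv(out / "model_comparison.csv", index=False)
        timings["fit"] = time.perf_counter() - t0
        logger.info("grid size (M1): %d; cache hit rate %.3f; sizes %s",
                    inference.grid_size(grid), agents.cache_hit_rate(),
                    agents.cache_sizes())

        t0 = time.perf_counter()
        cohort = table.merge(metrics_df, on=["subject_id", "timepoint"],
                             suffixes=("", "_metric"))
        cohort = decompose_age(cohort)
        cohort.to_csv(out / "cohort_decomposed.csv", index=False)

        lmm_rows = []
        if cohort["subject_id"].nunique() >= 8:
            dev = fit_longitudinal_model(
                cohort, "mean_trust",
                fixed=["longitudinal_age", "cross_sectional_age", "sex"],
                interactions=[("longitudinal_age", "cross_sectional_age")])
            dev.fixed_effects.insert(0, "outcome", "mean_trust")
            lmm_rows.append(dev.fixed_effects)
            adv = fit_longitudinal_model(
                cohort, "mean_trust",
                fixed=["longitudinal_age", "cross_sectional_age", "sex",
                       "adversity"],
                interactions=[("longitudinal_age", "cross_sectional_age"),
                              ("longitudinal_age", "adversity"),
                              ("cross_sectional_age", "adversity")])
            adv.fixed_effects.insert(0, "outcome", "mean_trust+adversity")
            lmm_rows.append(adv.fixed_effects)

            cfq = cohort[cohort["timepoint"] == "T1"]
            cfq_long = cfq.melt(
                id_vars=["subject_id", "age", "sex", "adversity",
                         "a_priori_trust"],
                value_vars=["cfq_wave1", "cfq_wave2", "cfq_wave3"],
                var_name="wave", value_name="cfq")
            cfq_long["wave_idx"] = cfq_long["wave"].str[-1].astype(float) - 2.0
            cfq_model = fit_longitudinal_model(
                cfq_long, "cfq",
                fixed=["wave_idx", "a_priori_trust", "adversity", "sex"],
                interactions=[("wave_idx", "a_priori_trust"),
                              ("wave_idx", "a_priori_trust", "adversity")])
            cfq_model.fixed_effects.insert(0, "outcome", "cfq")
            lmm_rows.append(cfq_model.fixed_effects)
        if lmm_rows:
            pd.concat(lmm_rows).to_csv(out / "longitudinal_models.csv",
                                       index=False)
        timings["longitudinal"] = time.perf_counter() - t0

        dataio.write_manifest(out / "manifest.json", config_mod.to_dict(cfg),
                              cfg.seed, extra={"timings_s": timings,
                                               "metrics_meta": meta})
        logger.info("stage timings: %s", timings)
    except Exception as exc:  # preserve partial outputs, name the stage
        done = set(timings)
        stage = {0: "simulate", 1: "metrics", 2: "fit",
                 3: "longitudinal"}.get(len(done), "unknown")
        logger.error("pipeline failed during stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
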