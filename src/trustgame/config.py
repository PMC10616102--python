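"""Run configuration: serializable settings for the full pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import CohortConfig, TrusteeConfig, default_trustee_params
from .agents import AgentParams
from .metrics import MetricsConfig


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run from seed alone."""

    seed: int = 0
    output_dir: str = "results/run"
    grid: str = "reduced"            # "full" | "reduced" | "recovery"
    likelihood_scope: str = "both_players"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    fit_models: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5")

    def resolved(self) -> "RunConfig":
        out = RunConfig(**{**asdict_shallow(self)})
        out.cohort.seed = self.seed
        return out


def asdict_shallow(cfg: RunConfig) -> dict:
    return {f.name: getattr(cfg, f.name) for f in fields(cfg)}


def to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["cohort"]["trustee"]["params"] = asdict(cfg.cohort.trustee.params)
    return d


def save_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(to_dict(cfg), sort_keys=False))
    return path


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    cohort_raw = dict(raw.pop("cohort", {}) or {})
    trustee_raw = dict(cohort_raw.pop("trustee", {}) or {})
    params_raw = trustee_raw.pop("params", None)
    params = AgentParams(**params_raw) if params_raw else default_trustee_params()
    if trustee_raw.get("schedule") is not None:
        trustee_raw["schedule"] = [float(x) for x in trustee_raw["schedule"]]
    trustee = TrusteeConfig(params=params, **trustee_raw)
    for key in ("age_range", "interval_range", "zeta_base_weights",
                "alpha_probs", "tom_values", "tom_probs", "plan_values",
                "plan_probs", "beta_values", "awareness_values"):
        if key in cohort_raw and cohort_raw[key] is not None:
            cohort_raw[key] = tuple(cohort_raw[key])
    cohort = CohortConfig(trustee=trustee, **cohort_raw)
    metrics_raw = dict(raw.pop("metrics", {}) or {})
    metrics = MetricsConfig(**metrics_raw)
    if "fit_models" in raw and raw["fit_models"] is not None:
        raw["fit_models"] = tuple(raw["fit_models"])
    return RunConfig(cohort=cohort, metrics=metrics, **raw)
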