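import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trustgame import agents
from trustgame.agents import AgentParams
from trustgame.cohort import (CohortConfig, TrusteeConfig, generate_cohort,
                              recovery_experiment, sample_trustee_schedule,
                              simulate_game, simulate_lmm_cohort)
from trustgame.dataio import write_trials


def cheap_cfg(**kw):
    base = dict(n_subjects=40, seed=7, tom_values=(0,), tom_probs=(1.0,),
                plan_values=(1,), plan_probs=(1.0,), beta_values=(1.0,),
                awareness_values=(2,))
    base.update(kw)
    return CohortConfig(**base)


def test_identical_seeds_identical_cohorts(tmp_path, cheap_cohort):
    table, trajs = cheap_cohort
    table2, trajs2 = generate_cohort(cheap_cfg())
    assert table.equals(table2)
    p1 = write_trials(trajs, tmp_path / "a.csv")
    p2 = write_trials(trajs2, tmp_path / "b.csv")
    assert p1.read_bytes() == p2.read_bytes()


def test_empty_cohort_schema_valid():
    table, trajs = generate_cohort(cheap_cfg(n_subjects=0))
    assert len(table) == 0 and trajs == []
    assert "cfq_wave3" in table.columns and "true_omega" in table.columns


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(interval_sd=-1.0)
    with pytest.raises(ValueError):
        CohortConfig(n_subjects=-1)
    with pytest.raises(ValueError):
        CohortConfig(age_range=(24.0, 14.0))


def test_negative_age_omega_link(cheap_cohort):
    table, _ = cheap_cohort
    rho = stats.spearmanr(table["age"], table["true_omega"]).statistic
    assert rho < 0


def test_zero_effect_config_gives_null_age_link():
    cfg = cheap_cfg(n_subjects=60, seed=11, omega_cross_slope=0.0,
                    omega_long_slope=0.0)
    table, _ = generate_cohort(cfg)
    res = stats.spearmanr(table["age"], table["true_omega"])
    assert abs(res.statistic) < 0.25


def test_zeta_increases_over_adversity_quartiles():
    table, _ = generate_cohort(cheap_cfg(n_subjects=80, seed=13))
    subj = table.drop_duplicates("subject_id").copy()
    subj["quart"] = pd.qcut(subj["adversity"], 4, labels=False)
    means = subj.groupby("quart")["true_zeta"].mean()
    assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


def test_cfq_generator_conditional_means():
    """OLS on the generator's own design recovers the injected slopes."""
    import statsmodels.formula.api as smf
    cfg = cheap_cfg(n_subjects=150, seed=5)
    table, _ = generate_cohort(cfg)
    s = table.drop_duplicates("subject_id")
    rows = []
    for w in (1, 2, 3):
        d = s[["adversity", "a_priori_trust"]].copy()
        d["wave"] = w - 2.0
        d["cfq"] = s[f"cfq_wave{w}"].values
        rows.append(d)
    lng = pd.concat(rows)
    lng["t1"] = lng["a_priori_trust"] - 10.0
    fit = smf.ols("cfq ~ wave + t1 + adversity + t1:wave + t1:wave:adversity",
                  lng).fit()
    assert fit.params["wave"] == pytest.approx(cfg.cfq_wave_slope, abs=0.4)
    assert fit.params["adversity"] == pytest.approx(cfg.cfq_adversity_slope,
                                                    abs=0.8)
    assert fit.params["t1"] == pytest.approx(cfg.cfq_trust_slope, abs=0.25)


def test_replay_zero_schedule_forces_zero_repayments():
    params = AgentParams("investor", 0.0, 0.4, 0, 1, 0.0, 0, 1.0)
    traj = simulate_game(params, [0.0] * 10, 3)
    assert all(r == 0.0 for r in traj.repayments)


def test_averse_trustee_agent_prefers_equal_split():
    """An alpha=1 trustee facing large investments mostly repays half."""
    agents.clear_caches()
    investor = AgentParams("investor", 0.0, 0.4, 0, 1, 0.0, 0, 1.0)
    trustee = AgentParams("trustee", 1.0, 1.0, 1, 1, 0.0, 0, 1.0)
    rng = np.random.default_rng(2)
    fracs = []
    for _ in range(3):
        traj = simulate_game(investor, trustee, rng)
        fracs += [float(f) for f, a in zip(traj.fractions, traj.investments)
                  if a == 20 and f is not None]
    modal = pd.Series(fracs).mode()[0]
    assert modal == pytest.approx(0.5)


def test_recovery_report_shape():
    grid = {"alpha": (0.0,), "omega": (0.4, 0.8), "tom": (0,), "plan": (1,),
            "zeta": (0.0, 0.5), "awareness": (2,), "beta": (1.0,)}
    from trustgame.inference import M1, M5
    rep = recovery_experiment(4, grid=grid, specs=(M1, M5), seed=1)
    assert len(rep["fits"]) == rep["n_agents"] * rep["n_models"] == 8
    assert rep["grid_size"] == 4
    assert "omega_confusion" in rep
    assert rep["omega_confusion"].values.sum() == 4


def test_low_stochasticity_agents_recover_at_least_as_well():
    grid_lo = {"alpha": (0.0,), "omega": (0.4, 0.8, 1.2), "tom": (0,),
               "plan": (1,), "zeta": (0.0,), "awareness": (2,),
               "beta": (0.25,)}
    grid_hi = dict(grid_lo, beta=(1.0,))
    r_lo = recovery_experiment(12, grid=grid_lo, seed=3)
    r_hi = recovery_experiment(12, grid=grid_hi, seed=3)
    assert r_hi["omega_exact"] >= r_lo["omega_exact"]


def test_schedule_sampler_legal():
    rng = np.random.default_rng(0)
    sched = sample_trustee_schedule(rng)
    assert len(sched) == 10
    assert set(sched) <= {0.0, 1 / 6, 1 / 3, 1 / 2, 2 / 3}


def test_lmm_cohort_known_structure():
    df = simulate_lmm_cohort(300, rng=9, long_age_slope=1.0, noise_sd=0.5,
                             subject_sd=0.5)
    piv = df.pivot(index="subject_id", columns="timepoint", values="outcome")
    ages = df.pivot(index="subject_id", columns="timepoint", values="age")
    slope = ((piv["T2"] - piv["T1"]) / (ages["T2"] - ages["T1"])).mean()
    assert slope == pytest.approx(1.0, abs=0.15)
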