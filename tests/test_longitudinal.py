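import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from trustgame.cohort import simulate_lmm_cohort
from trustgame.longitudinal import (adversity_factor, decompose_age,
                                    fit_longitudinal_model)


def small_table():
    return pd.DataFrame({
        "subject_id": ["a", "a", "b", "b", "c"],
        "age": [14.0, 15.5, 22.0, 24.0, 20.0],
    })


def test_decompose_age_formulas():
    out = decompose_age(small_table())
    # subject a: mean 14.75; sample mean of subject means (14.75+23+20)/3
    sample_mean = (14.75 + 23.0 + 20.0) / 3
    a = out[out.subject_id == "a"]
    assert a["cross_sectional_age"].iloc[0] == pytest.approx(14.75 - sample_mean)
    assert list(a["longitudinal_age"]) == pytest.approx([-0.75, 0.75])
    # single-visit subject: longitudinal age 0
    assert out[out.subject_id == "c"]["longitudinal_age"].iloc[0] == 0.0
    # per-subject longitudinal ages sum to zero
    sums = out.groupby("subject_id")["longitudinal_age"].sum()
    assert np.allclose(sums, 0.0)


def test_decompose_age_translation_invariance():
    base = decompose_age(small_table())
    shifted = small_table()
    shifted["age"] += 3.0
    out = decompose_age(shifted)
    for col in ("cross_sectional_age", "longitudinal_age"):
        assert np.allclose(out[col], base[col])


@given(st.lists(st.tuples(st.integers(0, 19),
                          st.floats(min_value=14, max_value=26)),
                min_size=4, max_size=40))
def test_decompose_age_reconstruction_identity(items):
    df = pd.DataFrame({"subject_id": [f"s{i}" for i, _ in items],
                       "age": [a for _, a in items]})
    out = decompose_age(df)
    sample_mean = out.groupby("subject_id")["age"].mean().mean()
    recon = sample_mean + out["cross_sectional_age"] + out["longitudinal_age"]
    assert np.allclose(recon, out["age"], atol=1e-10)


def test_decompose_age_rejects_nonpositive():
    df = small_table()
    df.loc[0, "age"] = -1.0
    with pytest.raises(ValueError):
        decompose_age(df)


# ----------------------------------------------------------------------- PCA

def test_adversity_factor_perfectly_correlated_columns():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    df = pd.DataFrame({"mops_abuse": x, "apq_inconsistent": 3 * x + 5})
    fac = adversity_factor(df)
    assert fac.explained_variance_share == pytest.approx(1.0)
    assert abs(fac.loadings["mops_abuse"]) == pytest.approx(
        abs(fac.loadings["apq_inconsistent"]))
    assert fac.loadings["mops_abuse"] > 0  # oriented toward adversity


def test_adversity_factor_orthogonal_share():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(3000, 2)), columns=["neg1", "neg2"])
    fac = adversity_factor(df)
    assert fac.explained_variance_share == pytest.approx(0.5, abs=0.05)


def test_adversity_factor_orientation_and_affine_invariance():
    rng = np.random.default_rng(2)
    latent = rng.normal(size=300)
    df = pd.DataFrame({
        "mops_abuse": latent + 0.3 * rng.normal(size=300),
        "mops_overcontrol": latent + 0.3 * rng.normal(size=300),
        "apq_positive": -latent + 0.3 * rng.normal(size=300),
    })
    fac = adversity_factor(df, positive_subscales=("apq_positive",))
    assert fac.loadings["mops_abuse"] > 0
    assert fac.loadings["apq_positive"] < 0
    assert np.corrcoef(fac.scores, latent)[0, 1] > 0.9
    # affine rescaling of inputs leaves scores unchanged
    df2 = df.copy()
    df2["mops_abuse"] = 10 * df2["mops_abuse"] - 7
    fac2 = adversity_factor(df2, positive_subscales=("apq_positive",))
    assert np.allclose(fac2.scores, fac.scores, atol=1e-8)
    # global sign flip leaves |scores| unchanged
    fac3 = adversity_factor(-df, positive_subscales=("apq_positive",))
    assert np.allclose(np.abs(fac3.scores), np.abs(fac.scores), atol=1e-8)


def test_adversity_factor_rejects_constant_column():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
    with pytest.raises(ValueError, match="flat"):
        adversity_factor(df)


# -------------------------------------------------------------- mixed models

def test_lmm_recovers_injected_slope():
    df = simulate_lmm_cohort(400, rng=5, long_age_slope=0.27,
                             cross_age_slope=0.2)
    df = decompose_age(df)
    out = fit_longitudinal_model(
        df, "outcome",
        fixed=["longitudinal_age", "cross_sectional_age", "sex"],
        interactions=[("longitudinal_age", "cross_sectional_age")])
    fe = out.fixed_effects.set_index("term")
    row = fe.loc["longitudinal_age"]
    assert row["ci_low"] <= 0.27 <= row["ci_high"]
    assert fe.loc["cross_sectional_age"]["estimate"] == pytest.approx(0.2,
                                                                      abs=0.15)
    assert out.converged
    assert out.random_effects["group_var"] > 0


def test_lmm_null_interaction_centred_on_zero():
    df = simulate_lmm_cohort(400, rng=6, interaction=0.0)
    df = decompose_age(df)
    out = fit_longitudinal_model(
        df, "outcome",
        fixed=["longitudinal_age", "cross_sectional_age", "sex"],
        interactions=[("longitudinal_age", "cross_sectional_age")])
    fe = out.fixed_effects.set_index("term")
    inter = fe.loc["longitudinal_age:cross_sectional_age"]
    assert inter["ci_low"] <= 0.0 <= inter["ci_high"]


def test_lmm_rejects_singular_design():
    df = simulate_lmm_cohort(50, rng=7)
    df = decompose_age(df)
    df["age_copy"] = df["longitudinal_age"]
    with pytest.raises(ValueError, match="collinear"):
        fit_longitudinal_model(df, "outcome",
                               fixed=["longitudinal_age", "age_copy", "sex"])


def test_lmm_rejects_missing_columns():
    df = simulate_lmm_cohort(20, rng=8)
    with pytest.raises(ValueError, match="missing"):
        fit_longitudinal_model(df, "outcome", fixed=["not_a_column"])


def test_lmm_random_slopes_flag():
    df = simulate_lmm_cohort(150, rng=9)
    df = decompose_age(df)
    out = fit_longitudinal_model(df, "outcome", fixed=["longitudinal_age"],
                                 random_slopes=["longitudinal_age"])
    assert "longitudinal_age" in list(out.fixed_effects["term"])
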