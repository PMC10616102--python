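"""Longitudinal statistical stages.

Three pieces used by the cohort analyses:

* within/between-person age decomposition - each visit age is split
  into a cross-sectional component (participant mean age, centred on the
  sample) and a longitudinal component (visit age, centred on the
  participant), so within-person change can be separated from
  between-person age differences;
* a family-adversity factor - the first principal component of
  standard-normalized questionnaire subscale totals, oriented so that
  higher scores mean higher adversity;
* linear mixed models with subject random intercepts (random slopes
  behind a flag), fitted by REML through statsmodels, with centred
  continuous predictors and effect-coded categorical contrasts.

Degrees of freedom for the fixed-effect t tests use the residual
approximation (observations minus fixed-effect parameters); estimator
quality is validated by coverage/recovery simulations rather than by
matching any particular df recipe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


def decompose_age(cohort: pd.DataFrame, age_col: str = "age",
                  subject_col: str = "subject_id") -> pd.DataFrame:
    """Add cross-sectional and longitudinal age columns.

    cross_sectional_age_i = mean(age_i) - mean over subjects of mean(age_i);
    longitudinal_age_ij   = age_ij - mean(age_i).
    Subjects with missing ages are dropped with a warning.
    """
    out = cohort.copy()
    missing = out[out[age_col].isna()][subject_col].unique()
    if len(missing):
        logger.warning("dropping subjects with missing ages: %s", list(missing))
        out = out[~out[subject_col].isin(missing)]
    if (out[age_col] <= 0).any():
        raise ValueError("ages must be positive")
    subj_mean = out.groupby(subject_col)[age_col].transform("mean")
    sample_mean = out.groupby(subject_col)[age_col].mean().mean()
    out["cross_sectional_age"] = subj_mean - sample_mean
    out["longitudinal_age"] = out[age_col] - subj_mean
    return out


@dataclass
class AdversityFactor:
    """First-PC scores of standardized subscales, oriented to adversity."""

    scores: pd.Series
    loadings: pd.Series
    explained_variance_share: float


def adversity_factor(subscales: pd.DataFrame,
                     positive_subscales: tuple[str, ...] = ()
                     ) -> AdversityFactor:
    """First principal component of standard-normalized subscale totals.

    Columns named in ``positive_subscales`` measure positive parenting;
    the component is sign-oriented so that the mean loading of the
    remaining (negative-experience) subscales is positive, i.e. higher
    scores denote greater self-reported family adversity.
    """
    if subscales.shape[1] < 2:
        raise ValueError("need at least two subscales")
    if subscales.shape[0] < 3:
        raise ValueError("need at least three subjects")
    sd = subscales.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant subscale column(s): {constant}")
    z = (subscales - subscales.mean()) / sd
    pca = PCA(n_components=1)
    scores = pca.fit_transform(z.values)[:, 0]
    loadings = pca.components_[0]
    negative_cols = [c for c in subscales.columns if c not in positive_subscales]
    orient = np.mean([loadings[subscales.columns.get_loc(c)]
                      for c in negative_cols])
    if orient < 0:
        scores, loadings = -scores, -loadings
    return AdversityFactor(
        scores=pd.Series(scores, index=subscales.index, name="adversity"),
        loadings=pd.Series(loadings, index=subscales.columns, name="loading"),
        explained_variance_share=float(pca.explained_variance_ratio_[0]))


@dataclass
class ModelOutput:
    """Fixed-effect table, variance components and the fitted model."""

    fixed_effects: pd.DataFrame  # term, estimate, se, stat, df, pvalue, ci
    random_effects: dict
    formula: str
    n_obs: int
    converged: bool
    model: object


def _build_formula(outcome: str, fixed: list[str],
                   interactions: list[str]) -> str:
    terms = list(fixed) + [":".join(t) if isinstance(t, (list, tuple)) else t
                           for t in interactions]
    return f"{outcome} ~ " + " + ".join(terms) if terms else f"{outcome} ~ 1"


def fit_longitudinal_model(table: pd.DataFrame, outcome: str,
                           fixed: list[str],
                           interactions: list | None = None,
                           groups: str = "subject_id",
                           random_slopes: list[str] | None = None,
                           center: bool = True,
                           reml: bool = True) -> ModelOutput:
    """Linear mixed model with subject random intercepts.

    ``fixed`` lists main-effect columns; ``interactions`` lists tuples of
    columns whose products enter as interaction terms.  Continuous
    predictors are centred on zero; categorical columns must already be
    effect-coded numerics (e.g. sex in {-0.5, +0.5}).  Random slopes can
    be requested via ``random_slopes``.
    """
    interactions = interactions or []
    df = table.copy()
    needed = {outcome, groups} | set(fixed)
    for t in interactions:
        needed |= set(t) if isinstance(t, (list, tuple)) else {t}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = df.dropna(subset=sorted(needed))
    if center:
        for col in set(fixed) | {c for t in interactions
                                 for c in (t if isinstance(t, (list, tuple)) else (t,))}:
            if df[col].nunique() > 2:  # leave effect-coded binaries alone
                df[col] = df[col] - df[col].mean()
    formula = _build_formula(outcome, fixed, interactions)

    # explicit singularity check with a named listing of collinear columns
    import patsy
    _, X = patsy.dmatrices(formula, df, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = X.loc[:, X.std() > 0].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [(a, b) for a in corr.index for b in corr.columns
                 if a < b and corr.loc[a, b] > 0.999]
        raise ValueError(f"singular design matrix; collinear columns: {pairs}")

    re_formula = None
    if random_slopes:
        re_formula = "~" + " + ".join(random_slopes)
    model = smf.mixedlm(formula, df, groups=df[groups], re_formula=re_formula)
    fit = None
    last_err: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):  # robustness fallbacks
        try:
            fit = model.fit(reml=reml, method=method, maxiter=500)
            break
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_err = exc
    if fit is None:
        raise RuntimeError(f"mixed model failed to fit: {last_err}")

    fe_names = fit.fe_params.index
    df_resid = max(len(df) - len(fe_names), 1)
    est = fit.fe_params
    se = fit.bse.loc[fe_names]
    tstat = est / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df_resid)
    crit = stats.t.ppf(0.975, df_resid)
    fixed_df = pd.DataFrame({
        "term": fe_names, "estimate": est.values, "se": se.values,
        "stat": tstat.values, "df": df_resid, "pvalue": pvals,
        "ci_low": est.values - crit * se.values,
        "ci_high": est.values + crit * se.values,
    }).reset_index(drop=True)
    random_effects = {"group_var": float(np.asarray(fit.cov_re)[0, 0]),
                      "residual_var": float(fit.scale)}
    return ModelOutput(fixed_df, random_effects, formula, len(df),
                       bool(fit.converged), fit)
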