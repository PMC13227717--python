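"""Country-wise survey-weighted regressions of outcomes on one exposure.

Continuous outcomes use weighted linear regression; binary outcomes use
modified Poisson regression (Poisson estimating equations with a log link
on a 0/1 outcome), which targets risk ratios directly.  Both take their
variance from the design-based linearization estimator — never the naive
model-based variance.  Effects are standardized with weighted SDs so they
can be pooled across countries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import columns as C
from .design import SurveyDesign, design_covariance, weighted_sd
from .impute import ImputationSet, rubin_pool
from .pca import pc_decompose, pc_scores, select_components

logger = logging.getLogger(__name__)

EXPOSURE_SCHEMES = ("NR_vs_OA", "N_vs_ROA", "NRO_vs_A", "continuous")

_CATEGORY_CODES = {"never": 1, "rarely": 2, "often": 3, "always": 4}


@dataclass
class ModelSpec:
    """One (outcome, model) regression contract for a single country."""

    model_id: str                      # "M1" or "M2"
    outcome: str
    outcome_type: str                  # "continuous" or "binary"
    exposure: str = C.EXPOSURE_ITEM
    scheme: str = "NR_vs_OA"
    covariates: list[str] = field(default_factory=lambda:
                                  list(C.MODEL1_COVARIATES))
    n_pcs: int = 7                     # used when model_id == "M2"


@dataclass
class CountryFit:
    country: str
    outcome: str
    model_id: str
    b: float                            # log-RR scale for binary outcomes
    v: float                            # design-based variance of b
    sd_x: float
    sd_y: float | None
    n: int
    converged: bool


def recode_exposure(values, scheme: str = "NR_vs_OA") -> np.ndarray:
    """Recode the four-category exposure item under one coding scheme.

    Binary schemes return 0/1 (1 = the 'exposed' collapse); ``continuous``
    returns the integer codes 1..4.  Accepts integer codes or the labels
    never/rarely/often/always.
    """
    if scheme not in EXPOSURE_SCHEMES:
        raise ValueError(f"unknown exposure scheme '{scheme}'")
    arr = pd.Series(values)
    if arr.dtype == object:
        unseen = set(arr.dropna().unique()) - set(_CATEGORY_CODES)
        if unseen:
            raise ValueError(f"unseen exposure categories: {sorted(unseen)}")
        codes = arr.map(_CATEGORY_CODES).to_numpy(float)
    else:
        codes = arr.to_numpy(float)
        bad = set(np.unique(codes[~np.isnan(codes)])) - {1.0, 2.0, 3.0, 4.0}
        if bad:
            raise ValueError(f"unseen exposure codes: {sorted(bad)}")
    if scheme == "continuous":
        return codes
    cut = {"NR_vs_OA": 3, "N_vs_ROA": 2, "NRO_vs_A": 4}[scheme]
    out = np.where(np.isnan(codes), np.nan, (codes >= cut).astype(float))
    return out


def _design_matrix(df, exposure_vals, covariates):
    cols = [np.ones(len(df)), exposure_vals]
    names = ["const", "exposure"]
    for c in covariates:
        x = df[c].to_numpy(float)
        if np.nanstd(x) == 0:
            logger.info("covariate %s constant; dropped", c)
            continue
        cols.append(x)
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return X, names


def _aliased_columns(X, names):
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10
    return [n for n, d in zip(names, diag) if d < tol]


def _fit_core(df, design, y, X, w, family):
    """Point estimates via GLM estimating equations; design-based variance.

    Returns (beta, cov, converged).  ``family`` is "gaussian" or "poisson".
    """
    if family == "gaussian":
        res = sm.WLS(y, X, weights=w).fit()
        beta = np.asarray(res.params, float)
        mu = X @ beta
        bread = np.linalg.inv(X.T @ (w[:, None] * X))
    else:
        glm = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
        try:
            res = glm.fit(maxiter=100, tol=1e-10)
        except Exception as err:
            logger.warning("modified Poisson failed to converge: %s", err)
            return None, None, False
        if not res.converged:
            return None, None, False
        beta = np.asarray(res.params, float)
        mu = np.exp(X @ beta)
        bread = np.linalg.inv(X.T @ ((w * mu)[:, None] * X))
    scores = (w * (y - mu))[:, None] * X
    cov = design_covariance(df, design, scores, bread)
    return beta, cov, True


def _fit(panel, spec: ModelSpec, design: SurveyDesign,
         weight_col: str = C.WEIGHT, pc_frame: pd.DataFrame | None = None,
         family: str | None = None) -> CountryFit:
    country = panel[C.COUNTRY].iloc[0]
    ycol = C.outcome_column(spec.outcome)
    if ycol not in panel.columns:
        return CountryFit(country, spec.outcome, spec.model_id,
                          np.nan, np.nan, np.nan, None, 0, False)
    exposure_vals = recode_exposure(panel[spec.exposure], spec.scheme)
    covariates = list(spec.covariates)
    df = panel.copy()
    if spec.model_id == "M2" and pc_frame is not None:
        for c in pc_frame.columns:
            df[c] = pc_frame[c]
        covariates += list(pc_frame.columns)

    use = (df[ycol].notna().to_numpy()
           & ~np.isnan(exposure_vals)
           & df[weight_col].notna().to_numpy())
    for c in covariates:
        use &= df[c].notna().to_numpy()
    df = df.loc[use]
    xv = exposure_vals[use]
    y = df[ycol].to_numpy(float)
    w = df[weight_col].to_numpy(float)

    X, _ = _design_matrix(df, xv, covariates)
    if family is None:
        family = "poisson" if spec.outcome_type == "binary" else "gaussian"
    beta, cov, converged = _fit_core(df, design, y, X, w, family)
    if not converged:
        return CountryFit(country, spec.outcome, spec.model_id,
                          np.nan, np.nan, np.nan, None, len(df), False)

    # sd_x := 1 for a 0/1 category contrast; weighted SD for the
    # approximately-continuous coding
    sd_x = weighted_sd(xv, w) if spec.scheme == "continuous" else 1.0
    sd_y = (weighted_sd(y, w) if spec.outcome_type == "continuous" else None)
    return CountryFit(country, spec.outcome, spec.model_id,
                      float(beta[1]), float(cov[1, 1]), float(sd_x),
                      sd_y, int(len(df)), True)


def fit_weighted_linear(panel, spec: ModelSpec,
                        design: SurveyDesign | None = None,
                        weight_col: str = C.WEIGHT,
                        pc_frame=None) -> CountryFit:
    """Survey-weighted linear regression for a continuous outcome."""
    if spec.outcome_type != "continuous":
        raise ValueError("fit_weighted_linear requires a continuous outcome")
    return _fit(panel, spec, design or SurveyDesign(), weight_col, pc_frame,
                family="gaussian")


def fit_modified_poisson(panel, spec: ModelSpec,
                         design: SurveyDesign | None = None,
                         weight_col: str = C.WEIGHT,
                         pc_frame=None) -> CountryFit:
    """Modified Poisson (log-link risk-ratio) regression for a 0/1 outcome.

    The returned coefficient is on the log-RR scale; its variance is the
    design-based sandwich, never the model-based Poisson variance.
    """
    if spec.outcome_type != "binary":
        raise ValueError("fit_modified_poisson requires a binary outcome")
    return _fit(panel, spec, design or SurveyDesign(), weight_col, pc_frame,
                family="poisson")


def standardize_effect(fit: CountryFit, exposure_type: str = "binary",
                       outcome_type: str = "continuous"):
    """Standardized effect and variance for cross-country pooling.

    Continuous outcome: b_std = b * sd_x / sd_y (variance scaled by the
    squared ratio).  Binary outcome: b_std = b * sd_x on the log-RR scale.
    A 0/1 exposure contrast carries sd_x = 1, so the effect is the change
    in outcome SDs (or log-RR) between the exposure categories.
    """
    del exposure_type  # the contrast convention lives in fit.sd_x
    if outcome_type == "continuous":
        if fit.sd_y is None or fit.sd_y == 0:
            raise ValueError("sd_y required (and nonzero) to standardize")
        ratio = fit.sd_x / fit.sd_y
    else:
        ratio = fit.sd_x
    return fit.b * ratio, fit.v * ratio**2


@dataclass
class AnalysisConfig:
    """Configuration of one outcome-wide run."""

    outcomes: list[tuple[str, str]]    # (name, "continuous"|"binary")
    scheme: str = "NR_vs_OA"
    models: tuple[str, ...] = ("M1", "M2")
    n_pcs: int = 7
    covariates: list[str] = field(default_factory=lambda:
                                  list(C.MODEL1_COVARIATES))
    weight_col: str = C.WEIGHT


def run_outcome_wide(
    imputations: ImputationSet | list[pd.DataFrame],
    config: AnalysisConfig,
    design: SurveyDesign | None = None,
) -> pd.DataFrame:
    """Fit every (country x outcome x model) cell on each imputed dataset,
    Rubin-pool coefficient and variance, and standardize.

    Returns one row per cell with pooled ``b``, ``v``, standardized
    ``b_std``, ``v_std``, the SDs used, n, and a convergence flag.
    Failures are emitted as rows with ``converged = False``; nothing is
    silently dropped.
    """
    design = design or SurveyDesign()
    panels = (imputations.panels if isinstance(imputations, ImputationSet)
              else list(imputations))
    m = len(panels)
    countries = list(dict.fromkeys(panels[0][C.COUNTRY]))
    conf_cols = [c for c in panels[0].columns
                 if c.startswith(C.CONFOUNDER_PREFIX)]

    cells: dict[tuple, list[CountryFit]] = {}
    for panel in panels:
        for country in countries:
            df = panel[panel[C.COUNTRY] == country]
            pc_frame = None
            if "M2" in config.models and conf_cols:
                decomp = pc_decompose(df[conf_cols], country=country)
                k = select_components(decomp, "fixed", k=config.n_pcs)
                pc_frame = pc_scores(df, decomp, k)
            for outcome, otype in config.outcomes:
                for model_id in config.models:
                    spec = ModelSpec(model_id, outcome, otype,
                                     scheme=config.scheme,
                                     covariates=list(config.covariates),
                                     n_pcs=config.n_pcs)
                    fit = _fit(df, spec, design, config.weight_col,
                               pc_frame if model_id == "M2" else None)
                    cells.setdefault((country, outcome, otype, model_id),
                                     []).append(fit)

    rows = []
    for (country, outcome, otype, model_id), fits in cells.items():
        good = [f for f in fits if f.converged]
        if not good:
            rows.append(dict(country=country, outcome=outcome,
                             outcome_type=otype, model=model_id,
                             b=np.nan, v=np.nan, b_std=np.nan, v_std=np.nan,
                             sd_x=np.nan, sd_y=np.nan, n=0,
                             converged=False, m=0))
            continue
        if len(good) < len(fits):
            logger.warning("%s/%s/%s: %d of %d imputations non-convergent",
                           country, outcome, model_id,
                           len(fits) - len(good), len(fits))
        if len(good) == 1:
            b, v = good[0].b, good[0].v
        else:
            pooled = rubin_pool([f.b for f in good], [f.v for f in good],
                                complete_data_df=good[0].n - 2)
            b, v = pooled.estimate, pooled.total
        sd_x = float(np.mean([f.sd_x for f in good]))
        sd_y = (float(np.mean([f.sd_y for f in good]))
                if otype == "continuous" else np.nan)
        ref = CountryFit(country, outcome, model_id, b, v, sd_x,
                         sd_y if otype == "continuous" else None,
                         good[0].n, True)
        b_std, v_std = standardize_effect(ref, outcome_type=otype)
        rows.append(dict(country=country, outcome=outcome,
                         outcome_type=otype, model=model_id, b=b, v=v,
                         b_std=b_std, v_std=v_std, sd_x=sd_x, sd_y=sd_y,
                         n=good[0].n, converged=True, m=len(good)))
    return pd.DataFrame(rows)
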