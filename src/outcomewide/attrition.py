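"""Stabilized inverse-probability-of-retention weights.

A per-country logistic regression predicts the probability that a
respondent was retained at Wave 2; retained respondents then receive the
stabilized weight pbar / phat_i, where pbar is the marginal retention
rate.  Multiplied by the sampling weight, these form the analysis weight
for the semi-complete-case sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import columns as C

logger = logging.getLogger(__name__)

#: predictors of retention (dropped with a notice when absent)
DEFAULT_RETENTION_PREDICTORS = [
    C.WEIGHT, "age", "gender", "education", "income_quintile", "employed",
    "married", "urban", "immigrant", "religious_attendance",
    "health_growing_up",
]


@dataclass
class RetentionModel:
    predictors: list[str]
    coefficients: np.ndarray  # intercept first
    fitted: np.ndarray        # phat_i in (0, 1), aligned with the panel
    marginal: float           # pbar


def fit_retention_model(
    panel: pd.DataFrame,
    retained: np.ndarray | pd.Series | None = None,
    predictors: list[str] | None = None,
) -> RetentionModel:
    """Maximum-likelihood logistic fit of retention on Wave-1 predictors."""
    r = (panel[C.RETAINED] if retained is None else retained)
    r = np.asarray(r, float)
    if predictors is None:
        predictors = DEFAULT_RETENTION_PREDICTORS
    usable = []
    for p in predictors:
        if p not in panel.columns:
            logger.info("retention predictor %s absent; dropped", p)
            continue
        if panel[p].std() == 0 or panel[p].isna().any():
            logger.info("retention predictor %s constant/incomplete; dropped", p)
            continue
        usable.append(p)

    X = sm.add_constant(panel[usable].to_numpy(float), has_constant="add")
    if r.min() == r.max():
        # degenerate: everyone (or no one) retained
        coefs = np.zeros(X.shape[1])
        coefs[0] = 30.0 if r.min() == 1.0 else -30.0
        fitted = np.full(len(r), float(r.min()))
        return RetentionModel(usable, coefs, np.clip(fitted, 1e-9, 1 - 1e-9),
                              float(r.mean()))
    try:
        res = sm.GLM(r, X, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as err:  # pragma: no cover - defensive
        raise RuntimeError(f"retention model failed: {err}") from err
    fitted = np.asarray(res.fittedvalues, float)
    if fitted.min() < 1e-8 or fitted.max() > 1 - 1e-8:
        offender = _separating_predictor(panel, usable, r)
        raise RuntimeError(
            "perfect (or quasi-perfect) separation in retention model"
            + (f"; offending predictor: {offender}" if offender else ""))
    return RetentionModel(usable, np.asarray(res.params, float),
                          fitted, float(r.mean()))


def _separating_predictor(panel, predictors, r):
    for p in predictors:
        x = panel[p].to_numpy(float)
        if len(np.unique(x)) > 10:
            continue
        rates = pd.Series(r).groupby(pd.Series(x)).mean()
        if ((rates == 0) | (rates == 1)).any():
            return p
    return None


def stabilized_weights(
    model: RetentionModel,
    retained: np.ndarray | pd.Series,
    floor: float = 0.01,
) -> np.ndarray:
    """Stabilized weights pbar / phat_i for retained cases; NaN otherwise.

    Fitted probabilities below ``floor`` are truncated (with a logged
    warning) so a handful of extreme cases cannot dominate small samples.
    """
    r = np.asarray(retained, bool)
    phat = np.asarray(model.fitted, float)
    n_low = int((phat[r] < floor).sum())
    if n_low:
        logger.warning("truncating %d retention probabilities below %.3g",
                       n_low, floor)
    phat = np.maximum(phat, floor)
    w = np.full(r.size, np.nan)
    w[r] = model.marginal / phat[r]
    return w


def attrition_weight_column(
    panel: pd.DataFrame,
    predictors: list[str] | None = None,
    floor: float = 0.01,
) -> pd.Series:
    """Per-country stabilized retention weights as a panel-aligned column."""
    out = pd.Series(np.nan, index=panel.index, name=C.ATTRITION_WEIGHT)
    for _, df in panel.groupby(C.COUNTRY, sort=False):
        model = fit_retention_model(df, predictors=predictors)
        out.loc[df.index] = stabilized_weights(
            model, df[C.RETAINED].to_numpy(bool), floor=floor)
    return out
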