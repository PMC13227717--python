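"""Complex sampling design: weighted descriptives and linearized variance.

The design is stratified single-stage cluster sampling: respondents carry
a sampling weight and belong to one primary sampling unit (PSU) nested in
one stratum.  Variance of estimating-equation estimators uses Taylor
linearization with the with-replacement approximation; strata containing
a single PSU ("lonely" PSUs) are treated as sampled with certainty and
contribute nothing to the variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import columns as C


@dataclass(frozen=True)
class SurveyDesign:
    """Names of the design columns plus the lonely-PSU policy."""

    weight: str = C.WEIGHT
    stratum: str = C.STRATUM
    psu: str = C.PSU
    lonely_psu_policy: str = "certainty"

    def validate(self, panel: pd.DataFrame) -> None:
        for col in (self.weight, self.stratum, self.psu):
            if col not in panel.columns:
                raise KeyError(f"design column '{col}' missing from panel")
        if (panel[self.weight] <= 0).any():
            raise ValueError("sampling weights must be strictly positive")
        nesting = panel.groupby(self.psu)[self.stratum].nunique()
        bad = nesting[nesting > 1]
        if len(bad):
            raise ValueError(f"PSUs in multiple strata: {list(bad.index[:5])}")
        if self.lonely_psu_policy != "certainty":
            raise ValueError(
                f"unsupported lonely-PSU policy '{self.lonely_psu_policy}'")


def weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    """Probability-weighted SD, sum(w (x - xbar)^2) / sum(w).

    No finite-population or n/(n-1) correction is applied; this is the SD
    used for effect standardization, and the convention is deliberate and
    documented (see the methods note).
    """
    m = weighted_mean(x, w)
    return float(np.sqrt(np.sum(w * (x - m) ** 2) / np.sum(w)))


def weighted_summary(
    design: SurveyDesign,
    panel: pd.DataFrame,
    variable: str,
    subset: pd.Series | np.ndarray | None = None,
) -> dict:
    """Weighted n, mean, SD and per-level proportions of one variable."""
    if variable not in panel.columns:
        raise KeyError(f"variable '{variable}' not in panel")
    df = panel if subset is None else panel.loc[np.asarray(subset, bool)]
    obs = df[variable].notna()
    if not obs.any():
        raise ValueError(f"variable '{variable}' has no observed values")
    x = df.loc[obs, variable].to_numpy(float)
    w = df.loc[obs, design.weight].to_numpy(float)
    if w.sum() <= 0:
        raise ValueError("total weight is zero")
    levels, inv = np.unique(x, return_inverse=True)
    props = np.bincount(inv, weights=w) / w.sum()
    return {
        "n": int(obs.sum()),
        "mean": weighted_mean(x, w),
        "sd": weighted_sd(x, w),
        "proportions": {float(v): float(p) for v, p in zip(levels, props)},
    }


def design_covariance(
    panel: pd.DataFrame,
    design: SurveyDesign,
    scores: np.ndarray,
    bread: np.ndarray,
) -> np.ndarray:
    """Linearization (sandwich) covariance of an estimating-equation fit.

    ``scores`` holds per-respondent weighted estimating-function values
    (n x p, rows aligned with ``panel``); ``bread`` is the inverse of the
    expected derivative of the estimating equations (p x p).  Within each
    stratum h with n_h PSUs, scores are summed to PSU totals t_hj and the
    "meat" accumulates (n_h / (n_h - 1)) * sum_j (t_hj - tbar_h)(..)'.
    Single-PSU strata contribute zero under the certainty policy.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[0] != len(panel):
        raise ValueError("scores rows must align with panel rows")
    p = scores.shape[1]
    bread = np.asarray(bread, float)
    if bread.shape != (p, p):
        raise ValueError(f"bread must be {p}x{p}, got {bread.shape}")

    strata = panel[design.stratum].to_numpy()
    psus = panel[design.psu].to_numpy()
    meat = np.zeros((p, p))
    for h in pd.unique(strata):
        in_h = strata == h
        psu_labels = pd.unique(psus[in_h])
        n_h = len(psu_labels)
        if n_h < 2:
            continue  # certainty: lonely PSU contributes no variance
        totals = np.vstack([
            scores[in_h & (psus == j)].sum(axis=0) for j in psu_labels
        ])
        centered = totals - totals.mean(axis=0)
        meat += (n_h / (n_h - 1)) * centered.T @ centered
    return bread @ meat @ bread


def combine_weights(
    sampling_weight: np.ndarray, attrition_weight: np.ndarray
) -> np.ndarray:
    """Analysis weight = sampling weight x attrition weight, elementwise."""
    sw = np.asarray(sampling_weight, float)
    aw = np.asarray(attrition_weight, float)
    if (sw <= 0).any() or (aw <= 0).any():
        raise ValueError("weights must be strictly positive")
    return sw * aw


def average_analysis_weight(
    sampling_weight: np.ndarray, attrition_weights: list[np.ndarray]
) -> np.ndarray:
    """Per-case average of the m analysis weights, for descriptive use."""
    stacked = np.vstack([
        combine_weights(sampling_weight, aw) for aw in attrition_weights
    ])
    return stacked.mean(axis=0)
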