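"""Sensitivity machinery: E-values (with confidence-limit E-values and an
observed-confounder calibration benchmark), reliability-attenuation
correction, and the R^2-based robustness value for linear models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import columns as C

#: standardized-difference to log-risk-ratio conversion constant
SMD_TO_LOG_RR = 0.91

_Z975 = 1.959963984540054


@dataclass
class EValueReport:
    scale: str                  # "risk-ratio" or "standardized-difference"
    point: float
    ci: float
    approximate: bool           # True when a scale conversion was used


@dataclass
class CalibrationBenchmark:
    benchmark: str
    rr_gy: float                # benchmark-outcome risk ratio
    rr_dg: float                # exposure-benchmark risk ratio
    dichotomization: str


def _evalue(rr: float) -> float:
    """E(RR) = RR + sqrt(RR (RR - 1)) for RR >= 1; inverted below 1."""
    if rr <= 0:
        raise ValueError("risk ratio must be positive")
    r = rr if rr >= 1.0 else 1.0 / rr
    return r + math.sqrt(r * (r - 1.0))


def evalue_from_rr(rr: float, ci_lo: float | None = None,
                   ci_hi: float | None = None) -> EValueReport:
    """Point and confidence-limit E-values from a risk ratio and its CI.

    The CI E-value uses the limit closest to the null and equals 1 when
    the interval spans RR = 1.
    """
    point = _evalue(rr)
    ci_e = float("nan")
    if ci_lo is not None and ci_hi is not None:
        if ci_lo > ci_hi:
            raise ValueError("invalid confidence interval")
        if ci_lo <= 1.0 <= ci_hi:
            ci_e = 1.0
        else:
            limit = ci_lo if rr >= 1.0 else ci_hi
            ci_e = _evalue(limit)
    return EValueReport("risk-ratio", point, ci_e, approximate=False)


def evalue_from_smd(d: float, se: float = 0.0) -> EValueReport:
    """Approximate E-value for a standardized mean difference.

    Converts d to an approximate risk ratio RR = exp(0.91 d) (and the CI
    limits to exp(0.91 (d +/- 1.96 se))) before applying the risk-ratio
    E-value formula.
    """
    if se < 0:
        raise ValueError("se must be nonnegative")
    rr = math.exp(SMD_TO_LOG_RR * d)
    lo = math.exp(SMD_TO_LOG_RR * (d - _Z975 * se))
    hi = math.exp(SMD_TO_LOG_RR * (d + _Z975 * se))
    base = evalue_from_rr(rr, lo, hi)
    return EValueReport("standardized-difference", base.point, base.ci,
                        approximate=True)


# ---------------------------------------------------------------------------
# observed-confounder calibration


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw, x[order]))


def dichotomize_quintiles(x, w=None):
    """Top-vs-bottom weighted-quintile coding: 1 / 0 / NaN (middle 60%).

    Ties at a quantile boundary fall in the lower bin.
    """
    x = np.asarray(x, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    obs = ~np.isnan(x)
    q20 = _weighted_quantile(x[obs], w[obs], 0.20)
    q80 = _weighted_quantile(x[obs], w[obs], 0.80)
    out = np.full(x.size, np.nan)
    out[obs & (x <= q20)] = 0.0
    out[obs & (x > q80)] = 1.0
    return out


def calibrate_evalue(
    panel: pd.DataFrame,
    exposure: str,
    outcome: str,
    benchmark: str = "gender",
    weight_col: str | None = None,
    already_binary: bool = False,
) -> CalibrationBenchmark:
    """Benchmark risk ratios for an observed binary confounder.

    Continuous exposure/outcome are dichotomized at the top and bottom
    weighted quintiles (middle dropped).  RR_GY is the larger, across
    exposure strata, of the (larger / smaller) outcome prevalence across
    benchmark levels; RR_DG is the larger, across benchmark levels, of
    Pr(D=1|G=g) / Pr(D=0|G=g).
    """
    w = (panel[weight_col].to_numpy(float) if weight_col
         else np.ones(len(panel)))
    g = panel[benchmark].to_numpy(float)
    if not set(np.unique(g[~np.isnan(g)])) <= {0.0, 1.0}:
        raise ValueError(f"benchmark '{benchmark}' must be binary 0/1")

    def binarize(col):
        x = panel[col].to_numpy(float)
        vals = set(np.unique(x[~np.isnan(x)]))
        if already_binary or vals <= {0.0, 1.0}:
            return x
        return dichotomize_quintiles(x, w)

    d = binarize(exposure)
    y = binarize(outcome)

    def wprob(mask_num, mask_den):
        num = np.nansum(w * mask_num)
        den = np.nansum(w * mask_den)
        if den == 0:
            raise ValueError("empty cell in calibration table")
        return num / den

    ok = ~(np.isnan(d) | np.isnan(y) | np.isnan(g))
    d, y, g, w = d[ok], y[ok], g[ok], w[ok]

    # RR_GY: outcome prevalence ratio across benchmark levels, within
    # exposure strata, larger over smaller, then max over strata
    rr_gy = 1.0
    for d_level in (0.0, 1.0):
        in_d = d == d_level
        if not in_d.any():
            raise ValueError(f"empty exposure stratum D={int(d_level)}")
        p_m = wprob((y == 1) & in_d & (g == 1), in_d & (g == 1))
        p_f = wprob((y == 1) & in_d & (g == 0), in_d & (g == 0))
        lo, hi = sorted([p_m, p_f])
        if lo == 0:
            raise ValueError("zero outcome prevalence in a benchmark cell")
        rr_gy = max(rr_gy, hi / lo)

    # RR_DG: Pr(D=1|G=g) / Pr(D=0|G=g), max over benchmark levels
    rr_dg = 0.0
    for g_level in (0.0, 1.0):
        in_g = g == g_level
        p1 = wprob((d == 1) & in_g, in_g)
        p0 = wprob((d == 0) & in_g, in_g)
        if p0 == 0:
            raise ValueError("empty exposure cell within a benchmark level")
        rr_dg = max(rr_dg, p1 / p0)

    return CalibrationBenchmark(
        benchmark=benchmark, rr_gy=float(rr_gy), rr_dg=float(rr_dg),
        dichotomization="top-vs-bottom weighted quintiles, middle dropped")


# ---------------------------------------------------------------------------
# reliability attenuation


def reliability_correct(b: float, se: float, lambda_: float):
    """Disattenuate an estimate for unreliability of both measures.

    ``lambda_`` is the geometric-mean reliability sqrt(lambda_x lambda_y);
    estimate and SE are divided by it, and the CI is rebuilt from the
    corrected pieces (so its width scales by exactly 1/lambda).  For
    binary outcomes apply this on the log-RR scale.
    """
    if not 0.0 < lambda_ <= 1.0:
        raise ValueError("reliability must lie in (0, 1]")
    b_corr = b / lambda_
    se_corr = se / lambda_
    ci = (b_corr - _Z975 * se_corr, b_corr + _Z975 * se_corr)
    return b_corr, se_corr, ci


def reliability_grid(b: float, se: float,
                     lambdas=(0.40, 0.55, 0.70)) -> pd.DataFrame:
    """Corrected estimates over the conventional reliability grid."""
    rows = []
    for lam in lambdas:
        b_c, se_c, ci = reliability_correct(b, se, lam)
        rows.append(dict(reliability=lam, estimate=b_c, se=se_c,
                         ci_lo=ci[0], ci_hi=ci[1]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# R^2-based robustness value


def robustness_value(t_stat: float, dof: float, q: float = 1.0) -> dict:
    """Cinelli-Hazlett partial R^2 and robustness value RV_q.

    RV_q is the share of residual variance a confounder must explain in
    both the exposure and the outcome to reduce the estimate by the
    fraction q.
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    t2 = t_stat**2
    partial_r2 = t2 / (t2 + dof)
    f = abs(t_stat) / math.sqrt(dof)
    fq = q * f
    rv = 0.5 * (math.sqrt(fq**4 + 4.0 * fq**2) - fq**2)
    return {"partial_r2": float(partial_r2), "rv_q": float(rv)}


def omitted_variable_bias(se_b: float, dof: float,
                          r2_y: float, r2_d: float) -> float:
    """|bias| on the coefficient implied by confounder strengths
    (R^2 with outcome, R^2 with exposure), per the linear-model bound."""
    return float(math.sqrt(r2_y * r2_d / (1.0 - r2_d)) * se_b
                 * math.sqrt(dof))
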