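"""Random-effects pooling of country effects with the Paule-Mandel
estimator, Q-profile heterogeneity intervals, an omnibus ("global")
p-value, and leave-one-country-out influence diagnostics.

Model: b_i ~ Normal(theta_i, v_i), theta_i ~ Normal(mu, tau^2).  The
Paule-Mandel tau^2 solves the generalized-Q moment equation
sum_i w_i(tau^2) (b_i - muhat(tau^2))^2 = k - 1 with w_i = 1/(v_i+tau^2),
truncated at zero when the equation has no positive root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_Z975 = 1.959963984540054
PM_TOL = 1e-10

#: tau-hat below this is flagged as a likely underestimate of heterogeneity
INSTABILITY_TAU = 0.01


@dataclass
class MetaResult:
    k: int
    mu: float
    se: float
    ci: tuple[float, float]
    tau2: float
    tau_ci: tuple[float, float]
    q: float                      # Cochran's Q at tau^2 = 0
    global_p: float
    global_p_method: str
    b: np.ndarray
    v: np.ndarray
    weights: np.ndarray           # normalized, sum to 1
    unstable_tau: bool
    influence: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def tau(self) -> float:
        return float(np.sqrt(self.tau2))


def _generalized_q(tau2, b, v):
    w = 1.0 / (v + tau2)
    mu = np.sum(w * b) / np.sum(w)
    return float(np.sum(w * (b - mu) ** 2))


def _pm_tau2(b, v, tol=PM_TOL, max_expand=60):
    k = b.size
    target = k - 1.0
    if _generalized_q(0.0, b, v) <= target:
        return 0.0
    upper = max(np.var(b, ddof=1), np.mean(v), 1e-8)
    for _ in range(max_expand):
        if _generalized_q(upper, b, v) < target:
            break
        upper *= 2.0
    else:
        raise RuntimeError("Paule-Mandel root not bracketed after expansion")
    return float(optimize.brentq(
        lambda t2: _generalized_q(t2, b, v) - target, 0.0, upper,
        xtol=tol, rtol=8.9e-16))


def pm_random_effects(
    b, v, compute_influence: bool = True,
    global_p_method: str = "chi2_sum",
) -> MetaResult:
    """Paule-Mandel random-effects pooling of k country effects."""
    b = np.asarray(b, float)
    v = np.asarray(v, float)
    k = b.size
    if k < 2:
        raise ValueError("pooling requires at least 2 countries")
    if (v <= 0).any():
        raise ValueError("all variances must be positive")

    tau2 = _pm_tau2(b, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    ci = (mu - _Z975 * se, mu + _Z975 * se)
    q0 = _generalized_q(0.0, b, v)
    tau_ci = tau_ci_qprofile(b, v) if k >= 3 else (0.0, np.inf)
    p, method = global_p(b, v, method=global_p_method, return_method=True)

    res = MetaResult(
        k=k, mu=mu, se=se, ci=ci, tau2=tau2,
        tau_ci=tau_ci, q=q0, global_p=p, global_p_method=method,
        b=b, v=v, weights=w / w.sum(),
        unstable_tau=bool(np.sqrt(tau2) < INSTABILITY_TAU),
    )
    if compute_influence and k >= 3:
        res.influence = influence(b, v, full=res)
    return res


def tau_ci_qprofile(b, v, level: float = 0.95):
    """Q-profile confidence interval for tau (reported on the tau scale).

    Bounds are the tau^2 values at which the generalized Q statistic
    equals the chi-square(k-1) quantiles; the lower bound truncates at 0.
    """
    b = np.asarray(b, float)
    v = np.asarray(v, float)
    k = b.size
    if k < 3:
        raise ValueError("Q-profile interval requires k >= 3")
    alpha = 1.0 - level
    q_hi = stats.chi2.ppf(1.0 - alpha / 2.0, k - 1)
    q_lo = stats.chi2.ppf(alpha / 2.0, k - 1)

    def solve(target):
        if _generalized_q(0.0, b, v) <= target:
            return 0.0
        upper = max(np.var(b, ddof=1), np.mean(v), 1e-8)
        for _ in range(60):
            if _generalized_q(upper, b, v) < target:
                break
            upper *= 2.0
        else:
            return np.inf  # profile never crosses the quantile
        return float(optimize.brentq(
            lambda t2: _generalized_q(t2, b, v) - target, 0.0, upper,
            xtol=PM_TOL))

    lo2 = solve(q_hi)
    hi2 = solve(q_lo)
    return (float(np.sqrt(lo2)), float(np.sqrt(hi2)))


def global_p(b, v, method: str = "chi2_sum", return_method: bool = False):
    """Omnibus p-value for 'the association is null in every country'.

    ``chi2_sum`` (default): sum of squared Wald z statistics against
    chi-square with k df.  ``fisher``: Fisher's combination of two-sided
    per-country p-values against chi-square with 2k df.
    """
    b = np.asarray(b, float)
    v = np.asarray(v, float)
    z = b / np.sqrt(v)
    k = z.size
    if method == "chi2_sum":
        p = float(stats.chi2.sf(np.sum(z**2), df=k))
    elif method == "fisher":
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        pvals = np.clip(pvals, 1e-300, 1.0)
        p = float(stats.chi2.sf(-2.0 * np.sum(np.log(pvals)), df=2 * k))
    else:
        raise ValueError(f"unknown global-p method '{method}'")
    return (p, method) if return_method else p


def influence(b, v, full: MetaResult | None = None) -> pd.DataFrame:
    """Leave-one-out estimates, studentized residuals and a Cook's-D-like
    statistic, one row per country."""
    b = np.asarray(b, float)
    v = np.asarray(v, float)
    k = b.size
    if k < 3:
        raise ValueError("influence diagnostics require k >= 3")
    if full is None:
        full = pm_random_effects(b, v, compute_influence=False)
    rows = []
    for i in range(k):
        keep = np.ones(k, bool)
        keep[i] = False
        tau2_i = _pm_tau2(b[keep], v[keep])
        w = 1.0 / (v[keep] + tau2_i)
        mu_i = float(np.sum(w * b[keep]) / np.sum(w))
        se_i = float(1.0 / np.sqrt(np.sum(w)))
        resid = (b[i] - mu_i) / np.sqrt(v[i] + tau2_i + se_i**2)
        cooks = (full.mu - mu_i) ** 2 / full.se**2
        rows.append(dict(index=i, mu_loo=mu_i, se_loo=se_i, tau2_loo=tau2_i,
                         studentized_residual=float(resid),
                         cooks_d=float(cooks)))
    return pd.DataFrame(rows)


def pool_countries(country_table: pd.DataFrame,
                   global_p_method: str = "chi2_sum") -> pd.DataFrame:
    """Meta-analyze a `run_outcome_wide` table per (outcome, model).

    Non-convergent countries are excluded (with k reduced); the forest
    inputs live on each MetaResult.  Returns one summary row per cell.
    """
    rows = []
    for (outcome, model), df in country_table.groupby(["outcome", "model"]):
        ok = df[df["converged"] & df["v_std"].gt(0)]
        otype = df["outcome_type"].iloc[0]
        res = pm_random_effects(ok["b_std"].to_numpy(),
                                ok["v_std"].to_numpy(),
                                global_p_method=global_p_method)
        rows.append(dict(
            outcome=outcome, outcome_type=otype, model=model, k=res.k,
            mu=res.mu, se=res.se, ci_lo=res.ci[0], ci_hi=res.ci[1],
            tau=res.tau, tau_lo=res.tau_ci[0], tau_hi=res.tau_ci[1],
            q=res.q, global_p=res.global_p, unstable_tau=res.unstable_tau,
        ))
    return pd.DataFrame(rows)
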