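"""Multiple imputation by chained equations with predictive mean matching.

Imputation is run independently within each country, mirroring an
analysis pipeline where every model is country-specific.  Each incomplete
variable is regressed on its predictors, regression coefficients are
perturbed with a draw from their approximate posterior (proper
imputation), predictions for missing cases are matched to the ``donor_k``
nearest observed predictions, and an observed donor value is copied.
Pooling across completed datasets follows Rubin's rules with the
Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import columns as C

logger = logging.getLogger(__name__)

_RIDGE = 1e-8


@dataclass
class ImputationSet:
    """m completed panels plus the original missingness mask."""

    m: int
    panels: list[pd.DataFrame]
    mask: pd.DataFrame  # True where originally missing
    seed: int
    iterations: int
    donor_k: int
    predictor_map: dict[str, list[str]] = field(default_factory=dict)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for j, panel in enumerate(self.panels):
            panel.to_csv(directory / f"imputation_{j + 1:02d}.csv", index=False)
        self.mask.to_csv(directory / "missing_mask.csv", index=False)
        manifest = {
            "m": self.m, "seed": self.seed, "iterations": self.iterations,
            "donor_k": self.donor_k, "predictor_map": self.predictor_map,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ImputationSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        panels = [
            pd.read_csv(directory / f"imputation_{j + 1:02d}.csv")
            for j in range(manifest["m"])
        ]
        mask = pd.read_csv(directory / "missing_mask.csv")
        return cls(m=manifest["m"], panels=panels, mask=mask,
                   seed=manifest["seed"], iterations=manifest["iterations"],
                   donor_k=manifest["donor_k"],
                   predictor_map=manifest["predictor_map"])


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m estimates."""

    estimate: float
    within: float
    between: float
    total: float
    df: float
    fmi: float

    @property
    def se(self) -> float:
        return math.sqrt(self.total)


def default_predictor_map(panel: pd.DataFrame) -> dict[str, list[str]]:
    """Wave-1 gaps predicted by complete Wave-1 covariates; Wave-2 gaps by
    those plus the Wave-1 exposure item."""
    wave1_predictors = [C.WEIGHT] + C.MODEL1_COVARIATES
    out: dict[str, list[str]] = {}
    for col in panel.columns:
        if col.startswith("_") or col in (C.COUNTRY, C.RESPONDENT, C.STRATUM,
                                          C.PSU, C.RETAINED):
            continue
        if not panel[col].isna().any():
            continue
        if col.endswith(C.WAVE2_SUFFIX):
            out[col] = wave1_predictors + [C.EXPOSURE_ITEM]
        else:
            out[col] = [p for p in wave1_predictors if p != col]
    return out


def _draw_coefficients(X, y, rng):
    """Posterior-style draw of OLS coefficients (normal approximation)."""
    n, p = X.shape
    xtx = X.T @ X + _RIDGE * np.eye(p)
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    # scale draw via chi-square, then normal draw for beta
    sigma2_star = sigma2 * dof / rng.chisquare(dof)
    chol = np.linalg.cholesky(xtx_inv * sigma2_star + _RIDGE * np.eye(p))
    beta_star = beta + chol @ rng.standard_normal(p)
    return beta, beta_star


def _pmm_impute_variable(df, var, predictors, obs, donor_k, rng):
    """One PMM update of ``var`` in-place; returns imputed values."""
    usable = []
    for p in predictors:
        if p not in df.columns:
            logger.info("predictor %s absent; dropped for %s", p, var)
            continue
        col = df[p].to_numpy(float)
        if np.isnan(col).any():
            # incomplete and not itself imputed at this point in the cycle
            logger.info("predictor %s incomplete; dropped for %s", p, var)
            continue
        if col.std() == 0:
            logger.info("predictor %s constant; dropped for %s", p, var)
            continue
        usable.append(p)
    X = np.column_stack(
        [np.ones(len(df))] + [df[p].to_numpy(float) for p in usable])
    y = df[var].to_numpy(float)
    beta, beta_star = _draw_coefficients(X[obs], y[obs], rng)
    # type-1 matching: fitted coefficients predict the donors, drawn
    # coefficients predict the missing cases, so parameter uncertainty
    # propagates into the between-imputation variance
    pred_obs = X[obs] @ beta
    pred_mis = X[~obs] @ beta_star
    # k nearest observed predictions; donor drawn uniformly among them
    dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
    k = min(donor_k, pred_obs.size)
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    choice = rng.integers(0, k, size=pred_mis.size)
    donors = nearest[np.arange(pred_mis.size), choice]
    return y[obs][donors]


def _impute_country(df, predictor_map, iterations, donor_k, rng):
    mask = {v: df[v].isna().to_numpy() for v in predictor_map if v in df}
    todo = [v for v, m in mask.items() if m.any()]
    for v in todo:
        n_obs = int((~mask[v]).sum())
        if n_obs < donor_k:
            raise ValueError(
                f"variable '{v}' has only {n_obs} observed values "
                f"(< donor_k={donor_k}) in country "
                f"{df[C.COUNTRY].iloc[0]!r}")
    # visit order: increasing missingness stabilizes early cycles
    todo.sort(key=lambda v: mask[v].sum())
    out = df.copy()
    for v in todo:  # initial fill: random observed draws
        obs_vals = out.loc[~mask[v], v].to_numpy(float)
        out.loc[mask[v], v] = rng.choice(obs_vals, size=int(mask[v].sum()))
    for _ in range(iterations):
        for v in todo:
            imputed = _pmm_impute_variable(
                out, v, predictor_map[v], ~mask[v], donor_k, rng)
            out.loc[mask[v], v] = imputed
    return out


def mice_pmm(
    panel: pd.DataFrame,
    predictor_map: dict[str, list[str]] | None = None,
    m: int = 20,
    iterations: int = 10,
    donor_k: int = 5,
    seed: int = 0,
) -> ImputationSet:
    """Chained-equation PMM imputation, run per country independently."""
    if predictor_map is None:
        predictor_map = default_predictor_map(panel)
    analysis_vars = [v for v in predictor_map if v in panel.columns]
    mask = panel[analysis_vars].isna() if analysis_vars else pd.DataFrame(
        index=panel.index)

    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=m)
    panels = []
    for j in range(m):
        rng = np.random.default_rng(child_seeds[j])
        if not analysis_vars or not mask.to_numpy().any():
            panels.append(panel.copy())
            continue
        parts = []
        for _, df in panel.groupby(C.COUNTRY, sort=False):
            parts.append(_impute_country(df, predictor_map, iterations,
                                         donor_k, rng))
        panels.append(pd.concat(parts).loc[panel.index])
    return ImputationSet(m=m, panels=panels, mask=mask, seed=seed,
                         iterations=iterations, donor_k=donor_k,
                         predictor_map={k: list(v)
                                        for k, v in predictor_map.items()})


def rubin_pool(
    estimates,
    variances,
    complete_data_df: float = np.inf,
) -> PooledEstimate:
    """Rubin's rules with the Barnard-Rubin degrees of freedom."""
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    m = q.size
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2 estimates")
    qbar = float(q.mean())
    wbar = float(u.mean())
    b = float(q.var(ddof=1))
    t = wbar + (1.0 + 1.0 / m) * b

    if b == 0.0 or t == 0.0:
        lam = 0.0
        r = 0.0
        df_old = np.inf
    else:
        lam = (1.0 + 1.0 / m) * b / t
        r = (1.0 + 1.0 / m) * b / wbar if wbar > 0 else np.inf
        df_old = (m - 1) / lam**2
    nu_com = complete_data_df
    if np.isfinite(nu_com):
        df_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
        df = np.inf if (df_old == np.inf and df_obs == np.inf) else \
            1.0 / (1.0 / df_old + 1.0 / df_obs)
    else:
        df = df_old
    fmi = (r + 2.0 / (df + 3.0)) / (r + 1.0) if np.isfinite(df) else \
        r / (r + 1.0)
    return PooledEstimate(estimate=qbar, within=wbar, between=b, total=t,
                          df=float(df), fmi=float(min(max(fmi, 0.0), 1.0)))


def estimate_fmi(
    panel: pd.DataFrame,
    predictor_map: dict[str, list[str]] | None = None,
    pilot_m: int = 5,
    seed: int = 0,
) -> dict:
    """Pilot-imputation FMI for the mean of each incomplete variable.

    Runs a small chained-equation imputation and applies Rubin's rules to
    the per-variable means; the dataset summary is the maximum, i.e. the
    worst-case variable, which is what drives the required number of
    imputations.  Returns all zeros when the panel is complete.
    """
    if predictor_map is None:
        predictor_map = default_predictor_map(panel)
    incomplete = [v for v in predictor_map
                  if v in panel.columns and panel[v].isna().any()]
    if not incomplete:
        return {"per_variable": {}, "summary": 0.0}
    imps = mice_pmm(panel, predictor_map, m=pilot_m, seed=seed)
    per_var = {}
    for v in incomplete:
        means = [float(p[v].mean()) for p in imps.panels]
        variances = [float(p[v].var(ddof=1) / len(p)) for p in imps.panels]
        pooled = rubin_pool(means, variances,
                            complete_data_df=len(panel) - 1)
        per_var[v] = pooled.fmi
    return {"per_variable": per_var, "summary": max(per_var.values())}


def choose_m(fmi: float, efficiency_threshold: float = 0.05) -> int:
    """Smallest m >= 1 with fmi / m strictly below the threshold."""
    if efficiency_threshold <= 0:
        raise ValueError("efficiency threshold must be positive")
    if not 0.0 <= fmi <= 1.0:
        raise ValueError("fmi must lie in [0, 1]")
    if fmi == 0.0:
        return 1
    m = math.floor(fmi / efficiency_threshold) + 1
    return max(1, m)
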