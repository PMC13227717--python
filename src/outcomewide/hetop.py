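"""Penalized heteroskedastic ordered probit (HETOP) DIF screening.

A single ordinal item observed in G groups (countries) is modeled with
common thresholds tau_1 < ... < tau_{K-1} and group-specific latent
location mu_g and scale sigma_g:

    Pr(Y = k | g) = Phi((tau_k - mu_g)/sigma_g) - Phi((tau_{k-1} - mu_g)/sigma_g)

Location deviations are uniform DIF; scale deviations (discrimination
proportional to 1/sigma_g) are nonuniform DIF.  A ridge penalty on
(mu_g, log sigma_g), weighted by group size, shrinks group deviations
toward zero; sweeping the penalty traces how robustly a group stands out.
After convergence the size-weighted means of mu_g and log sigma_g are
centered at zero (a pure reparameterization, likelihood-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr
from statsmodels.tools.numdiff import approx_hess

_IDENT_RIDGE = 1e-7  # breaks the location/scale indeterminacy at penalty 0


@dataclass
class HetopFit:
    groups: list[str]
    k_categories: int
    thresholds: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    se_mu: np.ndarray
    se_log_sigma: np.ndarray
    penalty: float
    penalized_loglik: float
    converged: bool
    n_g: np.ndarray
    dropped_groups: list[str] = field(default_factory=list)

    def group_index(self, group: str) -> int:
        return self.groups.index(group)


@dataclass
class DifFlags:
    reference_penalty: float
    z_threshold: float
    table: pd.DataFrame  # group, mu, sigma, SEs, uniform/nonuniform flags


def _unpack(params, K, G):
    t1 = params[0]
    if K > 2:
        diffs = np.exp(params[1:K - 1])
        thresholds = np.concatenate([[t1], t1 + np.cumsum(diffs)])
    else:
        thresholds = np.array([t1])
    mu = params[K - 1:K - 1 + G]
    log_sigma = params[K - 1 + G:]
    return thresholds, mu, log_sigma


def _cell_probs(thresholds, mu, sigma):
    z = (thresholds[None, :] - mu[:, None]) / sigma[:, None]
    cdf = np.concatenate(
        [np.zeros((len(mu), 1)), ndtr(z), np.ones((len(mu), 1))], axis=1)
    return np.diff(cdf, axis=1)


def _objective(params, counts, K, G, penalty, n_g, n):
    thresholds, mu, log_sigma = _unpack(params, K, G)
    probs = _cell_probs(thresholds, mu, np.exp(log_sigma))
    nll = -float(np.sum(counts * np.log(np.clip(probs, 1e-300, None))))
    dev = mu**2 + log_sigma**2
    pen = penalty * float(np.sum(n_g * dev)) / n
    pen += _IDENT_RIDGE * float(np.sum(dev))
    return nll + pen


def _center(thresholds, mu, log_sigma, n_g):
    w = n_g / n_g.sum()
    m = float(np.sum(w * mu))
    ls = float(np.sum(w * log_sigma))
    s = np.exp(ls)
    return ((thresholds - m) / s, (mu - m) / s, log_sigma - ls)


def fit_hetop(
    counts: pd.DataFrame | np.ndarray,
    penalty: float = 0.0,
    start: np.ndarray | None = None,
    compute_se: bool = True,
) -> HetopFit:
    """Fit the penalized HETOP model to a group x category count table.

    ``counts`` rows are groups, columns the K ordered categories (K >= 3
    for the scale to be identifiable).  Groups with fewer than two
    occupied categories are dropped with a notice in ``dropped_groups``.
    """
    if isinstance(counts, pd.DataFrame):
        groups = [str(g) for g in counts.index]
        table = counts.to_numpy(float)
    else:
        table = np.asarray(counts, float)
        groups = [f"g{i + 1}" for i in range(table.shape[0])]
    K = table.shape[1]
    if K < 3:
        raise ValueError("scale identification requires K >= 3 categories")

    occupied = (table > 0).sum(axis=1)
    keep = occupied >= 2
    dropped = [g for g, k in zip(groups, keep) if not k]
    groups = [g for g, k in zip(groups, keep) if k]
    table = table[keep]
    G = table.shape[0]
    if G < 2:
        raise ValueError("need at least 2 usable groups")
    n_g = table.sum(axis=1)
    n = float(n_g.sum())

    if start is None:
        # moment start: thresholds from pooled cumulative proportions
        pooled = table.sum(axis=0) / n
        cum = np.clip(np.cumsum(pooled)[:-1], 1e-4, 1 - 1e-4)
        t = np.array([_safe_ndtri(c) for c in cum])
        t = np.maximum.accumulate(t + 1e-6 * np.arange(K - 1))
        params0 = np.concatenate([
            [t[0]], np.log(np.clip(np.diff(t), 1e-3, None)),
            np.zeros(G), np.zeros(G)])
    else:
        params0 = np.asarray(start, float)

    res = optimize.minimize(
        _objective, params0, args=(table, K, G, penalty, n_g, n),
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-8})

    thresholds, mu, log_sigma = _unpack(res.x, K, G)
    thresholds, mu, log_sigma = _center(thresholds, mu, log_sigma, n_g)

    se_mu = np.full(G, np.nan)
    se_ls = np.full(G, np.nan)
    if compute_se:
        # observed information at the penalized optimum, propagated through
        # the centering transform (delta method).  Centering annihilates
        # the common location/scale direction, which is only weakly
        # identified, so raw-parameter SEs would be meaninglessly large.
        hess = approx_hess(res.x, _objective,
                           args=(table, K, G, penalty, n_g, n))
        cov = np.linalg.pinv(hess)
        w = n_g / n_g.sum()
        J = np.zeros((2 * G, len(res.x)))
        s = np.exp(float(np.sum(w * np.log(np.exp(
            _unpack(res.x, K, G)[2])))))
        raw_mu = _unpack(res.x, K, G)[1]
        m = float(np.sum(w * raw_mu))
        for g in range(G):
            J[g, K - 1:K - 1 + G] = (np.eye(G)[g] - w) / s
            J[g, K - 1 + G:] = -(raw_mu[g] - m) / s * w
            J[G + g, K - 1 + G:] = np.eye(G)[g] - w
        cov_c = J @ cov @ J.T
        diag = np.clip(np.diag(cov_c), 0.0, None)
        se_mu = np.sqrt(diag[:G])
        se_ls = np.sqrt(diag[G:])

    return HetopFit(
        groups=groups, k_categories=K, thresholds=thresholds, mu=mu,
        sigma=np.exp(log_sigma), se_mu=se_mu, se_log_sigma=se_ls,
        penalty=penalty, penalized_loglik=-float(res.fun),
        converged=bool(res.success), n_g=n_g, dropped_groups=dropped,
        )


def _safe_ndtri(p):
    from scipy.special import ndtri
    return float(ndtri(p))


def _pack(fit: HetopFit) -> np.ndarray:
    t = fit.thresholds
    return np.concatenate([
        [t[0]], np.log(np.clip(np.diff(t), 1e-8, None)),
        fit.mu, np.log(fit.sigma)])


def penalty_path(counts, penalties, compute_se: bool = True) -> list[HetopFit]:
    """Fits over an increasing penalty grid, warm-starting each from the
    previous optimum."""
    penalties = list(penalties)
    if any(p < 0 for p in penalties) or sorted(penalties) != penalties:
        raise ValueError("penalty grid must be nonnegative and increasing")
    fits: list[HetopFit] = []
    start = None
    for pen in penalties:
        fit = fit_hetop(counts, penalty=pen, start=start,
                        compute_se=compute_se)
        fits.append(fit)
        start = _pack(fit)
    return fits


def flag_dif(path: list[HetopFit], reference_penalty: float,
             z_threshold: float = 2.0) -> DifFlags:
    """Flag groups whose location (uniform DIF) or log-scale (nonuniform
    DIF) deviation exceeds ``z_threshold`` standard errors at the
    reference penalty."""
    penalties = [f.penalty for f in path]
    if reference_penalty not in penalties:
        raise ValueError(f"reference penalty {reference_penalty} not in path")
    fit = path[penalties.index(reference_penalty)]
    log_sigma = np.log(fit.sigma)
    rows = []
    for i, g in enumerate(fit.groups):
        z_mu = (abs(fit.mu[i]) / fit.se_mu[i]
                if fit.se_mu[i] > 0 else np.inf)
        z_ls = (abs(log_sigma[i]) / fit.se_log_sigma[i]
                if fit.se_log_sigma[i] > 0 else np.inf)
        rows.append(dict(
            group=g, mu=float(fit.mu[i]), sigma=float(fit.sigma[i]),
            se_mu=float(fit.se_mu[i]), se_log_sigma=float(fit.se_log_sigma[i]),
            uniform_dif=bool(z_mu > z_threshold),
            nonuniform_dif=bool(z_ls > z_threshold),
        ))
    return DifFlags(reference_penalty=reference_penalty,
                    z_threshold=z_threshold, table=pd.DataFrame(rows))


def expected_item_response(fit: HetopFit, group: str,
                           latent_grid: np.ndarray) -> np.ndarray:
    """Expected response E[Y | eta] along a latent grid for one group.

    ER_g(eta) = sum_k k [Phi((tau_k - mu_g - eta)/sigma_g) - ...]; the
    curve is monotone nondecreasing in eta, and flatter for larger
    sigma_g (lower discrimination).
    """
    i = fit.group_index(group)
    eta = np.asarray(latent_grid, float)
    z = (fit.thresholds[None, :] - fit.mu[i] - eta[:, None]) / fit.sigma[i]
    cdf = np.concatenate(
        [np.zeros((eta.size, 1)), ndtr(z), np.ones((eta.size, 1))], axis=1)
    probs = np.diff(cdf, axis=1)
    categories = np.arange(1, fit.k_categories + 1)
    return probs @ categories


def counts_from_panel(panel: pd.DataFrame, item_column: str,
                      group_column: str = "country",
                      k_categories: int | None = None) -> pd.DataFrame:
    """Group x category count table for an ordinal item."""
    obs = panel[panel[item_column].notna()]
    tab = pd.crosstab(obs[group_column], obs[item_column].astype(int))
    if k_categories is not None:
        for k in range(1, k_categories + 1):
            if k not in tab.columns:
                tab[k] = 0
        tab = tab[sorted(tab.columns)]
    return tab
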