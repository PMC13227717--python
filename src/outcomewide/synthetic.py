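"""Seeded generator for two-wave multinational wellbeing-panel data.

The generator produces a stratified, clustered, weighted cohort spanning
many countries, with a four-category focal exposure item, a block of
correlated contemporaneous confounders, continuous 0-10 and binary Wave-2
outcomes, covariate-dependent attrition, item-level missingness, and
(optionally) injected differential item functioning on one ordinal item.

Country-specific true effects are drawn as theta_i ~ Normal(mu, tau^2),
so the random-effects pooling stage has a known ground truth.  Every
drawn quantity is recorded in a :class:`TruthRecord`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri
from scipy.stats import norm

from . import columns as C

#: outcome types understood by the generator
CONTINUOUS = "continuous_0_10"
BINARY = "binary"
ORDINAL = "ordinal_4"

DEFAULT_OUTCOME_MENU = [
    ("secure_flourishing", CONTINUOUS),
    ("life_satisfaction", CONTINUOUS),
    ("happiness", CONTINUOUS),
    ("daily_smoker", BINARY),
    ("currently_employed", BINARY),
    ("mastery", ORDINAL),
]

#: attrition depends positively on baseline wellbeing proxies, mirroring
#: panels where healthier, more settled respondents are easier to recontact
DEFAULT_ATTRITION_COEFFICIENTS = {
    "health_growing_up": 0.35,
    "education": 0.25,
    "age": 0.20,
    "income_quintile": 0.15,
}

_CONTINUOUS_CENTER = 5.0
_CONTINUOUS_SCALE = 1.4  # storage scale for unit-variance latent outcomes


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-wave cohort.

    Defaults mirror the structure of a 23-country flourishing panel:
    heterogeneous country effects (mu = 0.2, tau = 0.09 on the
    standardized scale), 79 correlated confounders driven by 5 latent
    factors, stratified cluster sampling with inverse-inclusion weights,
    and retention targets spanning 23%-90%.
    """

    n_countries: int = 23
    n_per_country: int | Sequence[int] = 2000
    strata_per_country: int = 4
    psus_per_stratum: int = 6
    true_mu: float = 0.2
    true_tau: float = 0.09
    exposure_prevalence: float = 0.70
    outcome_menu: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_OUTCOME_MENU)
    )
    confounder_count: int = 79
    n_factors: int = 5
    confounder_communality: float = 0.45
    exposure_factor_loading: float = 0.0
    binary_base_risk: float = 0.20
    retention_range: tuple[float, float] = (0.23, 0.90)
    item_missing_rate: float = 0.02
    dif_item: str | None = None
    dif_shifts: dict[str, tuple[float, float]] | None = None
    reliability: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_tau < 0:
            raise ValueError("true_tau must be >= 0")
        for p in (self.exposure_prevalence, self.item_missing_rate,
                  *self.retention_range):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 < self.binary_base_risk < 1.0:
            raise ValueError("binary_base_risk must lie in (0, 1)")
        if self.reliability is not None and not 0.0 < self.reliability <= 1.0:
            raise ValueError("reliability must lie in (0, 1]")
        if self.confounder_count < 2:
            raise ValueError("need at least 2 confounders")

    @property
    def country_labels(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_countries)]

    def sizes(self) -> list[int]:
        if isinstance(self.n_per_country, int):
            return [self.n_per_country] * self.n_countries
        sizes = list(self.n_per_country)
        if len(sizes) != self.n_countries:
            raise ValueError("n_per_country list length != n_countries")
        return sizes


@dataclass
class TruthRecord:
    """Ground truth drawn while generating a cohort (no hidden state)."""

    true_mu: float
    true_tau: float
    theta: dict[str, float]
    exposure_thresholds: list[float]
    binary_base_risk: float
    outcome_menu: list[tuple[str, str]]
    attrition_coefficients: dict[str, float] = field(default_factory=dict)
    attrition_intercepts: dict[str, float] = field(default_factory=dict)
    retention_targets: dict[str, float] = field(default_factory=dict)
    dif_item: str | None = None
    dif_shifts: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        d["outcome_menu"] = [tuple(t) for t in d["outcome_menu"]]
        d["dif_shifts"] = {k: tuple(v) for k, v in d["dif_shifts"].items()}
        return cls(**d)


def _exposure_thresholds(prevalence: float) -> list[float]:
    """Cutpoints on the standard-normal exposure latent.

    The rarely/often cut is placed so that Pr(often or always) equals the
    requested prevalence; the outer cuts are offset to give non-degenerate
    never and always categories.
    """
    t2 = ndtri(1.0 - prevalence)
    return [t2 - 0.9, t2, t2 + 1.0]


def _ordinal_from_latent(latent: np.ndarray, thresholds: Sequence[float],
                         rng: np.random.Generator,
                         loc: float = 0.0, scale: float = 1.0) -> np.ndarray:
    """Heteroskedastic ordered-probit draw: categories 1..K."""
    y_star = loc + latent + scale * rng.standard_normal(latent.size)
    return 1 + np.searchsorted(np.asarray(thresholds), y_star).astype(np.int64)


def _hidden_latent(item: str) -> str:
    return f"_eta_{item}"


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a complete (no attrition, no missingness) two-wave panel.

    Returns the panel and a :class:`TruthRecord` with all drawn effects.
    The panel includes a hidden ``_eta_<item>`` column per ordinal item,
    holding the latent construct used to draw that item; it is consumed
    by :func:`inject_dif` and excluded from analysis contracts.
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.country_labels
    sizes = spec.sizes()

    theta = spec.true_mu + spec.true_tau * rng.standard_normal(spec.n_countries)
    if spec.true_tau == 0.0:
        theta = np.full(spec.n_countries, spec.true_mu)

    # confounder loading structure is shared across countries so PCs mean
    # the same thing everywhere
    loadings = rng.standard_normal((spec.confounder_count, spec.n_factors))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    thresholds = _exposure_thresholds(spec.exposure_prevalence)

    frames = []
    for ci, (country, n) in enumerate(zip(labels, sizes)):
        frames.append(
            _generate_country(spec, rng, country, n, theta[ci],
                              loadings, thresholds)
        )
    panel = pd.concat(frames, ignore_index=True)

    truth = TruthRecord(
        true_mu=spec.true_mu,
        true_tau=spec.true_tau,
        theta={c: float(t) for c, t in zip(labels, theta)},
        exposure_thresholds=[float(t) for t in thresholds],
        binary_base_risk=spec.binary_base_risk,
        outcome_menu=list(spec.outcome_menu),
    )
    return panel, truth


def _generate_country(spec, rng, country, n, theta_i, loadings, thresholds):
    data: dict = {
        C.COUNTRY: np.repeat(country, n),
        C.RESPONDENT: [f"{country}-{i:06d}" for i in range(n)],
    }

    # -- design: strata with unequal sampling fractions, PSUs nested inside
    n_strata = spec.strata_per_country
    fractions = np.linspace(0.05, 0.5, n_strata)
    stratum = rng.integers(0, n_strata, size=n)
    psu_within = rng.integers(0, spec.psus_per_stratum, size=n)
    data[C.STRATUM] = [f"{country}-S{s + 1}" for s in stratum]
    data[C.PSU] = [f"{country}-S{s + 1}-P{p + 1}"
                   for s, p in zip(stratum, psu_within)]
    data[C.WEIGHT] = 1.0 / fractions[stratum]

    # -- demographics (coded numerically; see columns module)
    data["age"] = np.clip(rng.normal(45, 15, n), 18, 90).round()
    data["gender"] = rng.binomial(1, 0.52, n)
    data["education"] = rng.integers(0, 5, n)
    data["employed"] = rng.binomial(1, 0.60, n)
    data["married"] = rng.binomial(1, 0.55, n)
    data["urban"] = rng.binomial(1, 0.65, n)
    data["income_quintile"] = rng.integers(1, 6, n)
    data["immigrant"] = rng.binomial(1, 0.10, n)
    data["religious_attendance"] = rng.integers(0, 6, n)

    # -- retrospective childhood covariates
    data["mother_relationship"] = rng.integers(1, 5, n)
    data["father_relationship"] = rng.integers(1, 5, n)
    data["parents_married_age12"] = rng.binomial(1, 0.75, n)
    data["abused_growing_up"] = rng.binomial(1, 0.15, n)
    data["outsider_growing_up"] = rng.binomial(1, 0.20, n)
    data["health_growing_up"] = rng.integers(1, 6, n)
    data["financial_status_growing_up"] = rng.integers(1, 6, n)
    data["religious_attendance_age12"] = rng.integers(0, 6, n)

    # -- correlated confounder block from a low-rank factor structure
    factors = rng.standard_normal((n, spec.n_factors))
    h = spec.confounder_communality
    conf = (np.sqrt(h) * factors @ loadings.T
            + np.sqrt(1.0 - h) * rng.standard_normal((n, spec.confounder_count)))
    for j, col in enumerate(C.confounder_columns(spec.confounder_count)):
        data[col] = conf[:, j]

    # -- focal exposure: latent depends on demographics (adjusted for by
    # Model 1) and optionally on the confounder factors
    demo = np.column_stack([
        (data["age"] - 45.0) / 15.0,
        data["gender"] - 0.5,
        (data["education"] - 2.0) / 1.4,
        (data["health_growing_up"] - 3.0) / 1.4,
    ])
    demo_coef = np.array([0.15, 0.10, 0.20, 0.20])
    lin = demo @ demo_coef + spec.exposure_factor_loading * factors[:, 0]
    lin_var = demo_coef @ demo_coef + spec.exposure_factor_loading ** 2
    x_latent = lin + np.sqrt(max(1.0 - lin_var, 0.05)) * rng.standard_normal(n)
    data[C.EXPOSURE_ITEM] = 1 + np.searchsorted(thresholds, x_latent)
    exposed = (data[C.EXPOSURE_ITEM] >= 3).astype(float)
    p_exposed = 1.0 - norm.cdf(thresholds[1])

    # -- Wave-2 outcomes with country effect theta_i on the binary exposure
    # contrast; continuous outcomes have unit population variance before
    # rescaling to the 0-10 storage scale
    gamma_demo = np.array([0.12, 0.08, 0.12, 0.12])
    gamma_fac = np.full(spec.n_factors, np.sqrt(0.15 / spec.n_factors))
    sys_var = (gamma_demo @ gamma_demo + 0.15
               + theta_i ** 2 * p_exposed * (1.0 - p_exposed))
    resid_sd = np.sqrt(1.0 - sys_var) if sys_var < 1.0 else np.nan

    for name, kind in spec.outcome_menu:
        col = C.outcome_column(name)
        if kind == CONTINUOUS:
            if not np.isfinite(resid_sd):
                raise ValueError(
                    f"continuous outcome '{name}': systematic variance "
                    "exceeds 1; reduce effect sizes")
            y_star = (theta_i * (exposed - p_exposed)
                      + demo @ gamma_demo + factors @ gamma_fac
                      + resid_sd * rng.standard_normal(n))
            y = _CONTINUOUS_CENTER + _CONTINUOUS_SCALE * y_star
            data[col] = np.clip(y, 0.0, 10.0)
            if spec.reliability is not None and spec.reliability < 1.0:
                lam = spec.reliability
                noise_sd = _CONTINUOUS_SCALE * np.sqrt((1.0 - lam) / lam)
                data[col] = data[col] + noise_sd * rng.standard_normal(n)
        elif kind == BINARY:
            lp = (np.log(spec.binary_base_risk)
                  + theta_i * exposed + 0.1 * (data["gender"] - 0.5))
            n_clipped = int((lp > np.log(0.95)).sum())
            if n_clipped > 0.2 * n:
                raise ValueError(
                    f"binary outcome '{name}': risk model implies invalid "
                    f"probabilities for {n_clipped}/{n} respondents"
                )
            data[col] = rng.binomial(1, np.exp(np.minimum(lp, np.log(0.95))))
        elif kind == ORDINAL:
            eta = 0.7 * x_latent
            data[_hidden_latent(name)] = eta
            data[col] = _ordinal_from_latent(
                eta, np.sqrt(1.49) * np.asarray(thresholds), rng,
                scale=np.sqrt(1.49 - 0.49))
        else:
            raise ValueError(f"unknown outcome type '{kind}' for '{name}'")

    data[C.RETAINED] = np.ones(n, dtype=bool)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# attrition


def inject_attrition(
    panel: pd.DataFrame,
    coefficients: dict[str, float] | None = None,
    target_range: tuple[float, float] = (0.23, 0.90),
    seed: int = 0,
    truth: TruthRecord | None = None,
) -> pd.DataFrame:
    """Draw a covariate-dependent retention flag and mask Wave-2 columns.

    Retention follows a per-country logistic model on standardized Wave-1
    covariates.  Per-country intercepts are calibrated (by root finding on
    the realized linear predictors) so expected retention spans
    ``target_range`` across countries, mirroring real panels where
    retention ranged from 23% to 90%.
    """
    coefficients = (DEFAULT_ATTRITION_COEFFICIENTS
                    if coefficients is None else coefficients)
    missing = [c for c in coefficients if c not in panel.columns]
    if missing:
        raise KeyError(f"attrition predictors not in panel: {missing}")

    rng = np.random.default_rng(seed)
    out = panel.copy()
    countries = list(dict.fromkeys(out[C.COUNTRY]))
    lo, hi = target_range
    targets = (np.linspace(lo, hi, len(countries)) if len(countries) > 1
               else np.array([(lo + hi) / 2.0]))

    wave2 = [c for c in out.columns if c.endswith(C.WAVE2_SUFFIX)]
    intercepts: dict[str, float] = {}
    for country, target in zip(countries, targets):
        idx = out[C.COUNTRY] == country
        lin = np.zeros(int(idx.sum()))
        for col, coef in coefficients.items():
            x = out.loc[idx, col].to_numpy(float)
            sd = x.std()
            lin += coef * ((x - x.mean()) / sd if sd > 0 else 0.0)

        if np.isposinf(target) or target >= 1.0:
            p = np.ones_like(lin)
            intercepts[country] = np.inf
        else:
            def gap(c, lin=lin, target=target):
                return expit(c + lin).mean() - target
            c0 = brentq(gap, -30.0, 30.0)
            intercepts[country] = float(c0)
            p = expit(c0 + lin)

        retained = rng.random(lin.size) < p
        if not retained.any():
            raise RuntimeError(f"no respondents retained in {country}")
        out.loc[idx, C.RETAINED] = retained
        if not retained.all():
            out.loc[idx & ~out[C.RETAINED], wave2] = np.nan

    if truth is not None:
        truth.attrition_coefficients = dict(coefficients)
        truth.attrition_intercepts = intercepts
        truth.retention_targets = {c: float(t)
                                   for c, t in zip(countries, targets)}
    return out


def inject_item_missingness(
    panel: pd.DataFrame, rate: float, seed: int = 0
) -> pd.DataFrame:
    """MCAR item-level missingness on exposure, confounders and outcomes.

    Wave-2 cells are only eligible among retained respondents (attrition
    missingness is handled by :func:`inject_attrition`).
    """
    if rate == 0.0:
        return panel.copy()
    rng = np.random.default_rng(seed)
    out = panel.copy()
    conf = [c for c in out.columns if c.startswith(C.CONFOUNDER_PREFIX)]
    wave1_items = [C.EXPOSURE_ITEM] + conf
    wave2_items = [c for c in out.columns if c.endswith(C.WAVE2_SUFFIX)]
    for col in wave1_items:
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    retained = out[C.RETAINED].to_numpy(bool)
    for col in wave2_items:
        mask = (rng.random(len(out)) < rate) & retained
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# differential item functioning


def inject_dif(
    panel: pd.DataFrame,
    item: str,
    per_country_shifts: dict[str, tuple[float, float]],
    seed: int = 0,
    truth: TruthRecord | None = None,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Regenerate one ordinal item with shifted measurement parameters.

    Each country's responses are redrawn from the heteroskedastic
    ordered-probit measurement model with location shift ``loc`` and scale
    ``exp(log_scale)`` applied to that country's group parameters.  The
    latent construct is untouched, so any shift is pure DIF.  Measurement
    thresholds default to the generator's (taken from ``truth`` when
    given, so they match the cohort's exposure prevalence).
    """
    col = C.outcome_column(item)
    latent_col = _hidden_latent(item)
    if col not in panel.columns or latent_col not in panel.columns:
        raise KeyError(f"'{item}' is not an ordinal item of this panel")

    if thresholds is None:
        thresholds = (truth.exposure_thresholds if truth is not None
                      else _exposure_thresholds(0.70))
    rng = np.random.default_rng(seed)
    out = panel.copy()
    base_thresholds = np.sqrt(1.49) * np.asarray(thresholds)
    for country in dict.fromkeys(out[C.COUNTRY]):
        idx = (out[C.COUNTRY] == country).to_numpy()
        loc, log_scale = per_country_shifts.get(country, (0.0, 0.0))
        eta = out.loc[idx, latent_col].to_numpy(float)
        keep = out.loc[idx, col].notna().to_numpy()
        drawn = _ordinal_from_latent(eta, base_thresholds, rng,
                                     loc=loc, scale=np.exp(log_scale))
        vals = out.loc[idx, col].to_numpy(float)
        vals[keep] = drawn[keep]
        out.loc[idx, col] = vals

    if truth is not None:
        truth.dif_item = item
        truth.dif_shifts = {k: tuple(map(float, v))
                            for k, v in per_country_shifts.items()}
    return out


# ---------------------------------------------------------------------------
# orchestration


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, TruthRecord]:
    """Full study-conditions simulation: cohort + attrition + item
    missingness + optional DIF."""
    panel, truth = generate_cohort(spec)
    panel = inject_attrition(panel, target_range=spec.retention_range,
                             seed=spec.seed + 1, truth=truth)
    if spec.dif_item is not None and spec.dif_shifts:
        panel = inject_dif(panel, spec.dif_item, spec.dif_shifts,
                           seed=spec.seed + 2, truth=truth)
    panel = inject_item_missingness(panel, spec.item_missing_rate,
                                    seed=spec.seed + 3)
    return panel, truth
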