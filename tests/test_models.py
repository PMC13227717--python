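"""Exposure recoding, weighted linear and modified Poisson fits,
standardization, and the outcome-wide driver."""

import numpy as np
import pandas as pd
import pytest

import outcomewide as ow
from outcomewide import columns as C
from outcomewide.models import ModelSpec


@pytest.mark.parametrize("value,scheme,expected", [
    ("often", "NR_vs_OA", 1.0),
    ("rarely", "NR_vs_OA", 0.0),
    ("rarely", "N_vs_ROA", 1.0),
    ("never", "N_vs_ROA", 0.0),
    ("often", "NRO_vs_A", 0.0),
    ("always", "NRO_vs_A", 1.0),
    (2, "continuous", 2.0),
])
def test_recode_exposure_schemes(value, scheme, expected):
    assert ow.recode_exposure([value], scheme)[0] == expected


def test_recode_exposure_rejects_unseen():
    with pytest.raises(ValueError):
        ow.recode_exposure(["sometimes"], "NR_vs_OA")
    with pytest.raises(ValueError):
        ow.recode_exposure([7], "NR_vs_OA")
    with pytest.raises(ValueError):
        ow.recode_exposure([1], "bogus")


def _fixture_panel(n=400, seed=0, risk=(0.25, 0.5)):
    """One country, unit weights, iid design; binary + continuous outcome."""
    rng = np.random.default_rng(seed)
    x = rng.integers(1, 5, n)
    exposed = (x >= 3).astype(float)
    y_cont = 0.3 * exposed + rng.standard_normal(n)
    y_bin = rng.binomial(1, np.where(exposed == 1, risk[1], risk[0]))
    return pd.DataFrame({
        C.COUNTRY: "X", C.STRATUM: "s1",
        C.PSU: [f"p{i}" for i in range(n)], C.WEIGHT: 1.0,
        C.EXPOSURE_ITEM: x,
        C.outcome_column("cont"): y_cont,
        C.outcome_column("bin"): y_bin,
    })


def test_weighted_linear_equals_ols():
    panel = _fixture_panel(seed=1)
    spec = ModelSpec("M1", "cont", "continuous", covariates=[])
    fit = ow.fit_weighted_linear(panel, spec)
    x = ow.recode_exposure(panel[C.EXPOSURE_ITEM], "NR_vs_OA")
    X = np.column_stack([np.ones(len(panel)), x])
    beta = np.linalg.lstsq(X, panel[C.outcome_column("cont")], rcond=None)[0]
    assert fit.b == pytest.approx(beta[1], abs=1e-10)
    assert fit.converged and fit.v > 0


def test_modified_poisson_no_covariates_is_risk_ratio():
    """exp(b) equals the weighted ratio of proportions exactly."""
    rng = np.random.default_rng(2)
    n = 600
    x = rng.integers(1, 5, n)
    exposed = (x >= 3).astype(float)
    y = rng.binomial(1, np.where(exposed == 1, 0.5, 0.25))
    w = rng.uniform(0.5, 3.0, n)
    panel = pd.DataFrame({
        C.COUNTRY: "X", C.STRATUM: "s1",
        C.PSU: [f"p{i}" for i in range(n)], C.WEIGHT: w,
        C.EXPOSURE_ITEM: x, C.outcome_column("bin"): y})
    spec = ModelSpec("M1", "bin", "binary", covariates=[])
    fit = ow.fit_modified_poisson(panel, spec)
    p1 = np.sum(w * y * exposed) / np.sum(w * exposed)
    p0 = np.sum(w * y * (1 - exposed)) / np.sum(w * (1 - exposed))
    assert np.exp(fit.b) == pytest.approx(p1 / p0, rel=1e-6)


def test_risk_ratio_not_invariant_to_outcome_relabeling():
    panel = _fixture_panel(seed=3, risk=(0.2, 0.6))
    spec = ModelSpec("M1", "bin", "binary", covariates=[])
    rr_yes = np.exp(ow.fit_modified_poisson(panel, spec).b)
    flipped = panel.copy()
    col = C.outcome_column("bin")
    flipped[col] = 1 - flipped[col]
    rr_no = np.exp(ow.fit_modified_poisson(flipped, spec).b)
    assert rr_yes != pytest.approx(1.0 / rr_no, rel=1e-3)


def test_design_se_close_to_cluster_bootstrap():
    """Design-based SE within 10% of a cluster-bootstrap SE on a
    2-stratum clustered fixture."""
    rng = np.random.default_rng(4)
    n_psu, per_psu = 30, 12
    rows = []
    for h in range(2):
        for j in range(n_psu):
            u = rng.standard_normal() * 0.3  # cluster effect
            for i in range(per_psu):
                x = rng.integers(1, 5)
                rows.append(dict(
                    country="X", stratum=f"s{h}", psu=f"s{h}p{j}",
                    weight=rng.uniform(0.5, 2.0), item=x,
                    y=0.3 * (x >= 3) + u + rng.standard_normal()))
    df = pd.DataFrame(rows)
    panel = df.rename(columns={
        "stratum": C.STRATUM, "psu": C.PSU, "weight": C.WEIGHT,
        "item": C.EXPOSURE_ITEM, "y": C.outcome_column("cont"),
        "country": C.COUNTRY})
    spec = ModelSpec("M1", "cont", "continuous", covariates=[])
    fit = ow.fit_weighted_linear(panel, spec)

    def slope(d):
        x = (d[C.EXPOSURE_ITEM] >= 3).astype(float)
        X = np.column_stack([np.ones(len(d)), x])
        wts = d[C.WEIGHT].to_numpy()
        y = d[C.outcome_column("cont")].to_numpy()
        Xw = X * wts[:, None]
        return np.linalg.solve(X.T @ Xw, Xw.T @ y)[1]

    boots = []
    psus = {h: [f"s{h}p{j}" for j in range(n_psu)] for h in range(2)}
    grouped = {p: g for p, g in panel.groupby(C.PSU)}
    for _ in range(400):
        parts = []
        for h in range(2):
            pick = rng.choice(psus[h], size=n_psu, replace=True)
            parts.extend(grouped[p] for p in pick)
        boots.append(slope(pd.concat(parts)))
    boot_se = np.std(boots, ddof=1)
    assert np.sqrt(fit.v) == pytest.approx(boot_se, rel=0.10)


def test_null_effect_type_one_error_calibrated():
    """Design-based Wald test of a null exposure effect rejects at about
    the nominal 5% level."""
    rejections = 0
    n_sims = 300
    spec = ModelSpec("M1", "cont", "continuous", covariates=[])
    for s in range(n_sims):
        rng = np.random.default_rng(10_000 + s)
        n = 200
        x = rng.integers(1, 5, n)
        panel = pd.DataFrame({
            C.COUNTRY: "X",
            C.STRATUM: rng.choice(["s1", "s2"], n),
            C.PSU: rng.integers(0, 20, n).astype(str),
            C.WEIGHT: rng.uniform(0.5, 2.0, n),
            C.EXPOSURE_ITEM: x,
            C.outcome_column("cont"): rng.standard_normal(n),
        })
        panel[C.PSU] = panel[C.STRATUM] + "-" + panel[C.PSU]
        fit = ow.fit_weighted_linear(panel, spec)
        rejections += abs(fit.b / np.sqrt(fit.v)) > 1.96
    assert 0.03 <= rejections / n_sims <= 0.07


def test_slope_recovery():
    """Mean estimate over seeds within 2 MC-SEs of the generating slope."""
    est = []
    spec = ModelSpec("M1", "cont", "continuous", covariates=[])
    for s in range(120):
        panel = _fixture_panel(n=300, seed=20_000 + s)
        est.append(ow.fit_weighted_linear(panel, spec).b)
    est = np.array(est)
    mcse = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - 0.3) < 2 * mcse


def test_standardize_effect_rules():
    f = ow.CountryFit("X", "o", "M1", b=0.4, v=0.016, sd_x=0.5, sd_y=2.0,
                      n=100, converged=True)
    b, v = ow.standardize_effect(f, outcome_type="continuous")
    assert b == pytest.approx(0.1)
    assert v == pytest.approx(0.016 / 16.0)
    # binary exposure contrast: sd_x = 1 by convention
    f2 = ow.CountryFit("X", "o", "M1", b=0.4, v=0.016, sd_x=1.0, sd_y=2.0,
                       n=100, converged=True)
    b2, _ = ow.standardize_effect(f2, outcome_type="continuous")
    assert b2 == pytest.approx(0.2)
    # binary outcome: multiply by sd_x only (log-RR scale)
    f3 = ow.CountryFit("X", "o", "M1", b=0.4, v=0.016, sd_x=0.5, sd_y=None,
                       n=100, converged=True)
    b3, v3 = ow.standardize_effect(f3, outcome_type="binary")
    assert b3 == pytest.approx(0.2)
    assert v3 == pytest.approx(0.004)
    with pytest.raises(ValueError):
        ow.standardize_effect(
            ow.CountryFit("X", "o", "M1", 0.4, 0.1, 1.0, 0.0, 10, True),
            outcome_type="continuous")


def test_standardization_scale_equivariant():
    panel = _fixture_panel(seed=5)
    spec = ModelSpec("M1", "cont", "continuous", covariates=[])
    fit1 = ow.fit_weighted_linear(panel, spec)
    scaled = panel.copy()
    scaled[C.outcome_column("cont")] *= 7.0
    fit2 = ow.fit_weighted_linear(scaled, spec)
    b1, _ = ow.standardize_effect(fit1, outcome_type="continuous")
    b2, _ = ow.standardize_effect(fit2, outcome_type="continuous")
    assert b1 == pytest.approx(b2, rel=1e-10)


def test_rank_deficient_design_names_columns():
    panel = _fixture_panel(seed=6)
    panel["dup"] = 1.0  # aliased with the intercept
    spec = ModelSpec("M1", "cont", "continuous", covariates=["dup"])
    # constant covariates are dropped, so force collinearity instead
    panel["dup"] = ow.recode_exposure(panel[C.EXPOSURE_ITEM], "NR_vs_OA")
    with pytest.raises(ValueError, match="aliased"):
        ow.fit_weighted_linear(panel, spec)


def test_run_outcome_wide_identical_imputations(small_panel):
    panel, _ = small_panel
    cfg = ow.AnalysisConfig(outcomes=[("secure_flourishing", "continuous")],
                            models=("M1",))
    single = ow.run_outcome_wide([panel], cfg)
    triple = ow.run_outcome_wide([panel, panel.copy(), panel.copy()], cfg)
    merged = single.merge(triple, on=["country", "outcome", "model"],
                          suffixes=("_1", "_3"))
    assert np.allclose(merged["b_std_1"], merged["b_std_3"])
    assert np.allclose(merged["v_std_1"], merged["v_std_3"])


def test_run_outcome_wide_smoke_all_converge(small_panel):
    panel, _ = small_panel
    cfg = ow.AnalysisConfig(
        outcomes=[("secure_flourishing", "continuous"),
                  ("daily_smoker", "binary")])
    table = ow.run_outcome_wide([panel], cfg)
    assert len(table) == 4 * 2 * 2  # countries x outcomes x models
    assert table["converged"].all()
    assert (table["v_std"] > 0).all()


def test_run_outcome_wide_missing_outcome_row_emitted(small_panel):
    panel, _ = small_panel
    cfg = ow.AnalysisConfig(outcomes=[("not_measured", "continuous")],
                            models=("M1",))
    table = ow.run_outcome_wide([panel], cfg)
    assert len(table) == 4
    assert (~table["converged"]).all()


def test_exposure_scheme_comparison_table(small_panel):
    """All four coding schemes produce a comparable effect table."""
    panel, _ = small_panel
    results = {}
    for scheme in ("NR_vs_OA", "N_vs_ROA", "NRO_vs_A", "continuous"):
        cfg = ow.AnalysisConfig(
            outcomes=[("secure_flourishing", "continuous")],
            models=("M1",), scheme=scheme)
        tab = ow.run_outcome_wide([panel], cfg)
        pooled = ow.pool_countries(tab)
        results[scheme] = pooled["mu"].iloc[0]
    assert len(results) == 4
    assert all(np.isfinite(v) for v in results.values())
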