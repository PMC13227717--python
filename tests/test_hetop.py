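"""Penalized heteroskedastic ordered-probit DIF screening."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

import outcomewide as ow
from outcomewide import columns as C


def _simulate_counts(mu, sigma, thresholds, n, seed=0):
    """Multinomial group x category counts from the HETOP model."""
    rng = np.random.default_rng(seed)
    G = len(mu)
    K = len(thresholds) + 1
    table = np.zeros((G, K))
    for g in range(G):
        z = (np.asarray(thresholds) - mu[g]) / sigma[g]
        cdf = np.concatenate([[0.0], ndtr(z), [1.0]])
        table[g] = rng.multinomial(n, np.diff(cdf))
    return table


THRESH = [-1.0, 0.0, 1.0]


def test_no_dif_null_recovers_common_distribution():
    table = _simulate_counts([0.0] * 5, [1.0] * 5, THRESH, 4000, seed=1)
    fit = ow.fit_hetop(table, penalty=1.0)
    assert fit.converged
    assert np.allclose(fit.mu, 0.0, atol=0.1)
    assert np.allclose(fit.sigma, 1.0, atol=0.12)
    assert (np.diff(fit.thresholds) > 0).all()


def test_large_penalty_shrinks_all_deviations():
    table = _simulate_counts([0.4, -0.4, 0.0], [1.3, 0.8, 1.0],
                             THRESH, 2000, seed=2)
    fit = ow.fit_hetop(table, penalty=1e6)
    assert np.max(np.abs(fit.mu)) < 0.01
    assert np.max(np.abs(np.log(fit.sigma))) < 0.01


def test_unpenalized_two_group_matches_saturated_mle():
    """With K=3 and two groups, the unpenalized common-threshold fit is a
    reparameterization of the saturated multinomial: fitted cell
    probabilities equal the observed proportions (the group-wise MLE)."""
    table = np.array([[300.0, 500.0, 200.0],
                      [150.0, 450.0, 400.0]])
    fit = ow.fit_hetop(table[:, :], penalty=0.0)
    z = (fit.thresholds[None, :] - fit.mu[:, None]) / fit.sigma[:, None]
    cdf = np.concatenate([np.zeros((2, 1)), ndtr(z), np.ones((2, 1))], axis=1)
    probs = np.diff(cdf, axis=1)
    observed = table / table.sum(axis=1, keepdims=True)
    assert np.allclose(probs, observed, atol=2e-4)


def test_scale_dif_recovered():
    """A low-discrimination group (sigma = 2) gets the largest fitted
    sigma, above 1.5 at moderate penalty."""
    sigma = [1.0] * 7 + [2.0]
    table = _simulate_counts([0.0] * 8, sigma, THRESH, 3000, seed=3)
    fit = ow.fit_hetop(table, penalty=1.0)
    assert np.argmax(fit.sigma) == 7
    assert fit.sigma[7] > 1.5


def test_identification_centering():
    table = _simulate_counts([0.5, -0.2, 0.1], [1.2, 0.9, 1.0],
                             THRESH, 2000, seed=4)
    fit = ow.fit_hetop(table, penalty=0.5)
    w = fit.n_g / fit.n_g.sum()
    assert np.sum(w * fit.mu) == pytest.approx(0.0, abs=1e-8)
    assert np.sum(w * np.log(fit.sigma)) == pytest.approx(0.0, abs=1e-8)


def test_degenerate_group_dropped():
    table = np.array([[100.0, 200.0, 100.0],
                      [0.0, 400.0, 0.0],
                      [150.0, 150.0, 100.0]])
    table[1] = [0.0, 400.0, 0.0]
    fit = ow.fit_hetop(pd.DataFrame(table, index=["a", "b", "c"]))
    assert fit.dropped_groups == ["b"]
    assert fit.groups == ["a", "c"]


def test_k2_rejected():
    with pytest.raises(ValueError):
        ow.fit_hetop(np.array([[10.0, 20.0], [20.0, 10.0]]))


def test_penalty_path_monotone_shrinkage():
    table = _simulate_counts([0.5, -0.5, 0.2, -0.2], [1.0, 1.0, 1.4, 0.8],
                             THRESH, 3000, seed=5)
    path = ow.penalty_path(table, [0.0, 1.0, 10.0, 100.0], compute_se=False)
    max_dev = [np.max(np.abs(f.mu)) for f in path]
    for a, b in zip(max_dev, max_dev[1:]):
        assert b <= a + 1e-4
    # penalized log-likelihood nonincreasing in penalty at the optimum
    # (likelihood part only can rise; the full objective cannot)
    assert path[-1].penalized_loglik <= path[0].penalized_loglik + 1e-6


def test_null_path_stays_near_zero():
    table = _simulate_counts([0.0] * 6, [1.0] * 6, THRESH, 4000, seed=6)
    path = ow.penalty_path(table, [0.5, 5.0, 50.0], compute_se=False)
    for f in path:
        assert np.max(np.abs(f.mu)) < 0.06
        assert np.max(np.abs(np.log(f.sigma))) < 0.08


def test_flag_dif_detects_injected_location_shift():
    """A +0.5 location shift in one of 8 groups at n = 2000 is flagged in
    nearly every replicate, and it carries the largest |location|."""
    hits = 0
    n_seeds = 25
    for s in range(n_seeds):
        mu = [0.0] * 8
        mu[3] = 0.5
        table = _simulate_counts(mu, [1.0] * 8, THRESH, 2000, seed=100 + s)
        path = ow.penalty_path(table, [0.5])
        flags = ow.flag_dif(path, 0.5, z_threshold=2.0)
        hits += bool(flags.table.loc[3, "uniform_dif"])
        assert flags.table["mu"].abs().idxmax() == 3
    assert hits >= int(0.95 * n_seeds)


def test_flag_dif_null_false_positive_rate():
    """On a no-DIF fixture the per-group flag rate stays near the nominal
    two-sided level of the z threshold."""
    flagged, total = 0, 0
    n_seeds = 30
    for s in range(n_seeds):
        table = _simulate_counts([0.0] * 6, [1.0] * 6, THRESH, 2000,
                                 seed=500 + s)
        flags = ow.flag_dif(ow.penalty_path(table, [0.5]), 0.5,
                            z_threshold=2.0)
        flagged += int(flags.table["uniform_dif"].sum())
        total += 6
    rate = flagged / total
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


def test_flag_dif_detects_scale_shift():
    sigma = [1.0] * 6
    sigma[2] = np.exp(1.0)  # log-scale shift +1
    table = _simulate_counts([0.0] * 6, sigma, THRESH, 3000, seed=7)
    path = ow.penalty_path(table, [0.5])
    flags = ow.flag_dif(path, 0.5)
    assert bool(flags.table.loc[2, "nonuniform_dif"])
    assert flags.table.loc[2, "sigma"] > 1.5


def test_flags_deterministic():
    table = _simulate_counts([0.3, 0.0, -0.3], [1.0, 1.0, 1.0],
                             THRESH, 1500, seed=8)
    a = ow.flag_dif(ow.penalty_path(table, [1.0]), 1.0).table
    b = ow.flag_dif(ow.penalty_path(table, [1.0]), 1.0).table
    pd.testing.assert_frame_equal(a, b)


def test_expected_item_response_properties():
    table = _simulate_counts([0.0, 0.6], [1.0, 2.0], THRESH, 4000, seed=9)
    fit = ow.fit_hetop(table, penalty=0.1)
    grid = np.linspace(-3, 3, 61)
    er0 = ow.expected_item_response(fit, fit.groups[0], grid)
    assert (np.diff(er0) >= -1e-12).all()  # monotone in the latent
    # symmetric thresholds, mu = 0: ER(0) = (1 + K)/2
    sym = ow.HetopFit(groups=["g"], k_categories=4,
                      thresholds=np.array([-1.0, 0.0, 1.0]),
                      mu=np.array([0.0]), sigma=np.array([1.0]),
                      se_mu=np.zeros(1), se_log_sigma=np.zeros(1),
                      penalty=0.0, penalized_loglik=0.0, converged=True,
                      n_g=np.array([1.0]))
    assert ow.expected_item_response(sym, "g", np.array([0.0]))[0] == \
        pytest.approx(2.5)
    # larger sigma flattens the curve
    flat = ow.expected_item_response(fit, fit.groups[1], grid)
    assert np.max(np.diff(flat)) < np.max(np.diff(er0))


def test_counts_from_panel_and_injected_dif_recovery(small_panel):
    """Scale DIF injected by the generator is recovered by the fit."""
    panel, truth = small_panel
    shifted = ow.inject_dif(panel, "mastery", {"C03": (0.0, 0.7)},
                            seed=10, truth=truth)
    counts = ow.counts_from_panel(shifted, C.outcome_column("mastery"))
    assert counts.shape[0] == 4
    fit = ow.fit_hetop(counts, penalty=0.5)
    i = fit.group_index("C03")
    assert fit.sigma[i] == max(fit.sigma)
    assert fit.sigma[i] > 1.3
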