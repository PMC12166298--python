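"""Power simulator: model fit, effect injection, ANOVA, power curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibromarker import (
    EffectSpec,
    ExpressionMatrix,
    LogNormalModel,
    anova_pvalue,
    fit_lognormal,
    nearest_psd,
    power_curve,
    required_n,
    simulate_two_groups,
)
from fibromarker.power import _two_group_f_pvalues, anova_sweep, cohens_d


def analytic_power(d, n, alpha=0.05):
    """Closed-form two-sided two-sample t power at noncentrality d*sqrt(n/2)."""
    df = 2 * n - 2
    ncp = d * np.sqrt(n / 2.0)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)


# ---------------------------------------------------------------- model fit

def test_fit_recovers_known_parameters():
    rng = np.random.default_rng(5)
    mu = np.array([8.0, 7.5, 9.0])
    corr = np.array([[1.0, 0.7, 0.2], [0.7, 1.0, 0.1], [0.2, 0.1, 1.0]])
    sd = np.array([1.0, 0.8, 1.2])
    sigma = corr * np.outer(sd, sd)
    X = rng.multivariate_normal(mu, sigma, size=500)
    m = ExpressionMatrix(
        pd.DataFrame(np.exp2(X.T), index=["a", "b", "c"],
                     columns=[f"s{i}" for i in range(500)]),
        scale="tpm",
    )
    model = fit_lognormal(m)
    np.testing.assert_allclose(model.mu, mu, atol=0.12)
    est_corr = model.sigma / np.sqrt(np.outer(np.diag(model.sigma), np.diag(model.sigma)))
    np.testing.assert_allclose(est_corr, corr, atol=0.1)


def test_fit_hand_computed_covariance():
    vals = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 4.0, 4.0]])
    m = ExpressionMatrix(
        pd.DataFrame(vals, index=["a", "b"], columns=list("wxyz")), scale="log"
    )
    model = fit_lognormal(m)
    np.testing.assert_allclose(model.mu, [2.5, 3.0])
    np.testing.assert_allclose(model.sigma, np.cov(vals, ddof=1), atol=1e-12)
    assert not model.repair_applied


def test_fit_requires_three_samples():
    m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"]))
    with pytest.raises(ValueError):
        fit_lognormal(m)


def test_nearest_psd_repairs_indefinite_matrix():
    bad = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
    assert np.linalg.eigvalsh(bad).min() < -1e-3
    fixed, repaired = nearest_psd(bad)
    assert repaired
    assert np.linalg.eigvalsh(fixed).min() >= -1e-10
    good = np.eye(2)
    same, flag = nearest_psd(good)
    assert not flag
    np.testing.assert_array_equal(same, good)


# ---------------------------------------------------------------- simulation

def _single_gene_model(sd=1.0):
    return LogNormalModel(genes=["GREM1"], mu=np.array([8.0]), sigma=np.array([[sd**2]]))


def test_null_effect_groups_exchangeable():
    model = _single_gene_model()
    rejections = 0
    reps = 2000
    rng_seeds = np.random.SeedSequence(0).spawn(reps)
    for s in rng_seeds:
        a, b = simulate_two_groups(model, EffectSpec("GREM1", d=0.0), 5, seed=s)
        p = anova_pvalue(np.log2(a.iloc[0] + 1), np.log2(b.iloc[0] + 1))
        rejections += p < 0.05
    rate = rejections / reps
    assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / reps) + 0.005


def test_effect_realizes_as_standardized_mean_difference():
    model = _single_gene_model(sd=1.3)
    a, b = simulate_two_groups(model, EffectSpec("GREM1", d=1.0), 2000, seed=10)
    la, lb = np.log2(a.iloc[0].to_numpy()), np.log2(b.iloc[0].to_numpy())
    assert abs(cohens_d(lb, la) - 1.0) < 0.05


def test_propagation_respects_correlation_threshold():
    sigma = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
    model = LogNormalModel(genes=["t", "hi", "lo"], mu=np.zeros(3), sigma=sigma)
    spec = EffectSpec("t", d=2.0, corr_threshold=0.8, propagate=True)
    from fibromarker.power import _shifted_mu

    mu_b = _shifted_mu(model, spec)
    assert mu_b[0] == pytest.approx(2.0)
    assert mu_b[1] == pytest.approx(2.0)
    assert mu_b[2] == pytest.approx(0.0)
    # boundary: threshold 1.0 shifts only the target (self-correlation = 1)
    mu_only = _shifted_mu(model, EffectSpec("t", d=2.0, corr_threshold=1.0))
    np.testing.assert_allclose(mu_only, [2.0, 0.0, 0.0])


def test_simulation_seeded_determinism():
    model = _single_gene_model()
    a1, b1 = simulate_two_groups(model, EffectSpec("GREM1", d=1.0), 10, seed=3)
    a2, b2 = simulate_two_groups(model, EffectSpec("GREM1", d=1.0), 10, seed=3)
    assert a1.equals(a2) and b1.equals(b2)
    with pytest.raises(KeyError):
        simulate_two_groups(model, EffectSpec("LY96", d=1.0), 5)


# ---------------------------------------------------------------- ANOVA

def test_anova_identical_groups():
    with pytest.warns(UserWarning, match="degenerate"):
        assert anova_pvalue([1, 1, 1], [1, 1, 1]) == 1.0
    assert anova_pvalue([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_anova_f_equals_t_squared(rng):
    for _ in range(50):
        a = rng.normal(size=6)
        b = rng.normal(size=8) + 0.5
        f, p_f = stats.f_oneway(a, b)
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-9)
        assert anova_pvalue(a, b) == pytest.approx(p_t, rel=1e-9)


def test_anova_degenerate_separation():
    assert anova_pvalue([0.0, 0.0], [1.0, 1.0]) < 0.01


def test_vectorized_f_matches_scipy(rng):
    a = rng.normal(size=(7, 40))
    b = rng.normal(size=(5, 40)) + 0.3
    p_vec = _two_group_f_pvalues(a, b)
    p_ref = np.array([stats.f_oneway(a[:, j], b[:, j])[1] for j in range(40)])
    np.testing.assert_allclose(p_vec, p_ref, rtol=1e-10)


def test_anova_sweep_flags_shifted_gene():
    model = LogNormalModel(
        genes=["t", "n1", "n2"], mu=np.array([8.0, 6.0, 7.0]), sigma=np.eye(3)
    )
    a, b = simulate_two_groups(model, EffectSpec("t", d=3.0, propagate=False), 30, seed=2)
    p = anova_sweep(a, b)
    assert p["t"] < 0.001
    assert (p[["n1", "n2"]] > 0.001).all()


# ---------------------------------------------------------------- power

def test_power_curve_type_one_error_at_null():
    model = _single_gene_model()
    curve = power_curve(model, EffectSpec("GREM1", d=0.0), n_reps=2000, seed=0)
    se = np.sqrt(0.05 * 0.95 / 2000)
    assert (np.abs(curve.power - 0.05) < 2 * se + 0.005).all()


def test_power_matches_closed_form_at_d_one():
    model = _single_gene_model()
    curve = power_curve(model, EffectSpec("GREM1", d=1.0), n_reps=1000, seed=1)
    for n, pw in zip(curve.n_grid, curve.power):
        assert pw == pytest.approx(analytic_power(1.0, n), abs=0.03)


def test_power_monotone_in_n_and_d():
    model = _single_gene_model()
    c1 = power_curve(model, EffectSpec("GREM1", d=0.8), n_reps=1500, seed=4)
    tol = 2 * np.sqrt(0.25 / 1500)
    assert (np.diff(c1.power) > -2 * tol).all()
    c2 = power_curve(model, EffectSpec("GREM1", d=1.4), n_reps=1500, seed=4)
    assert (c2.power >= c1.power - 2 * tol).all()


def test_power_curve_determinism_and_validation():
    model = _single_gene_model()
    spec = EffectSpec("GREM1", d=0.5)
    c1 = power_curve(model, spec, n_reps=200, seed=9)
    c2 = power_curve(model, spec, n_reps=200, seed=9)
    np.testing.assert_array_equal(c1.power, c2.power)
    with pytest.raises(ValueError):
        power_curve(model, spec, n_reps=50)
    with pytest.raises(ValueError):
        power_curve(model, spec, n_grid=(10, 10, 20), n_reps=200)


def test_required_n_rules():
    model = _single_gene_model()
    big = power_curve(model, EffectSpec("GREM1", d=3.0), n_reps=1000, seed=2)
    assert required_n(big) == big.n_grid[0]
    null = power_curve(model, EffectSpec("GREM1", d=0.0), n_reps=1000, seed=2)
    assert required_n(null) is None


def test_required_n_consistent_with_analytic_oracle():
    """At d=1 the Monte-Carlo required n agrees with the closed form, up to
    grid values whose analytic power sits within Monte-Carlo error of the
    75% target."""
    model = _single_gene_model()
    curve = power_curve(model, EffectSpec("GREM1", d=1.0), n_reps=4000, seed=6)
    grid = curve.n_grid
    mc_n = required_n(curve, 0.75)
    exact = [n for n in grid if analytic_power(1.0, n) >= 0.75]
    oracle_n = exact[0] if exact else None
    assert mc_n is not None and oracle_n is not None
    if mc_n != oracle_n:
        se = np.sqrt(0.75 * 0.25 / curve.n_reps)
        boundary = min(mc_n, oracle_n)
        assert abs(analytic_power(1.0, boundary) - 0.75) < 3 * se
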