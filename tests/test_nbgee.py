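"""Negative binomial fitting, spatial working correlation, sandwich, Wald."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import optimize, stats

from trdspat.nbgee import (
    ModelSpec,
    RankDeficientError,
    SpatialKernel,
    SpatialWeights,
    estimate_spatial_correlation,
    fit_nb,
    joint_test,
    nb_loglik,
    sandwich_covariance,
    wald_tests,
)
from trdspat.synthetic_tracts import SyntheticConfig, generate
from trdspat.validation import lattice_queen_weights
from conftest import make_tract


INTERCEPT_ONLY = ModelSpec(covariates=(), include_ruca=False)


def small_dataset(n=50, seed=0):
    cfg = SyntheticConfig(lattice=(10, 5), seed=seed, spatial_sd=0.0)
    tracts, _, _ = generate(cfg)
    return tracts[:n]


# ---------------------------------------------------------------------------
# fit_nb


def test_intercept_only_closed_form():
    # every tract: count 2, population 1000 -> offset 0, intercept = log 2
    tracts = [make_tract(i, population=1000, retailer_count=2) for i in range(20)]
    fit = fit_nb(INTERCEPT_ONLY, tracts)
    assert fit.converged
    assert fit.coef("intercept") == pytest.approx(math.log(2.0), abs=1e-6)


def test_fit_matches_brute_force_likelihood_maximization():
    tracts = small_dataset(50, seed=3)
    spec = ModelSpec(covariates=("pct_poverty", "pct_asian"), include_ruca=False)
    fit = fit_nb(spec, tracts)

    X = np.column_stack(
        [
            np.ones(50),
            np.array([t.pct_poverty for t in tracts]) / 10.0,
            np.array([t.pct_asian for t in tracts]) / 10.0,
        ]
    )
    y = np.array([t.retailer_count for t in tracts], dtype=float)
    off = np.log(np.array([t.population for t in tracts]) / 1000.0)

    def negll(par):
        beta, ltheta = par[:-1], par[-1]
        mu = np.exp(X @ beta + off)
        return -nb_loglik(y, mu, math.exp(ltheta))

    res = optimize.minimize(
        negll,
        x0=np.concatenate([fit.beta + 0.3, [0.0]]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    assert res.success
    np.testing.assert_allclose(fit.beta, res.x[:-1], atol=1e-4)
    assert fit.dispersion == pytest.approx(math.exp(res.x[-1]), abs=1e-3 * fit.dispersion)


def test_fit_cross_checks_against_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    tracts = small_dataset(50, seed=9)
    spec = ModelSpec(covariates=("pct_poverty",), include_ruca=False)
    fit = fit_nb(spec, tracts)
    X = np.column_stack([np.ones(50), np.array([t.pct_poverty for t in tracts]) / 10.0])
    y = np.array([t.retailer_count for t in tracts], dtype=float)
    off = np.log(np.array([t.population for t in tracts]) / 1000.0)
    glm = sm.GLM(
        y, X, family=sm.families.NegativeBinomial(alpha=1.0 / fit.dispersion), offset=off
    ).fit()
    np.testing.assert_allclose(fit.beta, glm.params, atol=2e-5)


def test_poisson_limit_at_huge_theta():
    sm = pytest.importorskip("statsmodels.api")
    cfg = SyntheticConfig(lattice=(8, 8), seed=4, spatial_sd=0.0, theta=1e6)
    tracts, _, _ = generate(cfg)
    spec = ModelSpec(
        covariates=("pct_poverty", "pct_black"), include_ruca=False, fixed_theta=1e6
    )
    fit = fit_nb(spec, tracts)
    X = np.column_stack(
        [
            np.ones(len(tracts)),
            np.array([t.pct_poverty for t in tracts]) / 10.0,
            np.array([t.pct_black for t in tracts]) / 10.0,
        ]
    )
    y = np.array([t.retailer_count for t in tracts], dtype=float)
    off = np.log(np.array([t.population for t in tracts]) / 1000.0)
    pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
    np.testing.assert_allclose(fit.beta, pois.params, atol=1e-3)


def test_offset_shift_moves_only_intercept():
    tracts = small_dataset(60, seed=6)
    spec = ModelSpec(covariates=("pct_poverty",), include_ruca=False)
    fit1 = fit_nb(spec, tracts)
    scaled = [replace(t, population=t.population * 10) for t in tracts]
    fit2 = fit_nb(spec, scaled)
    assert fit2.coef("intercept") - fit1.coef("intercept") == pytest.approx(
        -math.log(10.0), abs=1e-6
    )
    assert fit2.coef("pct_poverty") == pytest.approx(fit1.coef("pct_poverty"), abs=1e-6)


def test_likelihood_at_optimum_beats_perturbations(small_fit):
    # ascent sanity: the reported optimum dominates nearby points
    fit = small_fit
    rng = np.random.default_rng(0)
    for _ in range(10):
        beta = fit.beta + rng.normal(scale=0.02, size=fit.beta.size)
        mu = np.exp(fit.X @ beta + fit.offset)
        assert nb_loglik(fit.y, mu, fit.dispersion) <= fit.loglik + 1e-9


def test_rank_deficient_design_names_columns():
    tracts = small_dataset(40, seed=1)
    for t in tracts:
        t.pct_hispanic = 2.0 * t.pct_poverty  # force exact collinearity
    spec = ModelSpec(covariates=("pct_poverty", "pct_hispanic"), include_ruca=False)
    with pytest.raises(RankDeficientError) as err:
        fit_nb(spec, tracts)
    assert any("pct" in c for c in err.value.columns)


def test_all_zero_counts_rejected():
    tracts = [make_tract(i, retailer_count=0) for i in range(10)]
    with pytest.raises(ValueError, match="zero"):
        fit_nb(INTERCEPT_ONLY, tracts)


# ---------------------------------------------------------------------------
# spatial correlation estimation


def lattice_xy(nx, ny):
    return np.array([[i + 0.5, j + 0.5] for i in range(nx) for j in range(ny)])


def test_adjacency_rho_small_under_independence():
    rng = np.random.default_rng(8)
    w = lattice_queen_weights(30, 30)
    resid = rng.standard_normal(900)
    k = estimate_spatial_correlation(resid, w, kind="adjacency")
    assert k.kind == "adjacency"
    assert 0.0 <= k.rho < 0.05


def test_exponential_range_recovery_from_gp_residuals():
    # median phi over replicates should bracket the generating range
    from trdspat.validation import phi_recovery_study

    res = phi_recovery_study(n_reps=40, phi_true=2.0, seed=12)
    assert 1.5 <= res["median_phi"] <= 2.5


def test_zero_residuals_rejected():
    w = lattice_queen_weights(5, 5)
    with pytest.raises(ValueError):
        estimate_spatial_correlation(np.zeros(25), w)


def test_fallback_to_adjacency_when_bins_sparse(caplog):
    import logging

    rng = np.random.default_rng(1)
    w = lattice_queen_weights(4, 4)  # 16 tracts: too few pairs per bin
    with caplog.at_level(logging.WARNING):
        k = estimate_spatial_correlation(rng.standard_normal(16), w, min_pairs=1000)
    assert k.kind == "adjacency"


# ---------------------------------------------------------------------------
# sandwich covariance


def test_identity_kernel_reduces_to_hc0(small_fit):
    fit = small_fit
    w = SpatialWeights.from_centroids(fit.tract_ids, np.zeros((len(fit.tract_ids), 2)))
    V = sandwich_covariance(fit, w, SpatialKernel(kind="independence"))
    # independently coded HC0: A^-1 (X' diag(s^2) X) A^-1
    mu, th = fit.fitted_mu, fit.dispersion
    wts = mu / (1 + mu / th)
    A = fit.X.T @ (fit.X * wts[:, None])
    s = (fit.y - mu) / (1 + mu / th)
    B = fit.X.T @ np.diag(s**2) @ fit.X
    Ainv = np.linalg.inv(A)
    np.testing.assert_allclose(V, Ainv @ B @ Ainv, atol=1e-10)


def test_two_tract_toy_matches_hand_evaluation():
    # hand-built fit: 2 tracts, intercept + one covariate, R off-diagonal 0.5
    from trdspat.nbgee import FitResult

    X = np.array([[1.0, 0.0], [1.0, 1.0]])
    y = np.array([3.0, 1.0])
    mu = np.array([2.0, 2.0])
    theta = 4.0
    wts = mu / (1 + mu / theta)  # [4/3, 4/3]
    A = X.T @ (X * wts[:, None])
    fit = FitResult(
        names=["intercept", "x"],
        beta=np.array([math.log(2.0), 0.0]),
        model_cov=np.linalg.inv(A),
        sandwich_cov=None,
        dispersion=theta,
        fitted_mu=mu,
        deviance_residuals=np.zeros(2),
        converged=True,
        n_iter=1,
        loglik=0.0,
        tract_ids=["a", "b"],
        X=X,
        y=y,
        offset=np.zeros(2),
    )
    w = SpatialWeights.from_centroids(["a", "b"], np.array([[0.0, 0.0], [1.0, 0.0]]))
    kernel = SpatialKernel(kind="exponential", phi=1.0 / math.log(2.0), sill=0.5)
    # kernel correlation at distance 1: 0.5 * exp(-log 2) = 0.25
    V = sandwich_covariance(fit, w, kernel)

    s = (y - mu) / (1 + mu / theta)  # [2/3, -2/3]
    disp = np.mean(s**2 / wts)
    sig = np.sqrt(disp * wts)
    R01 = 0.5 * math.exp(-1.0 * math.log(2.0))
    Bhand = np.empty((2, 2))
    M = np.array([[s[0] ** 2, sig[0] * sig[1] * R01], [sig[0] * sig[1] * R01, s[1] ** 2]])
    Bhand = X.T @ M @ X
    Ainv = np.linalg.inv(A)
    np.testing.assert_allclose(V, Ainv @ Bhand @ Ainv, atol=1e-12)


def test_positive_correlation_widens_clustered_covariate_se(small_fit):
    fit = small_fit
    cents = lattice_xy(10, 10)
    w = SpatialWeights.from_centroids(fit.tract_ids, cents)
    V_ind = sandwich_covariance(fit, w, SpatialKernel(kind="independence"))
    V_sp = sandwich_covariance(
        fit, w, SpatialKernel(kind="exponential", phi=2.0, sill=0.3)
    )
    i = fit.names.index("pct_poverty")  # spatially smooth covariate
    assert V_sp[i, i] >= V_ind[i, i]
    j = fit.names.index("intercept")
    assert V_sp[j, j] >= V_ind[j, j]


def test_sandwich_requires_convergence(small_fit):
    import copy

    bad = copy.copy(small_fit)
    bad.converged = False
    w = SpatialWeights.from_centroids(bad.tract_ids, np.zeros((len(bad.tract_ids), 2)))
    with pytest.raises(ValueError):
        sandwich_covariance(bad, w, SpatialKernel(kind="independence"))


# ---------------------------------------------------------------------------
# Wald tests


def test_wald_zero_coefficient_gives_p_one(small_fit):
    import copy

    fit = copy.copy(small_fit)
    fit.beta = fit.beta.copy()
    fit.beta[1] = 0.0
    tab = wald_tests(fit, "sandwich")
    row = tab[tab.term == fit.names[1]].iloc[0]
    assert row.z == 0.0
    assert row.p == 1.0


def test_single_coefficient_joint_test_is_z_squared(small_fit):
    tab = wald_tests(small_fit, "sandwich")
    term = "pct_poverty"
    z = float(tab[tab.term == term].z.iloc[0])
    stat, df, p = joint_test(small_fit, [term], "sandwich")
    assert df == 1
    assert stat == pytest.approx(z**2, rel=1e-10)
    assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-9)


def test_joint_test_matches_quadratic_form_oracle(small_fit):
    terms = ["pct_poverty", "pct_black", "pct_asian"]
    stat, df, p = joint_test(small_fit, terms, "sandwich")
    idx = [small_fit.names.index(t) for t in terms]
    b = small_fit.beta[idx]
    V = small_fit.sandwich_cov[np.ix_(idx, idx)]
    oracle = float(b @ np.linalg.inv(V) @ b)
    assert df == 3
    assert stat == pytest.approx(oracle, rel=1e-9)
    assert p == pytest.approx(float(stats.chi2.sf(oracle, 3)), rel=1e-9)


# ---------------------------------------------------------------------------
# design handling


def test_absent_ruca_level_dummy_dropped():
    cfg = SyntheticConfig(lattice=(10, 10), seed=2, ruca_layout="no_small_town")
    tracts, _, _ = generate(cfg)
    fit = fit_nb(ModelSpec(), tracts)
    assert "ruca_SmallTown" not in fit.names
    assert "ruca_Rural" in fit.names
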