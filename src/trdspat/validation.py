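"""Replicate studies validating the estimators on synthetic truth.

These harnesses drive the generator and the model end to end: coefficient
recovery and confidence-interval coverage under spatial correlation,
type-I error of the Moran permutation test, recovery of the residual
correlation range, and sign recovery for the poverty-by-Appalachia
interaction.  They are shared by the test suite and the acceptance script.

Truth for recovery and coverage is the *marginal* coefficient vector: the
generator's multiplicative lognormal random effect shifts the
population-averaged intercept by ``spatial_sd**2 / 2`` relative to the
latent intercept while leaving slopes untouched (covariate fields are
drawn independently of the random effect), and the marginal model targets
exactly that population-averaged rate.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from trdspat.diagnostics import morans_i
from trdspat.nbgee import (
    ModelSpec,
    SpatialWeights,
    estimate_spatial_correlation,
    fit_nb,
    sandwich_covariance,
    spatial_kernel_for_fit,
)
from trdspat.synthetic_tracts import SyntheticConfig, generate, scenario_library


def _truth_vector(names: list[str], truth: dict) -> np.ndarray:
    return np.array([truth["beta_marginal"][n] for n in names])


def fit_one(config: SyntheticConfig, spec: ModelSpec | None = None):
    """Generate one dataset, fit it, and attach the spatial sandwich.

    Returns (fit, truth, kernel); ``fit.sandwich_cov`` holds the
    spatially adjusted covariance, the independence (HC0) covariance is
    returned alongside.
    """
    spec = spec or ModelSpec()
    tracts, _, truth = generate(config)
    fit = fit_nb(spec, tracts)
    ids = [t.tract_id for t in tracts]
    cents = np.array([t.centroid for t in tracts])
    weights = SpatialWeights.from_centroids(ids, cents)
    kernel = spatial_kernel_for_fit(fit, weights)
    hc0 = fit.sandwich_cov
    fit.sandwich_cov = sandwich_covariance(fit, weights, kernel)
    return fit, truth, kernel, hc0


def recovery_coverage_study(
    n_reps: int = 200,
    config: SyntheticConfig | None = None,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Coefficient recovery and CI coverage over replicate synthetic states.

    Returns mean estimates, Monte-Carlo SEs, the recovery z-score per
    coefficient (|mean - truth| / MC SE), and pooled coverage of
    ``level`` Wald intervals under the spatial sandwich and under the
    independence (HC0) covariance.
    """
    config = config or scenario_library()["paperlike"]
    zc = stats.norm.ppf(0.5 + level / 2.0)
    betas, covers_sw, covers_ind = [], [], []
    names = None
    truth_vec = None
    for r in range(n_reps):
        cfg = replace(config, seed=seed + r)
        fit, truth, _, hc0 = fit_one(cfg)
        if names is None:
            names = fit.names
            truth_vec = _truth_vector(names, truth)
        betas.append(fit.beta)
        se_sw = np.sqrt(np.diag(fit.sandwich_cov))
        se_ind = np.sqrt(np.diag(hc0))
        covers_sw.append(np.abs(fit.beta - truth_vec) <= zc * se_sw)
        covers_ind.append(np.abs(fit.beta - truth_vec) <= zc * se_ind)
    B = np.array(betas)
    mean_beta = B.mean(axis=0)
    mc_se = B.std(axis=0, ddof=1) / np.sqrt(n_reps)
    return {
        "names": names,
        "truth": truth_vec,
        "mean_beta": mean_beta,
        "mc_se": mc_se,
        "recovery_z": np.abs(mean_beta - truth_vec) / mc_se,
        "coverage_sandwich": float(np.mean(covers_sw)),
        "coverage_independence": float(np.mean(covers_ind)),
        "coverage_sandwich_by_coef": np.mean(covers_sw, axis=0),
        "coverage_independence_by_coef": np.mean(covers_ind, axis=0),
        "n_reps": n_reps,
    }


def lattice_queen_weights(nx: int = 30, ny: int = 30) -> SpatialWeights:
    """Queen contiguity for an nx-by-ny unit lattice, built directly."""
    from scipy import sparse

    ids = [f"{i:06d}" for i in range(nx * ny)]
    rows, cols = [], []
    for cx in range(nx):
        for cy in range(ny):
            i = cx * ny + cy
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    if dx == dy == 0:
                        continue
                    qx, qy = cx + dx, cy + dy
                    if 0 <= qx < nx and 0 <= qy < ny:
                        rows.append(i)
                        cols.append(qx * ny + qy)
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(nx * ny, nx * ny))
    xy = np.array([[cx + 0.5, cy + 0.5] for cx in range(nx) for cy in range(ny)])
    return SpatialWeights(ids=ids, adjacency=adj, centroids=xy)


def moran_type1_study(
    n_reps: int = 200,
    nx: int = 30,
    ny: int = 30,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the Moran permutation test on i.i.d. residuals."""
    weights = lattice_queen_weights(nx, ny)
    rng = np.random.default_rng(seed)
    rejections = 0
    for r in range(n_reps):
        resid = rng.standard_normal(nx * ny)
        res = morans_i(
            resid, weights, mode="permutation", n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        if res.p_value <= alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def phi_recovery_study(
    n_reps: int = 100, nx: int = 30, ny: int = 30, phi_true: float = 2.0, seed: int = 0
) -> dict:
    """Recovery of the exponential correlation range from pure GP residuals."""
    from trdspat.synthetic_tracts import _gaussian_field

    xy = np.array([[cx + 0.5, cy + 0.5] for cx in range(nx) for cy in range(ny)])
    ids = [f"{i:06d}" for i in range(nx * ny)]
    weights = SpatialWeights.from_centroids(ids, xy)
    rng = np.random.default_rng(seed)
    phis = []
    for r in range(n_reps):
        z = _gaussian_field(rng, xy, 1.0, phi_true)
        k = estimate_spatial_correlation(z, weights)
        phis.append(k.phi)
    return {"median_phi": float(np.median(phis)), "phi_true": phi_true, "n_reps": n_reps}


def interaction_sign_study(n_reps: int = 100, seed: int = 0) -> dict:
    """Fraction of replicates recovering the interaction coefficient's sign."""
    config = scenario_library()["appalachia_interaction"]
    spec = ModelSpec(
        include_appalachia=True, interactions=(("pct_poverty", "appalachia"),)
    )
    true_sign = np.sign(config.beta["pct_poverty:appalachia"])
    hits = 0
    for r in range(n_reps):
        cfg = replace(config, seed=seed + r)
        tracts, _, _ = generate(cfg)
        fit = fit_nb(spec, tracts)
        if np.sign(fit.coef("pct_poverty:appalachia")) == true_sign:
            hits += 1
    return {"sign_recovery_rate": hits / n_reps, "n_reps": n_reps}
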