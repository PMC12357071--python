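"""Negative binomial regression with a spatially adjusted sandwich covariance.

The mean model is marginal: counts :math:`Y_i` of tobacco retailers in
tract *i* follow a negative binomial distribution with

.. math:: \\log \\mu_i = x_i^\\top \\beta + \\log(P_i / 1000),

so :math:`\\exp(\\beta)` multiplies the retailer rate per 1000 residents.
Percentage covariates are divided by 10 before fitting, making each slope
the change in mean log density for a 10-percentage-point increase.  The
variance is :math:`\\mu + \\mu^2/\\theta` (NB2), with the dispersion
:math:`\\theta` profiled by maximum likelihood.

Point estimates come from independence maximum likelihood (iteratively
reweighted least squares with step-halving).  Residual spatial dependence
among tracts — densities of nearby tracts are more alike than the
covariates explain — is handled in a generalized-estimating-equation
fashion: a working spatial correlation is fitted to the Pearson residuals
and plugged into the middle of a sandwich covariance
:math:`A^{-1} B A^{-1}`, widening standard errors that independence-based
inference would understate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, sparse, special
from scipy.spatial.distance import pdist, squareform
from shapely.strtree import STRtree

from trdspat.tract_data import RucaLevel, TractRecord

logger = logging.getLogger(__name__)

RUCA_DUMMY_ORDER = (RucaLevel.MICROPOLITAN, RucaLevel.SMALL_TOWN, RucaLevel.RURAL)


class RankDeficientError(ValueError):
    """Design matrix is not full column rank."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"collinear design columns: {', '.join(columns)}")


@dataclass(frozen=True)
class ModelSpec:
    """Covariate design for the tract-level density model.

    ``covariates`` are percentage fields divided by ``covariate_scale``
    (default 10) before fitting.  RUCA enters as dummies against the
    Metropolitan baseline; ``pct_white`` is excluded by default because it
    is near-collinear with the other composition variables.  Interactions
    are pairs of field names whose (scaled) product is added.
    """

    covariates: tuple[str, ...] = (
        "pct_poverty",
        "pct_black",
        "pct_hispanic",
        "pct_asian",
    )
    include_ruca: bool = True
    include_appalachia: bool = False
    interactions: tuple[tuple[str, str], ...] = ()
    covariate_scale: float = 10.0
    tol: float = 1e-8
    max_iter: int = 100
    #: hold the dispersion fixed instead of profiling it (e.g. a huge value
    #: reproduces a Poisson fit; useful for sensitivity checks)
    fixed_theta: float | None = None


@dataclass
class FitResult:
    """A fitted negative binomial model with both covariance estimates."""

    names: list[str]
    beta: np.ndarray
    model_cov: np.ndarray
    sandwich_cov: np.ndarray
    dispersion: float
    fitted_mu: np.ndarray
    deviance_residuals: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    tract_ids: list[str]
    # retained for covariance work
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    offset: np.ndarray = field(repr=False, default=None)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se(self, name: str, cov: str = "sandwich") -> float:
        V = self.sandwich_cov if cov == "sandwich" else self.model_cov
        i = self.names.index(name)
        return float(np.sqrt(V[i, i]))

    @property
    def pearson_residuals(self) -> np.ndarray:
        v = self.fitted_mu + self.fitted_mu**2 / self.dispersion
        return (self.y - self.fitted_mu) / np.sqrt(v)

    @property
    def score_residuals(self) -> np.ndarray:
        """Working score residuals (y - mu) / (1 + mu/theta)."""
        return (self.y - self.fitted_mu) / (1.0 + self.fitted_mu / self.dispersion)

    @property
    def irls_weights(self) -> np.ndarray:
        return self.fitted_mu / (1.0 + self.fitted_mu / self.dispersion)


# ---------------------------------------------------------------------------
# design construction


def build_design(
    spec: ModelSpec, tracts: Sequence[TractRecord]
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray, list[TractRecord]]:
    """Build (X, names, y, offset, used_tracts) from tract records.

    Tracts with missing RUCA level are excluded (with a logged count) when
    RUCA is in the model; dummies for levels absent from the data are
    dropped with a logged note.
    """
    used = list(tracts)
    if spec.include_ruca:
        n0 = len(used)
        used = [t for t in used if t.ruca_level is not None]
        if len(used) < n0:
            logger.info("build_design: excluded %d tracts with missing RUCA", n0 - len(used))
    for t in used:
        if t.population <= 0:
            raise ValueError(f"tract {t.tract_id}: population must be positive")
        if t.retailer_count is None:
            raise ValueError(f"tract {t.tract_id}: retailer_count missing")

    cols: list[np.ndarray] = [np.ones(len(used))]
    names = ["intercept"]
    for cov in spec.covariates:
        vals = np.array([getattr(t, cov) for t in used], dtype=float)
        if np.any(np.isnan(vals)):
            raise ValueError(f"covariate {cov!r} has missing values")
        cols.append(vals / spec.covariate_scale)
        names.append(cov)
    if spec.include_ruca:
        present = {t.ruca_level for t in used}
        for level in RUCA_DUMMY_ORDER:
            if level in present:
                cols.append(np.array([1.0 if t.ruca_level is level else 0.0 for t in used]))
                names.append(f"ruca_{level.value}")
            else:
                logger.info("build_design: no %s tracts; dummy dropped", level.value)
    if spec.include_appalachia:
        cols.append(np.array([1.0 if t.appalachia else 0.0 for t in used]))
        names.append("appalachia")
    for a, b in spec.interactions:
        va = _term_values(a, used, spec)
        vb = _term_values(b, used, spec)
        cols.append(va * vb)
        names.append(f"{a}:{b}")

    X = np.column_stack(cols)
    _check_rank(X, names)
    y = np.array([t.retailer_count for t in used], dtype=float)
    offset = np.log(np.array([t.population for t in used], dtype=float) / 1000.0)
    return X, names, y, offset, used


def _term_values(name: str, tracts: Sequence[TractRecord], spec: ModelSpec) -> np.ndarray:
    if name == "appalachia":
        return np.array([1.0 if t.appalachia else 0.0 for t in tracts])
    vals = np.array([getattr(t, name) for t in tracts], dtype=float)
    if name.startswith("pct_"):
        vals = vals / spec.covariate_scale
    return vals


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        # identify offending columns by pivoted QR
        from scipy.linalg import qr as scipy_qr

        _, R2, piv = scipy_qr(X, mode="economic", pivoting=True)
        d2 = np.abs(np.diag(R2))
        k = int((d2 >= 1e-10 * max(d2.max(), 1.0)).sum())
        raise RankDeficientError([names[j] for j in sorted(piv[k:])])


# ---------------------------------------------------------------------------
# likelihood and fitting


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood with dispersion theta (variance mu + mu^2/theta)."""
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def nb_deviance_residuals(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """Signed square-root deviance contributions; the y = 0 limit is exact."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    dev = 2.0 * (term - (y + theta) * np.log((y + theta) / (mu + theta)))
    dev = np.maximum(dev, 0.0)  # clip tiny negative rounding
    return np.sign(y - mu) * np.sqrt(dev)


def _profile_theta(y: np.ndarray, mu: np.ndarray, lo: float = -7.0, hi: float = 16.0) -> float:
    res = optimize.minimize_scalar(
        lambda lt: -nb_loglik(y, mu, math.exp(lt)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(math.exp(res.x))


def fit_nb(spec: ModelSpec, tracts: Sequence[TractRecord]) -> FitResult:
    """Fit the NB model by IRLS for beta alternating with profile-ML theta.

    The log-likelihood is forced non-decreasing by step-halving; the fit
    converges when the largest coefficient change drops below
    ``spec.tol``.  The sandwich covariance stored on the result uses the
    identity working correlation (robust to heteroskedasticity only);
    :func:`sandwich_covariance` replaces it with a spatially informed one.
    """
    X, names, y, offset, used = build_design(spec, tracts)
    if not np.any(y > 0):
        raise ValueError("all retailer counts are zero; nothing to model")

    n, p = X.shape
    mu = y + np.mean(y[y > 0]) / 2.0
    eta = np.log(mu)
    # initial beta from working least squares
    z = eta - offset
    beta = np.linalg.lstsq(X, z, rcond=None)[0]
    eta = X @ beta + offset
    mu = np.exp(eta)
    theta = spec.fixed_theta or _profile_theta(y, mu)
    ll = nb_loglik(y, mu, theta)

    converged = False
    it = 0
    for it in range(1, spec.max_iter + 1):
        w = mu / (1.0 + mu / theta)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        step = beta_new - beta
        # step-halving guarantees likelihood ascent
        lam = 1.0
        for _ in range(40):
            cand = beta + lam * step
            mu_c = np.exp(X @ cand + offset)
            ll_c = nb_loglik(y, mu_c, theta)
            if ll_c >= ll - 1e-12:
                break
            lam *= 0.5
        beta_next = beta + lam * step
        delta = float(np.max(np.abs(beta_next - beta)))
        beta = beta_next
        eta = X @ beta + offset
        mu = np.exp(eta)
        if spec.fixed_theta is None:
            theta = _profile_theta(y, mu)
        ll = nb_loglik(y, mu, theta)
        if delta < spec.tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_nb: no convergence in %d iterations", spec.max_iter)

    w = mu / (1.0 + mu / theta)
    A = X.T @ (X * w[:, None])
    model_cov = np.linalg.inv(A)
    s = (y - mu) / (1.0 + mu / theta)
    Xs = X * s[:, None]
    hc0 = model_cov @ (Xs.T @ Xs) @ model_cov

    return FitResult(
        names=names,
        beta=beta,
        model_cov=model_cov,
        sandwich_cov=hc0,
        dispersion=theta,
        fitted_mu=mu,
        deviance_residuals=nb_deviance_residuals(y, mu, theta),
        converged=converged,
        n_iter=it,
        loglik=ll,
        tract_ids=[t.tract_id for t in used],
        X=X,
        y=y,
        offset=offset,
    )


# ---------------------------------------------------------------------------
# spatial weights and working correlation


@dataclass
class SpatialWeights:
    """Tract adjacency and/or centroid geometry for spatial inference.

    ``adjacency`` is a binary symmetric sparse matrix with zero diagonal
    (queen contiguity when built from polygons); ``centroids`` holds
    planar coordinates for distance-based kernels.  Row standardization is
    applied on demand by :meth:`matrix`.
    """

    ids: list[str]
    adjacency: sparse.csr_matrix | None = None
    centroids: np.ndarray | None = None
    row_standardized: bool = True

    @classmethod
    def queen_from_polygons(
        cls, polygons: Mapping[str, object], row_standardized: bool = True
    ) -> "SpatialWeights":
        """Queen contiguity: tracts sharing any boundary point are neighbors."""
        ids = sorted(polygons)
        geoms = [polygons[i] for i in ids]
        tree = STRtree(geoms)
        rows, cols = [], []
        for i, g in enumerate(geoms):
            for j in tree.query(g, predicate="intersects"):
                j = int(j)
                if j != i:
                    rows.append(i)
                    cols.append(j)
        n = len(ids)
        adj = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        adj.data[:] = 1.0
        cents = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
        return cls(ids=ids, adjacency=adj, centroids=cents, row_standardized=row_standardized)

    @classmethod
    def from_centroids(
        cls, ids: Sequence[str], xy: np.ndarray, row_standardized: bool = True
    ) -> "SpatialWeights":
        return cls(
            ids=list(ids),
            adjacency=None,
            centroids=np.asarray(xy, dtype=float),
            row_standardized=row_standardized,
        )

    def subset(self, ids: Sequence[str]) -> "SpatialWeights":
        """Restrict to the given tract ids, in the given order."""
        pos = {t: i for i, t in enumerate(self.ids)}
        idx = np.array([pos[t] for t in ids])
        adj = None
        if self.adjacency is not None:
            adj = self.adjacency[idx][:, idx].tocsr()
        cents = self.centroids[idx] if self.centroids is not None else None
        return SpatialWeights(
            ids=list(ids), adjacency=adj, centroids=cents,
            row_standardized=self.row_standardized,
        )

    def matrix(self) -> sparse.csr_matrix:
        """The weights matrix, row-standardized if configured."""
        if self.adjacency is None:
            raise ValueError("no adjacency structure; build from polygons")
        W = self.adjacency.astype(float).tocsr()
        if self.row_standardized:
            rs = np.asarray(W.sum(axis=1)).ravel()
            inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
            W = sparse.diags(inv) @ W
        return W.tocsr()

    def distance_matrix(self) -> np.ndarray:
        if self.centroids is None:
            raise ValueError("no centroids; distance kernel unavailable")
        return squareform(pdist(self.centroids))


@dataclass(frozen=True)
class SpatialKernel:
    """Fitted working correlation among tracts.

    ``exponential``: corr(d) = sill * exp(-d / phi) for d > 0 (1 at d = 0);
    the sill in [0, 1) absorbs the non-spatial share of residual variance
    (a nugget effect).  ``adjacency``: rho for neighbor pairs, 0 otherwise.
    ``independence``: the identity, reducing the sandwich to the plain
    heteroskedasticity-robust estimator.
    """

    kind: str  # "exponential" | "adjacency" | "independence"
    phi: float | None = None
    rho: float | None = None
    sill: float | None = None

    def correlation_matrix(self, weights: SpatialWeights) -> np.ndarray:
        n = len(weights.ids)
        if self.kind == "independence":
            return np.eye(n)
        if self.kind == "adjacency":
            A = weights.adjacency
            if A is None:
                raise ValueError("adjacency kernel needs contiguity structure")
            R = (self.rho * A.toarray()).astype(float)
            np.fill_diagonal(R, 1.0)
            return R
        D = weights.distance_matrix()
        R = self.sill * np.exp(-D / self.phi)
        np.fill_diagonal(R, 1.0)
        return R


def estimate_spatial_correlation(
    residuals: np.ndarray,
    weights: SpatialWeights,
    kind: str = "exponential",
    n_bins: int = 10,
    min_pairs: int = 30,
    max_distance: float | None = None,
    projection: np.ndarray | None = None,
) -> SpatialKernel:
    """Method-of-moments fit of a working residual correlation.

    The empirical correlation of centered residual pairs is computed per
    distance bin (or for neighbor pairs), and the kernel parameters are
    chosen by pair-count-weighted least squares over the bins.  With fewer
    than two bins holding ``min_pairs`` pairs, the fit falls back to the
    adjacency-indicator kernel with a logged warning.

    ``projection`` (the weighted design Z = diag(mu/sqrt(V)) X of the fit
    the residuals came from) corrects for leakage of the spatial signal
    into the fitted coefficients: Pearson residuals are (I - P_Z) eps, so
    their pair correlations understate the error correlation, most
    severely when covariates are themselves spatially smooth.  When given,
    the binned empirical correlations are matched against the
    projection-attenuated predictions of the candidate kernel rather than
    the kernel itself.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 2 or np.allclose(r, r[0]):
        raise ValueError("degenerate residuals: zero variance")
    z = r - r.mean()
    denom = float(np.mean(z**2))

    if kind == "independence":
        return SpatialKernel(kind="independence")

    if kind == "adjacency" or weights.centroids is None:
        return _fit_adjacency(z, denom, weights)

    n = z.size
    Dfull = squareform(pdist(weights.centroids))
    iu, ju = np.triu_indices(n, k=1)
    D = Dfull[iu, ju]
    if max_distance is None:
        max_distance = 0.25 * float(D.max())
    cross = z[iu] * z[ju]
    edges = np.linspace(0.0, max_distance, n_bins + 1)
    which = np.digitize(D, edges[1:-1])
    in_range = D <= max_distance
    masks, mids, corrs, counts = [], [], [], []
    for b in range(n_bins):
        m = in_range & (which == b)
        cnt = int(m.sum())
        if cnt >= min_pairs:
            masks.append(m)
            mids.append(0.5 * (edges[b] + edges[b + 1]))
            corrs.append(float(cross[m].mean()) / denom)
            counts.append(cnt)
    if len(mids) < 2:
        logger.warning(
            "estimate_spatial_correlation: <2 usable distance bins; "
            "falling back to adjacency kernel"
        )
        return _fit_adjacency(z, denom, weights)

    mids = np.array(mids)
    corrs = np.array(corrs)
    wts = np.array(counts, dtype=float)
    span = max(max_distance, 1e-6)
    bounds = (math.log(span) - 8.0, math.log(span) + 3.0)

    if projection is None:
        def sse(log_phi: float) -> float:
            e = np.exp(-mids / math.exp(log_phi))
            sill = _opt_sill(corrs, e, wts)
            return float(np.sum(wts * (corrs - sill * e) ** 2))

        res = optimize.minimize_scalar(sse, bounds=bounds, method="bounded")
        phi = float(math.exp(res.x))
        e = np.exp(-mids / phi)
        return SpatialKernel(kind="exponential", phi=phi, sill=_opt_sill(corrs, e, wts))

    # attenuation-aware fit: predictions pass through I - P_Z
    U, _ = np.linalg.qr(np.asarray(projection, dtype=float))
    UUt_pairs = (U[iu] * U[ju]).sum(axis=1)  # (U U')_ij for i<j pairs
    ip_offdiag = -UUt_pairs  # (I - P)_ij off-diagonal
    ip_diag = 1.0 - (U**2).sum(axis=1)
    a_k = np.array([float(ip_offdiag[m].mean()) for m in masks])
    d_a = float(ip_diag.mean())

    def bin_preds(phi: float) -> tuple[np.ndarray, float]:
        E = np.exp(-Dfull / phi)
        G = U.T @ E  # p x n
        F = G @ U  # p x p
        T = E - U @ G - G.T @ U.T + U @ F @ U.T  # (I-P) E (I-P)
        t_pairs = T[iu, ju]
        t_k = np.array([float(t_pairs[m].mean()) for m in masks])
        d_t = float(np.diag(T).mean())
        return t_k, d_t

    def sse_proj(log_phi: float) -> float:
        t_k, d_t = bin_preds(math.exp(log_phi))

        def inner(s: float) -> float:
            pred = ((1.0 - s) * a_k + s * t_k) / ((1.0 - s) * d_a + s * d_t)
            return float(np.sum(wts * (corrs - pred) ** 2))

        r2 = optimize.minimize_scalar(inner, bounds=(0.0, 1.0 - 1e-9), method="bounded")
        return float(r2.fun)

    res = optimize.minimize_scalar(sse_proj, bounds=bounds, method="bounded")
    phi = float(math.exp(res.x))
    t_k, d_t = bin_preds(phi)
    r2 = optimize.minimize_scalar(
        lambda s: float(
            np.sum(
                wts
                * (corrs - ((1.0 - s) * a_k + s * t_k) / ((1.0 - s) * d_a + s * d_t)) ** 2
            )
        ),
        bounds=(0.0, 1.0 - 1e-9),
        method="bounded",
    )
    return SpatialKernel(kind="exponential", phi=phi, sill=float(r2.x))


def _opt_sill(corrs: np.ndarray, e: np.ndarray, wts: np.ndarray) -> float:
    num = float(np.sum(wts * corrs * e))
    den = float(np.sum(wts * e * e))
    sill = num / den if den > 0 else 0.0
    return min(max(sill, 0.0), 1.0 - 1e-9)


def weighted_design(fit: FitResult) -> np.ndarray:
    """The weighted design Z = diag(mu/sqrt(V)) X whose column space the
    Pearson residuals are orthogonal to (used for attenuation correction)."""
    v = fit.fitted_mu + fit.fitted_mu**2 / fit.dispersion
    return fit.X * (fit.fitted_mu / np.sqrt(v))[:, None]


def spatial_kernel_for_fit(
    fit: FitResult, weights: SpatialWeights, kind: str = "exponential", **kwargs
) -> SpatialKernel:
    """Fit the working correlation to a model's Pearson residuals,
    correcting for the attenuation induced by coefficient estimation."""
    w = weights if list(weights.ids) == list(fit.tract_ids) else weights.subset(fit.tract_ids)
    return estimate_spatial_correlation(
        fit.pearson_residuals, w, kind=kind, projection=weighted_design(fit), **kwargs
    )


def _fit_adjacency(z: np.ndarray, denom: float, weights: SpatialWeights) -> SpatialKernel:
    A = weights.adjacency
    if A is None:
        raise ValueError("adjacency kernel needs contiguity structure")
    coo = sparse.triu(A, k=1).tocoo()
    if coo.nnz == 0:
        logger.warning("no neighbor pairs; returning independence kernel")
        return SpatialKernel(kind="independence")
    rho = float(np.mean(z[coo.row] * z[coo.col])) / denom
    rho = min(max(rho, 0.0), 1.0 - 1e-9)
    return SpatialKernel(kind="adjacency", rho=rho)


# ---------------------------------------------------------------------------
# sandwich covariance and tests


def sandwich_covariance(
    fit: FitResult, weights: SpatialWeights, kernel: SpatialKernel
) -> np.ndarray:
    """GEE-style covariance A^{-1} B A^{-1} with a spatial working correlation.

    A is the model-based information X'WX.  The middle matrix estimates
    Cov(X's) for the score residuals s: observed s_i^2 on the diagonal
    (robust to variance misspecification) and sigma_i sigma_j R_ij off the
    diagonal, where sigma_i is the model-scale score SD (sqrt of the IRLS
    weight, rescaled by the empirical Pearson dispersion) and R the fitted
    tract correlation.  Plugging the raw residual products into the
    off-diagonal instead would count the correlation twice
    (E[s_i s_j R_ij] = R_ij * Cov(s_i, s_j), not Cov(s_i, s_j)) and leave
    the adjustment toothless.  With R = I this reduces exactly to the
    HC0-style robust estimator.  A non-PSD middle matrix (possible after
    the moment fit) is projected to the nearest PSD matrix by eigenvalue
    clipping, with a log note.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; sandwich covariance undefined")
    w = weights if list(weights.ids) == list(fit.tract_ids) else weights.subset(fit.tract_ids)
    R = kernel.correlation_matrix(w)
    s = fit.score_residuals
    ww = fit.irls_weights
    disp = float(np.mean(s**2 / ww))  # empirical Pearson-scale dispersion
    sig = np.sqrt(disp * ww)
    Xs = fit.X * s[:, None]
    n = len(s)
    M = np.outer(sig, sig) * (R - np.eye(n))
    B = Xs.T @ Xs + fit.X.T @ M @ fit.X
    eig = np.linalg.eigvalsh(B)
    if eig.min() < -1e-8 * max(abs(eig.max()), 1.0):
        logger.warning("sandwich middle matrix not PSD; clipping eigenvalues")
        vals, vecs = np.linalg.eigh(B)
        B = (vecs * np.maximum(vals, 0.0)) @ vecs.T
    Ainv = fit.model_cov
    V = Ainv @ B @ Ainv
    return 0.5 * (V + V.T)


def wald_tests(fit: FitResult, cov_choice: str = "sandwich"):
    """Per-coefficient Wald z tests; returns a tidy DataFrame."""
    import pandas as pd
    from scipy import stats

    V = fit.sandwich_cov if cov_choice == "sandwich" else fit.model_cov
    se = np.sqrt(np.diag(V))
    z = fit.beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"term": fit.names, "estimate": fit.beta, "se": se, "z": z, "p": p}
    )


def joint_test(
    fit: FitResult, terms: Sequence[str], cov_choice: str = "sandwich"
) -> tuple[float, int, float]:
    """Joint Wald chi-square test that a set of coefficients is zero."""
    from scipy import stats

    V = fit.sandwich_cov if cov_choice == "sandwich" else fit.model_cov
    idx = [fit.names.index(t) for t in terms]
    b = fit.beta[idx]
    Vss = V[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(Vss, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular sub-covariance for joint test") from exc
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))
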