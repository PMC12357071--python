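"""Model checking: deviance residuals and Moran's I for spatial dependence.

Moran's I measures whether a variable observed on areal units is more
alike among neighbors than chance would allow.  Under the randomization
null its expectation is -1/(n-1); inference is either by permutation
(relabeling residuals over tracts) or by the normal approximation with
the classical randomization moments.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

from trdspat.nbgee import FitResult, SpatialWeights, nb_deviance_residuals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MoranResult:
    statistic_I: float
    expected_I: float
    p_value: float
    method: str  # "normal" | "permutation" | "exhaustive"
    n: int
    n_permutations: int | None = None
    variance_I: float | None = None


def deviance_residuals(fit: FitResult) -> np.ndarray:
    """NB deviance residuals of a converged fit (y = 0 handled exactly)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return nb_deviance_residuals(fit.y, fit.fitted_mu, fit.dispersion)


def _moran_stat(z: np.ndarray, W: sparse.csr_matrix, s0: float) -> float:
    n = z.size
    return float(n / s0 * (z @ (W @ z)) / (z @ z))


def morans_i(
    residuals: np.ndarray,
    weights: SpatialWeights,
    mode: str = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Moran's I of residuals under a spatial weights matrix.

    ``mode`` is "permutation" (two-sided, +1-corrected Monte Carlo p),
    "normal" (randomization moments), or "exhaustive" (all n! relabelings;
    n <= 9 only).  Tracts with no neighbors are dropped from the statistic
    with a logged count.
    """
    r = np.asarray(residuals, dtype=float)
    W = weights.matrix()
    deg = np.asarray((weights.adjacency != 0).sum(axis=1)).ravel()
    if np.any(deg == 0):
        keep = deg > 0
        logger.warning("morans_i: dropping %d neighborless tracts", int((~keep).sum()))
        r = r[keep]
        sub = weights.subset([weights.ids[i] for i in np.flatnonzero(keep)])
        W = sub.matrix()
    n = r.size
    if n < 4:
        raise ValueError("need at least 4 observations with neighbors")
    if np.ptp(r) == 0:
        raise ValueError("zero residual variance")

    z = r - r.mean()
    s0 = float(W.sum())
    I_obs = _moran_stat(z, W, s0)
    e_i = -1.0 / (n - 1)

    if mode == "normal":
        Wd = W.toarray()
        s1 = 0.5 * float(((Wd + Wd.T) ** 2).sum())
        rs = Wd.sum(axis=1) + Wd.sum(axis=0)
        s2 = float((rs**2).sum())
        m2 = float(np.mean(z**2))
        m4 = float(np.mean(z**4))
        b2 = m4 / m2**2
        num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
            (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
        )
        var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
        zscore = (I_obs - e_i) / math.sqrt(var_i)
        p = 2.0 * stats.norm.sf(abs(zscore))
        return MoranResult(I_obs, e_i, float(p), "normal", n, variance_I=var_i)

    if mode == "exhaustive":
        if n > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9")
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            I_p = _moran_stat(z[list(perm)], W, s0)
            if abs(I_p) >= abs(I_obs) - 1e-12:
                hits += 1
            total += 1
        return MoranResult(I_obs, e_i, hits / total, "exhaustive", n, n_permutations=total)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        I_p = _moran_stat(rng.permutation(z), W, s0)
        if abs(I_p) >= abs(I_obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MoranResult(I_obs, e_i, float(p), "permutation", n, n_permutations=n_perm)
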