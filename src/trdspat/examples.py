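"""Worked-example coefficient tables for four US states.

These are published marginal-model estimates (log tobacco retailer density
per 10-percentage-point covariate increase; RUCA dummies against a
Metropolitan baseline) for California, Connecticut, North Carolina and
Ohio.  They serve as ready-made inputs for the effect and contrast
machinery: feeding them through :func:`trdspat.multiplicative_effect`,
:func:`trdspat.ruca_ratio` and
:func:`trdspat.conditional_appalachia_effect` reproduces the headline
density-ratio statements of the analysis they come from.

Only coefficients and standard errors are published, not the covariance
off-diagonals, so contrast standard errors built from these tables treat
coefficients as uncorrelated — ratios are exact, intervals approximate.
"""

from __future__ import annotations

import numpy as np

from trdspat.nbgee import FitResult

#: Model 1 (no Appalachia terms): {state: {term: (estimate, se)}}.
MODEL1: dict[str, dict[str, tuple[float, float]]] = {
    "CA": {
        "intercept": (-0.662, 0.042),
        "ruca_Micropolitan": (0.226, 0.084),
        "ruca_SmallTown": (0.428, 0.157),
        "ruca_Rural": (0.625, 0.106),
        "pct_poverty": (0.190, 0.015),
        "pct_black": (-0.038, 0.019),
        "pct_hispanic": (-0.005, 0.007),
        "pct_asian": (-0.072, 0.011),
    },
    "CT": {
        # Connecticut has no small-town tracts; that dummy is absent.
        "intercept": (-0.161, 0.068),
        "ruca_Micropolitan": (-0.022, 0.224),
        "ruca_Rural": (-0.015, 0.319),
        "pct_poverty": (0.155, 0.043),
        "pct_black": (0.027, 0.028),
        "pct_hispanic": (0.085, 0.027),
        "pct_asian": (0.064, 0.064),
    },
    "NC": {
        "intercept": (-0.318, 0.047),
        "ruca_Micropolitan": (0.336, 0.063),
        "ruca_SmallTown": (0.330, 0.099),
        "ruca_Rural": (0.384, 0.119),
        "pct_poverty": (0.212, 0.022),
        "pct_black": (0.041, 0.012),
        "pct_hispanic": (0.021, 0.023),
        "pct_asian": (-0.138, 0.045),
    },
    "OH": {
        "intercept": (-0.325, 0.033),
        "ruca_Micropolitan": (0.147, 0.053),
        "ruca_SmallTown": (0.291, 0.089),
        "ruca_Rural": (0.322, 0.117),
        "pct_poverty": (0.183, 0.016),
        "pct_black": (-0.012, 0.010),
        "pct_hispanic": (0.072, 0.030),
        "pct_asian": (-0.168, 0.045),
    },
}

#: Model 2 (adds Appalachia; NC also a poverty-by-Appalachia interaction).
MODEL2: dict[str, dict[str, tuple[float, float]]] = {
    "NC": {
        "intercept": (-0.386, 0.052),
        "ruca_Micropolitan": (0.345, 0.063),
        "ruca_SmallTown": (0.327, 0.098),
        "ruca_Rural": (0.360, 0.118),
        "pct_poverty": (0.224, 0.024),
        "pct_black": (0.048, 0.012),
        "pct_hispanic": (0.027, 0.023),
        "pct_asian": (-0.123, 0.045),
        "appalachia": (0.281, 0.097),
        "pct_poverty:appalachia": (-0.011, 0.005),
    },
    "OH": {
        "intercept": (-0.343, 0.034),
        "ruca_Micropolitan": (0.126, 0.054),
        "ruca_SmallTown": (0.270, 0.089),
        "ruca_Rural": (0.300, 0.117),
        "pct_poverty": (0.175, 0.016),
        "pct_black": (-0.006, 0.010),
        "pct_hispanic": (0.084, 0.030),
        "pct_asian": (-0.155, 0.045),
        "appalachia": (0.115, 0.053),
    },
}

#: Median tract % below poverty in North Carolina (used in the worked
#: Appalachia example); 20 and 34.2 are the 0.75 and 0.95 quantiles.
NC_POVERTY_MEDIAN = 12.4


def fit_from_table(state: str, model: int = 1) -> FitResult:
    """Wrap a published coefficient table as a :class:`FitResult`.

    The covariance is diagonal (squared standard errors): the published
    tables do not include off-diagonal covariances, so contrast intervals
    built from these fits ignore coefficient correlation.
    """
    table = (MODEL1 if model == 1 else MODEL2)[state]
    names = list(table)
    beta = np.array([table[n][0] for n in names])
    cov = np.diag(np.array([table[n][1] for n in names]) ** 2)
    return FitResult(
        names=names,
        beta=beta,
        model_cov=cov,
        sandwich_cov=cov,
        dispersion=1.0,
        fitted_mu=np.array([]),
        deviance_residuals=np.array([]),
        converged=True,
        n_iter=0,
        loglik=float("nan"),
        tract_ids=[],
    )
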