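"""Synthetic state-like tract datasets for exercising the full pipeline.

The generator lays unit-square tracts on a lattice and endows them with
the statistical structure the analysis assumes: a spatially smooth poverty
field, county-block race/ethnicity compositions, a concentric rural–urban
gradient (urban core -> micropolitan -> small-town -> rural rings), an
Appalachian county block, and negative binomial retailer counts whose log
mean adds a spatially correlated Gaussian random effect to the covariate
signal.  Every draw flows from a single seeded generator, so a config is
reproducible bit-for-bit.

Nothing here imitates a real state's geography or census marginals; the
point is a controlled truth against which estimators can be validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from trdspat.tract_data import RucaLevel, TractRecord

#: Default true coefficients, per-10-percentage-point scale, echoing the
#: magnitudes a four-state retailer-density analysis reports.
DEFAULT_BETA: dict[str, float] = {
    "intercept": -0.4,
    "pct_poverty": 0.2,
    "pct_black": 0.0,
    "pct_hispanic": 0.05,
    "pct_asian": -0.1,
    "ruca_Micropolitan": 0.2,
    "ruca_SmallTown": 0.3,
    "ruca_Rural": 0.4,
    "appalachia": 0.0,
    "pct_poverty:appalachia": 0.0,
}

#: Representative RUCA primary code per collapsed level.
LEVEL_CODE = {
    RucaLevel.METROPOLITAN: 1,
    RucaLevel.MICROPOLITAN: 4,
    RucaLevel.SMALL_TOWN: 7,
    RucaLevel.RURAL: 10,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative parameterization of a synthetic state.

    ``beta`` is on the per-10% log-density scale.  ``spatial_sd`` and
    ``spatial_range`` (lattice units) control the exponential-covariance
    Gaussian random effect; ``theta`` is the NB dispersion.  Populations
    are log-uniform over ``pop_range``.  ``ruca_layout`` is "rings" (all
    four levels) or "no_small_town" (the small-town ring is absorbed,
    exercising absent-level handling).
    """

    lattice: tuple[int, int] = (30, 30)
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    theta: float = 5.0
    spatial_sd: float = 0.3
    spatial_range: float = 2.0
    pop_range: tuple[float, float] = (300.0, 8000.0)
    poverty_range: float = 3.0  # smoothness of the poverty field
    county_block: int = 5  # tracts per county side
    ruca_layout: str = "rings"
    appalachia_frac: float = 0.33  # right-hand column fraction flagged
    state: str = "SY"
    seed: int = 0

    def validate(self) -> None:
        if self.lattice[0] < 2 or self.lattice[1] < 2:
            raise ValueError("lattice must be at least 2x2")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.spatial_sd < 0:
            raise ValueError("spatial_sd must be >= 0")
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be positive")
        if not 0 < self.pop_range[0] <= self.pop_range[1]:
            raise ValueError("pop_range must be increasing and positive")
        if self.ruca_layout not in ("rings", "no_small_town"):
            raise ValueError(f"unknown ruca_layout {self.ruca_layout!r}")


def _ruca_levels(cfg: SyntheticConfig, xy: np.ndarray) -> list[RucaLevel]:
    nx, ny = cfg.lattice
    center = np.array([nx / 2.0, ny / 2.0])
    r = np.linalg.norm(xy - center, axis=1)
    rmax = float(np.linalg.norm(center))
    frac = r / rmax
    out = []
    if cfg.ruca_layout == "rings":
        cuts = (0.35, 0.55, 0.75)
        for f in frac:
            if f < cuts[0]:
                out.append(RucaLevel.METROPOLITAN)
            elif f < cuts[1]:
                out.append(RucaLevel.MICROPOLITAN)
            elif f < cuts[2]:
                out.append(RucaLevel.SMALL_TOWN)
            else:
                out.append(RucaLevel.RURAL)
    else:  # no_small_town
        for f in frac:
            if f < 0.45:
                out.append(RucaLevel.METROPOLITAN)
            elif f < 0.75:
                out.append(RucaLevel.MICROPOLITAN)
            else:
                out.append(RucaLevel.RURAL)
    return out


def _gaussian_field(
    rng: np.random.Generator, xy: np.ndarray, sd: float, rng_param: float
) -> np.ndarray:
    """Zero-mean Gaussian field with covariance sd^2 exp(-d/range), by Cholesky."""
    n = xy.shape[0]
    if sd == 0.0:
        return np.zeros(n)
    D = squareform(pdist(xy))
    C = sd**2 * np.exp(-D / rng_param)
    C[np.diag_indices(n)] += 1e-10 * sd**2
    L = np.linalg.cholesky(C)
    return L @ rng.standard_normal(n)


def generate(
    config: SyntheticConfig,
) -> tuple[list[TractRecord], dict, dict]:
    """Generate (tracts, polygons GeoJSON dict, truth record) from a config.

    The truth record stores the latent coefficients (``beta``), the
    marginal coefficients the independence model targets
    (``beta_marginal``: the intercept shifted by spatial_sd^2/2, the
    lognormal mean of the random effect), the dispersion, and the latent
    spatial effect per tract.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nx, ny = config.lattice
    beta = dict(DEFAULT_BETA)
    beta.update(config.beta)

    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cols = cols.ravel()
    rows = rows.ravel()
    xy = np.column_stack([cols + 0.5, rows + 0.5]).astype(float)
    n = nx * ny

    # counties are square blocks of tracts; FIPS "99" + 3-digit county index
    county_ix = (cols // config.county_block) * (
        (ny + config.county_block - 1) // config.county_block
    ) + (rows // config.county_block)
    county_fips = [f"99{int(c) + 1:03d}" for c in county_ix]
    appalachia_cut = (1.0 - config.appalachia_frac) * nx
    county_app: dict[str, bool] = {}
    for f, cx in zip(county_fips, cols):
        county_app.setdefault(f, False)
    # county is Appalachian when its left edge reaches the cut
    for f, cx in zip(county_fips, cols):
        if cx >= appalachia_cut:
            county_app[f] = True
    appalachia = np.array([county_app[f] for f in county_fips])

    levels = _ruca_levels(config, xy)

    # poverty: smooth Gaussian field pushed through its CDF onto [0, 60]
    pov_field = _gaussian_field(rng, xy, 1.0, config.poverty_range)
    pct_poverty = 60.0 * stats.norm.cdf(pov_field)

    # race/ethnicity: county-level Dirichlet base composition plus tract noise
    comp_alpha = {f: rng.uniform(0.5, 6.0, size=5) for f in sorted(set(county_fips))}
    shares = np.empty((n, 5))
    for i, f in enumerate(county_fips):
        shares[i] = rng.dirichlet(comp_alpha[f] * 8.0)
    pct_white, pct_black, pct_hispanic, pct_asian, _other = (100.0 * shares).T

    lo, hi = config.pop_range
    population = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n)).round().astype(int)

    b = _gaussian_field(rng, xy, config.spatial_sd, config.spatial_range)

    eta = (
        beta["intercept"]
        + beta["pct_poverty"] * pct_poverty / 10.0
        + beta["pct_black"] * pct_black / 10.0
        + beta["pct_hispanic"] * pct_hispanic / 10.0
        + beta["pct_asian"] * pct_asian / 10.0
        + np.array(
            [
                beta.get(f"ruca_{lv.value}", 0.0) if lv is not RucaLevel.METROPOLITAN else 0.0
                for lv in levels
            ]
        )
        + beta["appalachia"] * appalachia
        + beta["pct_poverty:appalachia"] * (pct_poverty / 10.0) * appalachia
        + np.log(population / 1000.0)
        + b
    )
    mu = np.exp(eta)
    counts = rng.poisson(rng.gamma(shape=config.theta, scale=mu / config.theta))

    tracts: list[TractRecord] = []
    for i in range(n):
        tid = f"{county_fips[i]}{i:06d}"
        tracts.append(
            TractRecord(
                tract_id=tid,
                county_fips=county_fips[i],
                state=config.state,
                population=int(population[i]),
                retailer_count=int(counts[i]),
                pct_poverty=float(pct_poverty[i]),
                pct_black=float(pct_black[i]),
                pct_hispanic=float(pct_hispanic[i]),
                pct_asian=float(pct_asian[i]),
                pct_white=float(pct_white[i]),
                ruca_code=LEVEL_CODE[levels[i]],
                appalachia=bool(appalachia[i]),
                centroid=(float(xy[i, 0]), float(xy[i, 1])),
            )
        )

    features = []
    for i in range(n):
        x0, y0 = float(cols[i]), float(rows[i])
        features.append(
            {
                "type": "Feature",
                "properties": {"tract_id": tracts[i].tract_id},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [
                            [x0, y0],
                            [x0 + 1.0, y0],
                            [x0 + 1.0, y0 + 1.0],
                            [x0, y0 + 1.0],
                            [x0, y0],
                        ]
                    ],
                },
            }
        )
    geojson = {"type": "FeatureCollection", "features": features}

    beta_marginal = dict(beta)
    beta_marginal["intercept"] = beta["intercept"] + config.spatial_sd**2 / 2.0
    truth = {
        "beta": beta,
        "beta_marginal": beta_marginal,
        "theta": config.theta,
        "spatial_sd": config.spatial_sd,
        "spatial_range": config.spatial_range,
        "seed": config.seed,
        "b": [float(v) for v in b],
    }
    return tracts, geojson, truth


def scenario_library() -> dict[str, SyntheticConfig]:
    """Named generative scenarios used throughout the test harness."""
    base = SyntheticConfig()
    return {
        "paperlike": base,
        "null_spatial": replace(base, spatial_sd=0.0),
        "ct_like": replace(base, ruca_layout="no_small_town"),
        "appalachia_interaction": replace(
            base,
            beta={**DEFAULT_BETA, "appalachia": 0.25, "pct_poverty:appalachia": -0.15},
        ),
    }
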