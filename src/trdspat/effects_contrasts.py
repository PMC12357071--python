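"""Rate-ratio effects and contrasts from fitted density models.

Coefficients live on the log-density scale in per-10-percentage-point
units, so a 10-point covariate increase multiplies the expected retailer
density by ``exp(beta)``.  Rurality contrasts are exponentiated coefficient
differences against any pair of RUCA levels (Metropolitan is the model
baseline with an implicit zero coefficient); families of pairwise
contrasts get Bonferroni-simultaneous confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from trdspat.nbgee import FitResult
from trdspat.tract_data import RucaLevel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastResult:
    """A density ratio between two strata with its confidence interval."""

    label_a: str
    label_b: str
    log_ratio: float | None
    se: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    alpha_adjusted: float = 0.05

    @property
    def ratio(self) -> float | None:
        return None if self.log_ratio is None else math.exp(self.log_ratio)

    @property
    def absent(self) -> bool:
        return self.log_ratio is None


@dataclass(frozen=True)
class EffectCurve:
    covariate: str
    reference: float
    grid: np.ndarray
    ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    excludes_one: np.ndarray  # per grid point: CI excludes a ratio of 1


def _ci(log_ratio: float, se: float, alpha: float) -> tuple[float, float]:
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    return math.exp(log_ratio - zc * se), math.exp(log_ratio + zc * se)


def multiplicative_effect(
    fit: FitResult, covariate: str, delta: float = 10.0, alpha: float = 0.05
) -> ContrastResult:
    """Multiplicative density change for a ``delta``-point covariate increase.

    ratio = exp(beta * delta/10) with the Wald CI on the same scale, using
    the sandwich standard error.
    """
    if covariate not in fit.names:
        raise KeyError(f"covariate {covariate!r} not in model: {fit.names}")
    scale = delta / 10.0
    b = fit.coef(covariate) * scale
    se = fit.se(covariate) * abs(scale)
    lo, hi = _ci(b, se, alpha)
    return ContrastResult(
        label_a=f"{covariate}+{delta:g}", label_b=covariate,
        log_ratio=b, se=se, ci_low=lo, ci_high=hi, alpha_adjusted=alpha,
    )


def _ruca_index(fit: FitResult, level: RucaLevel) -> int | None:
    """Column index of a RUCA dummy; -1 for the Metropolitan baseline."""
    if level is RucaLevel.METROPOLITAN:
        return -1
    name = f"ruca_{level.value}"
    return fit.names.index(name) if name in fit.names else None


def ruca_ratio(
    fit: FitResult, level_a: RucaLevel, level_b: RucaLevel, alpha: float = 0.05
) -> ContrastResult:
    """Density ratio between two rurality levels, level_a : level_b.

    The log ratio is the coefficient difference; its variance is
    var_a + var_b - 2 cov_ab from the sandwich covariance.  A level with
    no tracts in the fitted data yields an absent-level result (rendered
    as a dash in exported tables).
    """
    ia, ib = _ruca_index(fit, level_a), _ruca_index(fit, level_b)
    if ia is None or ib is None:
        return ContrastResult(
            label_a=level_a.value, label_b=level_b.value, log_ratio=None, se=None
        )
    c = np.zeros(len(fit.names))
    if ia >= 0:
        c[ia] = 1.0
    if ib >= 0:
        c[ib] -= 1.0
    b = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.sandwich_cov @ c))
    if level_a is level_b:
        return ContrastResult(
            label_a=level_a.value, label_b=level_b.value,
            log_ratio=0.0, se=0.0, ci_low=1.0, ci_high=1.0, alpha_adjusted=alpha,
        )
    lo, hi = _ci(b, se, alpha)
    return ContrastResult(
        label_a=level_a.value, label_b=level_b.value,
        log_ratio=b, se=se, ci_low=lo, ci_high=hi, alpha_adjusted=alpha,
    )


def all_pairwise_ruca_ratios(fit: FitResult, family_alpha: float = 0.05) -> list[ContrastResult]:
    """All pairwise rurality contrasts with Bonferroni-simultaneous CIs.

    The family is the C(k,2) pairs among RUCA levels present in the fit;
    absent-level pairs are reported as absent and do not count toward the
    family size.
    """
    order = [RucaLevel.MICROPOLITAN, RucaLevel.SMALL_TOWN, RucaLevel.RURAL]
    pairs = [
        (RucaLevel.MICROPOLITAN, RucaLevel.METROPOLITAN),
        (RucaLevel.SMALL_TOWN, RucaLevel.METROPOLITAN),
        (RucaLevel.RURAL, RucaLevel.METROPOLITAN),
        (RucaLevel.SMALL_TOWN, RucaLevel.MICROPOLITAN),
        (RucaLevel.RURAL, RucaLevel.MICROPOLITAN),
        (RucaLevel.RURAL, RucaLevel.SMALL_TOWN),
    ]
    raw = [ruca_ratio(fit, a, b) for a, b in pairs]
    present = [c for c in raw if not c.absent]
    adjusted = simultaneous_ci(present, family_alpha=family_alpha)
    adj_map = {(c.label_a, c.label_b): c for c in adjusted}
    return [adj_map.get((c.label_a, c.label_b), c) for c in raw]


def simultaneous_ci(
    contrasts: list[ContrastResult], family_alpha: float = 0.05
) -> list[ContrastResult]:
    """Bonferroni-simultaneous CIs: each interval at alpha/m for m contrasts."""
    m = len(contrasts)
    if m == 0:
        raise ValueError("empty contrast family")
    alpha = family_alpha / m
    out = []
    for c in contrasts:
        if c.absent:
            out.append(c)
            continue
        if c.se == 0.0:
            out.append(replace(c, alpha_adjusted=alpha))
            continue
        lo, hi = _ci(c.log_ratio, c.se, alpha)
        out.append(replace(c, ci_low=lo, ci_high=hi, alpha_adjusted=alpha))
    return out


def conditional_appalachia_effect(
    fit: FitResult, poverty_pct: float, alpha: float = 0.05
) -> ContrastResult:
    """Appalachian vs non-Appalachian density ratio at a given poverty level.

    With a poverty-by-Appalachia interaction in the model, the log ratio is
    beta_app + beta_int * poverty/10; its variance is the quadratic form of
    the contrast vector with the sandwich covariance (delta method on a
    linear combination).  Without the interaction the main effect is
    returned, with a log note.
    """
    if "appalachia" not in fit.names:
        raise KeyError("model has no appalachia term")
    c = np.zeros(len(fit.names))
    c[fit.names.index("appalachia")] = 1.0
    inter = next((n for n in fit.names if set(n.split(":")) == {"pct_poverty", "appalachia"}), None)
    if inter is None:
        logger.info("no poverty x appalachia interaction; using main effect only")
    else:
        c[fit.names.index(inter)] = poverty_pct / 10.0
    b = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.sandwich_cov @ c))
    lo, hi = _ci(b, se, alpha)
    return ContrastResult(
        label_a=f"Appalachian@poverty={poverty_pct:g}", label_b="non-Appalachian",
        log_ratio=b, se=se, ci_low=lo, ci_high=hi, alpha_adjusted=alpha,
    )


def effect_curve(
    fit: FitResult,
    covariate: str,
    observed_min: float,
    observed_max: float,
    reference: float = 0.0,
    n_grid: int = 101,
    alpha: float = 0.05,
) -> EffectCurve:
    """Multiplicative effect of a covariate over its observed range.

    The grid never extends past the observed data range, so the curve is
    only drawn where the state actually has tracts.  Ratios are relative
    to the ``reference`` covariate value; pointwise 95% bands use the
    sandwich SE.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if covariate not in fit.names:
        raise KeyError(f"covariate {covariate!r} not in model")
    b = fit.coef(covariate)
    se = fit.se(covariate)
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    grid = np.linspace(observed_min, observed_max, n_grid)
    dx = (grid - reference) / 10.0
    log_ratio = b * dx
    half = zc * se * np.abs(dx)
    lo = np.exp(log_ratio - half)
    hi = np.exp(log_ratio + half)
    return EffectCurve(
        covariate=covariate,
        reference=reference,
        grid=grid,
        ratio=np.exp(log_ratio),
        ci_low=lo,
        ci_high=hi,
        excludes_one=(lo > 1.0) | (hi < 1.0),
    )


def contrasts_to_frame(contrasts: list[ContrastResult]):
    """Contrast table as a DataFrame; absent levels rendered as a dash."""
    import pandas as pd

    rows = []
    for c in contrasts:
        if c.absent:
            rows.append(
                {"comparison": f"{c.label_a} vs {c.label_b}", "ratio": "–",
                 "ci_low": "–", "ci_high": "–", "alpha_adjusted": ""}
            )
        else:
            rows.append(
                {"comparison": f"{c.label_a} vs {c.label_b}",
                 "ratio": round(c.ratio, 6), "ci_low": round(c.ci_low, 6),
                 "ci_high": round(c.ci_high, 6), "alpha_adjusted": c.alpha_adjusted}
            )
    return pd.DataFrame(rows)
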