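"""Exploratory summaries of tobacco retailer density (TRD).

Per-tract TRD distributions are summarised by median and interquartile
range, overall and by rurality level, alongside an aggregate density
(total retailers per 1000 total residents).  Marginal associations between
log TRD and the percentage covariates are Pearson correlations; a small
offset is added inside the log only for this calculation, to guard against
log of zero.  These summaries ignore spatial dependence by design — they
describe, the models infer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from trdspat.tract_data import RucaLevel, TractRecord


@dataclass(frozen=True)
class TrdSummary:
    stratum: str
    n_tracts: int
    n_retailers: int
    median_trd: float | None
    iqr_trd: float | None
    mean_trd: float | None  # aggregate retailers per 1000 residents


@dataclass(frozen=True)
class CorrelationResult:
    covariate: str
    r: float
    p_value: float
    n: int


def _summary(stratum: str, tracts: Sequence[TractRecord]) -> TrdSummary:
    if not tracts:
        return TrdSummary(stratum, 0, 0, None, None, None)
    trd = np.array([t.trd for t in tracts])
    pop = sum(t.population for t in tracts)
    n_ret = sum(t.retailer_count for t in tracts)
    # quartiles by linear interpolation between order statistics
    q1, q3 = np.percentile(trd, [25, 75])
    return TrdSummary(
        stratum=stratum,
        n_tracts=len(tracts),
        n_retailers=int(n_ret),
        median_trd=float(np.median(trd)),
        iqr_trd=float(q3 - q1),
        mean_trd=1000.0 * n_ret / pop,
    )


def summarize_trd(
    tracts: Sequence[TractRecord], by_ruca: bool = True
) -> list[TrdSummary]:
    """TRD distribution summaries, overall and optionally per RUCA level."""
    out = [_summary("overall", list(tracts))]
    if by_ruca:
        for level in RucaLevel:
            sub = [t for t in tracts if t.ruca_level is level]
            if sub:
                out.append(_summary(level.value, sub))
    return out


def log_trd_correlation(
    tracts: Sequence[TractRecord], covariate: str, offset: float = 0.01
) -> CorrelationResult:
    """Pearson correlation of log(TRD + offset) with a percentage covariate.

    The offset (default 0.01) enters only here, never in model fitting.
    The two-sided p-value uses the t transform with n - 2 degrees of
    freedom.
    """
    x = np.array([getattr(t, covariate) for t in tracts], dtype=float)
    y = np.log(np.array([t.trd for t in tracts]) + offset)
    if len(x) < 3:
        raise ValueError("need at least 3 tracts for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: constant covariate or constant TRD")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(covariate=covariate, r=float(r), p_value=float(p), n=len(x))


def summaries_to_frame(summaries: Sequence[TrdSummary]):
    """Tidy DataFrame of TRD summaries, one row per stratum."""
    import pandas as pd

    return pd.DataFrame([s.__dict__ for s in summaries])
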