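"""Methylation-risk-score survival stratification.

Patients are split into high/low risk at an MRS cutoff (shipped default
0.44; strictly greater than the cutoff is high risk), prognosis is
summarized by Kaplan-Meier medians and Cox proportional-hazards fits
(Efron tie handling, Wald intervals, Harrell concordance), and a
maximally selected log-rank scan over a cutoff grid is provided as an
explicitly exploratory tool — the statistic at the selected cutoff is
selection-inflated and must not be read as a hypothesis test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MRS_CUTOFF",
    "KmSummary",
    "CoxFit",
    "stratify_by_mrs",
    "km_median",
    "fit_cox",
    "find_mrs_cutoff",
]

DEFAULT_MRS_CUTOFF = 0.44
NOT_REACHED = math.inf  # sentinel for a KM curve that never crosses 0.5


@dataclass(frozen=True)
class KmSummary:
    median: float  # months; NOT_REACHED (inf) when the curve stays above 0.5
    ci_low: float
    ci_high: float
    n: int
    n_events: int

    @property
    def reached(self) -> bool:
        return math.isfinite(self.median)


@dataclass(frozen=True)
class CoxFit:
    hazard_ratios: pd.Series  # per covariate
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    concordance_index: float
    penalized: bool = False


def stratify_by_mrs(mrs, cutoff: float = DEFAULT_MRS_CUTOFF):
    """Risk group from the Methylation Risk Score: ``high`` iff
    mrs > cutoff, else ``low``.  Accepts a scalar or an array/Series."""
    arr = np.asarray(mrs, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("MRS values must lie in [0, 1]")
    groups = np.where(arr > cutoff, "high", "low")
    if np.isscalar(mrs) or arr.ndim == 0:
        return str(groups[()])
    if isinstance(mrs, pd.Series):
        return pd.Series(groups, index=mrs.index, name="risk_group")
    return groups


def km_median(times, events, conf: float = 0.95) -> KmSummary:
    """Kaplan-Meier median overall survival with confidence bounds.

    The median is the earliest time at which the product-limit estimate
    drops to <= 0.5; when the curve never reaches 0.5 the median (and
    any undefined bound) is the ``NOT_REACHED`` (infinity) sentinel.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty group")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter(alpha=1 - conf)
    kmf.fit(times, events)
    med = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KmSummary(
        median=med if math.isfinite(med) else NOT_REACHED,
        ci_low=lo if math.isfinite(lo) else NOT_REACHED,
        ci_high=hi if math.isfinite(hi) else NOT_REACHED,
        n=len(times),
        n_events=int(events.sum()),
    )


def fit_cox(
    table: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "os_months",
    event_col: str = "event",
    conf: float = 0.95,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) over the named covariates.

    On monotone-likelihood/complete-separation failures the fit is
    retried with a small ridge penalty and flagged ``penalized``.
    """
    for col in [duration_col, event_col, *covariates]:
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from survival table")
    for cov in covariates:
        if table[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    if table[table[event_col] == 1][duration_col].nunique() < 2:
        raise ValueError("need >= 2 distinct event times")
    sub = table[[duration_col, event_col, *covariates]].dropna()

    penalized = False
    cph = CoxPHFitter(alpha=1 - conf)
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except Exception:  # monotone likelihood / separation
        logger.warning("Cox fit failed unpenalized; retrying with ridge penalty 0.1")
        penalized = True
        cph = CoxPHFitter(penalizer=0.1, alpha=1 - conf)
        cph.fit(sub, duration_col=duration_col, event_col=event_col)

    summary = cph.summary
    lo_col = f"exp(coef) lower {int(conf * 100)}%"
    hi_col = f"exp(coef) upper {int(conf * 100)}%"
    return CoxFit(
        hazard_ratios=summary["exp(coef)"].copy(),
        ci_low=summary[lo_col].copy(),
        ci_high=summary[hi_col].copy(),
        p_values=summary["p"].copy(),
        concordance_index=float(cph.concordance_index_),
        penalized=penalized,
    )


def find_mrs_cutoff(
    mrs,
    times,
    events,
    grid=None,
    min_group_frac: float = 0.15,
) -> tuple[float, float]:
    """Maximally selected log-rank scan for an MRS cutoff.

    Returns ``(cutoff, statistic)`` where the statistic is the log-rank
    chi-square at the selected grid point — exploratory only, since the
    maximization inflates it.  Grid points leaving less than
    ``min_group_frac`` of patients on either side are inadmissible.
    """
    mrs = np.asarray(mrs, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(mrs) < 10:
        raise ValueError("need >= 10 patients for a cutoff search")
    if events.sum() < 5:
        raise ValueError("need >= 5 events for a cutoff search")
    if grid is None:
        grid = np.round(np.arange(0.05, 0.96, 0.01), 2)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))

    best: tuple[float, float] | None = None
    for cut in grid:
        high = mrs > cut
        frac = high.mean()
        if len(grid) > 1 and not (min_group_frac <= frac <= 1 - min_group_frac):
            continue
        if high.all() or not high.any():
            continue
        res = logrank_test(times[high], times[~high], events[high], events[~high])
        stat = float(res.test_statistic)
        if best is None or stat > best[1]:
            best = (float(cut), stat)
    if best is None:
        raise ValueError("no admissible cutoff in the grid")
    return best
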