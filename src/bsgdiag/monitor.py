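"""Longitudinal CSF ctDNA monitoring.

Tracks the Methylation Signature Score (MSS) and driver-mutation VAF of
one patient across timepoints, labels per-interval score dynamics, and
flags minimal residual disease (MRD): methylation signal above a
detection floor while the mutation VAF has dropped below its own
(higher) detection limit.  VAF "undetectable" is an explicit sentinel
(``None``), never conflated with a measured 0.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scores import MssResult

logger = logging.getLogger(__name__)

__all__ = [
    "SeriesPoint",
    "LongitudinalSeries",
    "pearson_concordance",
    "mss_dynamics",
    "mrd_flag",
    "mss_detection_floor",
]

STABILITY_BAND = 0.005  # |delta| below this is called "stable"


@dataclass(frozen=True)
class SeriesPoint:
    day: float
    timepoint: str  # A=pre-op, B=intra-op, C=post-op, D=follow-up
    mss: MssResult
    vaf: float | None  # None = undetectable
    phase: str = ""

    def __post_init__(self) -> None:
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF must be in [0, 1] or None; got {self.vaf}")


@dataclass
class LongitudinalSeries:
    patient_id: str
    points: list[SeriesPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [p.day for p in self.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"timestamps must be strictly increasing; got {days}")

    def __len__(self) -> int:
        return len(self.points)


def pearson_concordance(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-based p-value.

    Used for tissue-CSF score concordance and VAF-MSS agreement.
    Requires >= 3 finite pairs and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must align")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired finite values; got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def mss_dynamics(series: LongitudinalSeries, stability_band: float = STABILITY_BAND) -> pd.DataFrame:
    """Per-point MSS deltas vs the previous point and vs baseline.

    QC-failed points are excluded with a logged reason.  Directions are
    ``increase`` / ``decrease`` / ``stable`` (|delta| < ``stability_band``)
    and depend only on score values, not on the absolute timestamps.
    """
    usable = [p for p in series.points if p.mss.qc_pass]
    n_excluded = len(series.points) - len(usable)
    if n_excluded:
        logger.info(
            "mss_dynamics(%s): excluded %d QC-failed point(s)", series.patient_id, n_excluded
        )
    if len(usable) < 2:
        raise ValueError("need >= 2 QC-passing points for dynamics")

    baseline = usable[0].mss.value
    rows = []
    for prev, cur in zip(usable, usable[1:]):
        d_prev = cur.mss.value - prev.mss.value
        d_base = cur.mss.value - baseline
        rows.append(
            {
                "day": cur.day,
                "timepoint": cur.timepoint,
                "mss": cur.mss.value,
                "delta_prev": d_prev,
                "delta_baseline": d_base,
                "direction_prev": _direction(d_prev, stability_band),
                "direction_baseline": _direction(d_base, stability_band),
            }
        )
    return pd.DataFrame(rows)


def _direction(delta: float, band: float) -> str:
    if abs(delta) < band:
        return "stable"
    return "increase" if delta > 0 else "decrease"


def mrd_flag(point: SeriesPoint, mss_floor: float) -> bool | None:
    """Minimal-residual-disease call for one monitoring point.

    True iff the mutation VAF is undetectable while the MSS exceeds
    ``mss_floor`` — methylation signal outlasting mutation evidence.
    Returns ``None`` (indeterminate) when the point's MSS failed QC.
    """
    if not point.mss.qc_pass:
        return None
    return point.vaf is None and point.mss.value > mss_floor


def mss_detection_floor(background_mss, q: float = 0.95) -> float:
    """Calibrate the MSS detection floor as the ``q`` quantile of scores
    from background (tumor-free or double-wildtype) samples."""
    background_mss = np.asarray(background_mss, dtype=float)
    if len(background_mss) == 0:
        raise ValueError("need background scores to calibrate the floor")
    return float(np.quantile(background_mss, q))
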