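"""Methylation Signature Score (MSS).

The MSS condenses a marker panel into one number per sample:

    MSS = ( sum(beta at H3-specific sites)
            + (1 - sum(beta at IDH-specific sites)) ) / N

with N the total probe count of the panel.  H3K27M-mutant tumors are
hypermethylated at H3-specific sites and hypomethylated at IDH-specific
sites, so they score highest; IDH-mutant tumors (hypermethylated at all
panel sites) score lowest; double-wildtype samples sit near zero.  The
attainable range for a panel with n_h3/n_idh probes is
[(1 - n_idh)/N, (n_h3 + 1)/N], which always lies inside [-1, 1].

Missing probes are handled by class-proportional rescaling: each class
sum over observed probes is scaled by n_class / n_observed_class, which
leaves the expected score unchanged under probes missing completely at
random.  A coverage QC flag marks samples observed below ``min_coverage``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .markers import MarkerPanel

__all__ = ["MssResult", "compute_mss", "mss_bounds", "compute_mss_frame"]


@dataclass(frozen=True)
class MssResult:
    value: float
    n_observed_h3: int
    n_observed_idh: int
    coverage: float
    qc_pass: bool


def mss_bounds(panel: MarkerPanel) -> tuple[float, float]:
    """Attainable (min, max) of the score for a given panel."""
    n = panel.n_h3 + panel.n_idh
    return (1 - panel.n_idh) / n, (panel.n_h3 + 1) / n


def compute_mss(
    sample_betas: "pd.Series | Mapping[str, float]",
    panel: MarkerPanel,
    min_coverage: float = 0.5,
) -> MssResult:
    """Score one sample over a marker panel.

    Raises ``ValueError`` when the panel lacks probes of either class or
    when a class has zero observed probes in the sample (the rescaled sum
    is undefined then).
    """
    if panel.n_h3 < 1 or panel.n_idh < 1:
        raise ValueError("panel needs at least one probe of each marker class")
    betas = pd.Series(sample_betas, dtype=float)

    h3_obs = betas.reindex(panel.h3_sites).dropna()
    idh_obs = betas.reindex(panel.idh_sites).dropna()
    if len(h3_obs) == 0 or len(idh_obs) == 0:
        raise ValueError(
            f"score undefined: observed probes H3={len(h3_obs)}, IDH={len(idh_obs)}"
        )
    if ((h3_obs < 0) | (h3_obs > 1)).any() or ((idh_obs < 0) | (idh_obs > 1)).any():
        raise ValueError("beta values outside [0, 1]")

    n = panel.n_h3 + panel.n_idh
    sum_h3 = float(h3_obs.sum()) * panel.n_h3 / len(h3_obs)
    sum_idh = float(idh_obs.sum()) * panel.n_idh / len(idh_obs)
    value = (sum_h3 + (1.0 - sum_idh)) / n

    coverage = (len(h3_obs) + len(idh_obs)) / n
    return MssResult(
        value=float(value),
        n_observed_h3=int(len(h3_obs)),
        n_observed_idh=int(len(idh_obs)),
        coverage=float(coverage),
        qc_pass=bool(coverage >= min_coverage),
    )


def compute_mss_frame(
    betas: pd.DataFrame, panel: MarkerPanel, min_coverage: float = 0.5
) -> pd.DataFrame:
    """Per-sample MSS table for a beta matrix (rows = samples)."""
    rows = {}
    for sample_id, sample in betas.iterrows():
        r = compute_mss(sample, panel, min_coverage)
        rows[sample_id] = {
            "mss": r.value,
            "n_observed_h3": r.n_observed_h3,
            "n_observed_idh": r.n_observed_idh,
            "coverage": r.coverage,
            "qc_pass": r.qc_pass,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    if not out.empty:
        out = out.astype({"n_observed_h3": int, "n_observed_idh": int, "qc_pass": bool})
    return out
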