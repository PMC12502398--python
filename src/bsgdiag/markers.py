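"""De novo CpG marker discovery for glioma subtype classification.

The screening stage mirrors targeted-methylation assay design: split the
array cohort into discovery/held-out portions, screen CpGs by rank-sum
test plus an absolute delta-beta cutoff, reduce candidates with a
three-algorithm consensus (random forest importance, linear max-margin
weights, L1 multinomial path order), and finally assign each retained
site a marker class:

* ``H3_specific`` — consistently hypermethylated in H3K27M-mutant tumors
  relative to both IDH-mutant and other (double-wildtype/control) samples;
* ``IDH_specific`` — hypermethylated in IDH-mutant tumors while H3K27M
  tumors stay low (comparable to the other samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .io import atomic_write_text

logger = logging.getLogger(__name__)

__all__ = [
    "DmCpgRecord",
    "MarkerPanel",
    "split_discovery",
    "find_dm_cpgs",
    "select_consensus_features",
    "assign_marker_classes",
    "discover_marker_panel",
]

H3_SPECIFIC = "H3_specific"
IDH_SPECIFIC = "IDH_specific"


@dataclass(frozen=True)
class DmCpgRecord:
    """One differentially methylated CpG from a two-group contrast."""

    cpg_id: str
    group_pair: tuple[str, str]
    delta_beta: float  # mean(A) - mean(B), available-case means
    p_value: float
    q_value: float


@dataclass
class MarkerPanel:
    """Ordered CpG marker set with H3-/IDH-specific class labels."""

    entries: pd.DataFrame  # columns: cpg_id, marker_class, delta_beta, q_value
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"cpg_id", "marker_class"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"panel entries need columns {sorted(required)}")
        classes = set(self.entries["marker_class"])
        if not classes.issubset({H3_SPECIFIC, IDH_SPECIFIC}):
            raise ValueError(f"unknown marker classes: {classes - {H3_SPECIFIC, IDH_SPECIFIC}}")
        if self.entries["cpg_id"].duplicated().any():
            raise ValueError("duplicate CpG ids in panel")

    @property
    def h3_sites(self) -> list[str]:
        mask = self.entries["marker_class"] == H3_SPECIFIC
        return self.entries.loc[mask, "cpg_id"].tolist()

    @property
    def idh_sites(self) -> list[str]:
        mask = self.entries["marker_class"] == IDH_SPECIFIC
        return self.entries.loc[mask, "cpg_id"].tolist()

    @property
    def n_h3(self) -> int:
        return int((self.entries["marker_class"] == H3_SPECIFIC).sum())

    @property
    def n_idh(self) -> int:
        return int((self.entries["marker_class"] == IDH_SPECIFIC).sum())

    @property
    def cpg_ids(self) -> list[str]:
        return self.entries["cpg_id"].tolist()

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        atomic_write_text(path, self.entries.to_csv(sep="\t", index=False))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerPanel":
        return cls(pd.read_csv(path, sep="\t", dtype={"cpg_id": str}))

    @classmethod
    def from_sites(cls, h3_sites: Sequence[str], idh_sites: Sequence[str]) -> "MarkerPanel":
        entries = pd.DataFrame(
            {
                "cpg_id": list(h3_sites) + list(idh_sites),
                "marker_class": [H3_SPECIFIC] * len(h3_sites) + [IDH_SPECIFIC] * len(idh_sites),
            }
        )
        return cls(entries)


def split_discovery(
    labels: pd.Series, frac: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Class-stratified discovery/held-out split of sample ids.

    Each class contributes ``round(frac * class size)`` samples to the
    discovery set, so the per-class share is within one sample of
    ``frac``.  Deterministic under ``seed``.
    """
    if not (0 < frac <= 1):
        raise ValueError(f"frac must be in (0, 1]; got {frac}")
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    discovery: list[str] = []
    test: list[str] = []
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        if len(ids) == 0:
            raise ValueError(f"class {cls!r} has no samples")
        n_disc = int(round(frac * len(ids)))
        if frac < 1:
            n_disc = min(max(n_disc, 1), len(ids))
        perm = rng.permutation(len(ids))
        discovery.extend(ids[perm[:n_disc]])
        test.extend(ids[perm[n_disc:]])
    return sorted(discovery), sorted(test)


def find_dm_cpgs(
    betas: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str],
    delta_min: float = 0.3,
    alpha: float = 0.05,
) -> list[DmCpgRecord]:
    """Screen CpGs differential between two classes.

    A site is retained when |mean(A) - mean(B)| >= ``delta_min`` (group
    means over available cases) and its Benjamini-Hochberg adjusted
    Wilcoxon rank-sum p-value is below ``alpha``.  Results are sorted by
    |delta_beta| descending.  All-missing sites are excluded (counted in
    a log line), not an error.
    """
    if not (0 <= delta_min <= 1):
        raise ValueError(f"delta_min must be in [0, 1]; got {delta_min}")
    a, b = pair
    labels = pd.Series(labels).reindex(betas.index)
    mask_a = (labels == a).to_numpy()
    mask_b = (labels == b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(f"both classes in {pair} need >= 2 samples")

    xa = betas.loc[mask_a]
    xb = betas.loc[mask_b]
    # available-case means; sites with no observations in either group drop out
    mean_a = xa.mean(axis=0, skipna=True)
    mean_b = xb.mean(axis=0, skipna=True)
    valid = mean_a.notna() & mean_b.notna()
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("find_dm_cpgs: excluded %d all-missing site(s)", n_dropped)

    cpgs = betas.columns[valid]
    delta = (mean_a - mean_b)[valid]
    pvals = np.empty(len(cpgs))
    for i, cpg in enumerate(cpgs):
        va = xa[cpg].dropna().to_numpy()
        vb = xb[cpg].dropna().to_numpy()
        if len(va) == 0 or len(vb) == 0 or (np.ptp(np.concatenate([va, vb])) == 0):
            pvals[i] = 1.0
        else:
            pvals[i] = stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]

    keep = (np.abs(delta.to_numpy()) >= delta_min) & (qvals < alpha)
    records = [
        DmCpgRecord(
            cpg_id=str(cpg),
            group_pair=(a, b),
            delta_beta=float(delta.iloc[i]),
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
        )
        for i, cpg in enumerate(cpgs)
        if keep[i]
    ]
    records.sort(key=lambda r: (-abs(r.delta_beta), r.cpg_id))
    return records


def select_consensus_features(
    betas: pd.DataFrame,
    labels: pd.Series,
    candidates: Iterable[str],
    k: int,
    seed: int = 0,
) -> list[str]:
    """Consensus feature reduction over three selection algorithms.

    Each algorithm ranks the candidate CpGs: (i) impurity importance from
    a random forest, (ii) aggregate |weight| from one-vs-rest linear SVMs,
    (iii) order of first entry along an L1-regularized multinomial
    logistic path.  A site is *selected* by an algorithm when it lies in
    that algorithm's top ``k``; the consensus keeps sites selected by at
    least two of the three, truncated to ``k`` by mean rank.  The result
    is invariant to candidate order and deterministic under ``seed``.
    """
    candidates = sorted(set(candidates))
    if k <= 0:
        raise ValueError(f"k must be positive; got {k}")
    missing_cols = [c for c in candidates if c not in betas.columns]
    if missing_cols:
        raise ValueError(f"candidates absent from matrix: {missing_cols[:5]}")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds candidate count {len(candidates)}")

    labels = pd.Series(labels).reindex(betas.index)
    x = betas[candidates].to_numpy(dtype=float)
    # median-impute per column: the selectors need complete data
    col_med = np.nanmedian(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_med, inds[1])
    y = labels.to_numpy()

    ranks = pd.DataFrame(index=candidates)
    ranks["rf"] = _rank_desc(_rf_importance(x, y, seed), candidates)
    ranks["svm"] = _rank_desc(_svm_weight(x, y), candidates)
    ranks["lasso"] = _rank_desc(-_lasso_entry_order(x, y), candidates)

    selected_by = (ranks <= k).sum(axis=1)
    consensus = ranks.index[selected_by >= 2]
    if len(consensus) == 0:  # degenerate: fall back to overall mean rank
        consensus = ranks.index
    mean_rank = ranks.loc[consensus].mean(axis=1).sort_values(kind="stable")
    return sorted(mean_rank.index[:k].tolist())


def _rank_desc(score: np.ndarray, index: Sequence[str]) -> pd.Series:
    s = pd.Series(score, index=index)
    return s.rank(ascending=False, method="first")


def _rf_importance(x: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    rf = RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    rf.fit(x, y)
    return rf.feature_importances_


def _svm_weight(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xs = StandardScaler().fit_transform(x)
    svm = LinearSVC(C=1.0, dual=False, max_iter=5000)
    svm.fit(xs, y)
    w = np.atleast_2d(svm.coef_)
    return np.abs(w).sum(axis=0)


def _lasso_entry_order(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Step index at which each feature first gets a nonzero coefficient
    along a decreasing-penalty multinomial L1 path (lower = earlier)."""
    xs = StandardScaler().fit_transform(x)
    n_steps = 30
    cs = np.logspace(-2.5, 1.5, n_steps)
    entry = np.full(x.shape[1], n_steps, dtype=float)
    for step, c in enumerate(cs):
        clf = LogisticRegression(l1_ratio=1.0, C=c, solver="saga", max_iter=2000, tol=1e-3)
        clf.fit(xs, y)
        nonzero = np.abs(clf.coef_).sum(axis=0) > 1e-10
        entry = np.where(nonzero & (entry == n_steps), step, entry)
        if nonzero.all():
            break
    return entry


def assign_marker_classes(
    betas: pd.DataFrame,
    labels: pd.Series,
    cpgs: Iterable[str],
    margin: float = 0.2,
    h3_label: str = "H3K27M",
    idh_label: str = "IDH",
) -> MarkerPanel:
    """Label each CpG H3-specific or IDH-specific from class mean betas.

    ``H3_specific``: mean(H3) exceeds both mean(IDH) and the mean of every
    other class by ``margin``.  ``IDH_specific``: mean(IDH) exceeds
    mean(H3) by ``margin`` while mean(H3) stays within ``margin`` of the
    other classes (H3 tumors are hypomethylated there).  Sites matching
    neither rule are dropped with a logged reason.  Raises when either
    marker class comes out empty — the signature score is undefined then.
    """
    labels = pd.Series(labels).reindex(betas.index)
    classes = set(labels.dropna().unique())
    if h3_label not in classes or idh_label not in classes:
        raise ValueError(f"labels must contain {h3_label!r} and {idh_label!r}")
    other_classes = sorted(classes - {h3_label, idh_label})

    cpgs = [c for c in cpgs]
    sub = betas[cpgs]
    mean_h3 = sub.loc[(labels == h3_label).to_numpy()].mean(axis=0, skipna=True)
    mean_idh = sub.loc[(labels == idh_label).to_numpy()].mean(axis=0, skipna=True)
    mean_other = {
        cls: sub.loc[(labels == cls).to_numpy()].mean(axis=0, skipna=True)
        for cls in other_classes
    }

    rows = []
    n_dropped = 0
    for cpg in cpgs:
        h3, idh = mean_h3[cpg], mean_idh[cpg]
        others = [m[cpg] for m in mean_other.values()]
        is_h3 = h3 >= idh + margin and all(h3 >= o + margin for o in others)
        is_idh = idh >= h3 + margin and all(h3 <= o + margin for o in others)
        if is_h3:
            rows.append((cpg, H3_SPECIFIC, float(h3 - idh)))
        elif is_idh:
            rows.append((cpg, IDH_SPECIFIC, float(h3 - idh)))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("assign_marker_classes: dropped %d site(s) matching neither pattern", n_dropped)

    entries = pd.DataFrame(rows, columns=["cpg_id", "marker_class", "delta_beta"])
    if entries.empty or (entries["marker_class"] == H3_SPECIFIC).sum() == 0:
        raise ValueError("no H3-specific markers assigned; signature score undefined")
    if (entries["marker_class"] == IDH_SPECIFIC).sum() == 0:
        raise ValueError("no IDH-specific markers assigned; signature score undefined")
    return MarkerPanel(entries, provenance={"margin": margin, "n_dropped": n_dropped})


def discover_marker_panel(
    betas: pd.DataFrame,
    labels: pd.Series,
    delta_min: float = 0.3,
    alpha: float = 0.05,
    k: int = 76,
    margin: float = 0.2,
    discovery_frac: float = 0.7,
    seed: int = 0,
    h3_label: str = "H3K27M",
    idh_label: str = "IDH",
) -> MarkerPanel:
    """End-to-end screening: split, differential screening over all
    class-pair contrasts, consensus selection, marker-class assignment.

    Assignment reuses the discovery samples only; the held-out split is
    left to the caller for unbiased evaluation.
    """
    labels = pd.Series(labels).reindex(betas.index)
    disc_ids, _ = split_discovery(labels, discovery_frac, seed)
    disc = betas.loc[disc_ids]
    disc_labels = labels.loc[disc_ids]

    classes = sorted(labels.dropna().unique())
    pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1 :]]
    candidates: set[str] = set()
    for pair in pairs:
        candidates.update(r.cpg_id for r in find_dm_cpgs(disc, disc_labels, pair, delta_min, alpha))
    if not candidates:
        raise ValueError("no differentially methylated CpGs passed screening")

    k_eff = min(k, len(candidates))
    selected = select_consensus_features(disc, disc_labels, candidates, k_eff, seed)
    return assign_marker_classes(disc, disc_labels, selected, margin, h3_label, idh_label)
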