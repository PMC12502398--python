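"""Three-class methylation classifier and the mutation-methylation fusion.

A random forest trained on panel beta values assigns each sample a
probability triple over {H3K27M, IDH, DW}.  The Methylation Risk Score
(MRS) is the forest's predicted H3K27M probability.  Mutation evidence is
converted to a deterministic triple — a called driver sets its subtype's
probability to 1, everything else to 0 — and the fused diagnosis takes
the per-class maximum of the two triples, calling the class with the
highest combined probability (ties broken H3K27M > IDH > DW, the
worst-prognosis class first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import MutationProfile, atomic_write_text

__all__ = [
    "CLASSES",
    "SubtypeProbs",
    "MethylationModel",
    "Diagnosis",
    "train_methylation_classifier",
    "predict_methylation_probs",
    "predict_methylation_frame",
    "mutation_probs",
    "fuse_bsgdiag",
    "classify_samples",
]

# canonical class order; also the tie-break priority (worst prognosis first)
CLASSES = ("H3K27M", "IDH", "DW")


@dataclass(frozen=True)
class SubtypeProbs:
    """Probability triple over the three molecular subtypes.

    Methylation-model triples sum to 1; mutation-derived triples are
    indicator-valued with at most one 1 (``conflict`` marks the
    biologically anomalous case of both drivers called, resolved in
    favor of H3K27M).
    """

    p_h3: float
    p_idh: float
    p_dw: float
    conflict: bool = False

    def __post_init__(self) -> None:
        for name, p in (("p_h3", self.p_h3), ("p_idh", self.p_idh), ("p_dw", self.p_dw)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_h3, self.p_idh, self.p_dw], dtype=float)

    @property
    def is_normalized(self) -> bool:
        return abs(self.p_h3 + self.p_idh + self.p_dw - 1.0) <= 1e-9

    def argmax_class(self) -> str:
        # np.argmax returns the first maximum, and CLASSES is ordered by priority
        return CLASSES[int(np.argmax(self.as_array()))]


@dataclass
class MethylationModel:
    forest: RandomForestClassifier
    panel_cpgs: list[str]
    impute_medians: pd.Series  # training-set, class-agnostic per-probe medians
    cv_report: pd.DataFrame
    best_params: dict
    seed: int
    min_coverage: float = 0.1

    def save(self, path: str | Path) -> None:
        """Serialize as a directory: meta.json + model.joblib."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "classes": list(CLASSES),
            "panel_cpgs": self.panel_cpgs,
            "impute_medians": {k: float(v) for k, v in self.impute_medians.items()},
            "best_params": self.best_params,
            "seed": self.seed,
            "min_coverage": self.min_coverage,
            "cv_report": self.cv_report.to_dict(orient="list"),
        }
        atomic_write_text(path / "meta.json", json.dumps(meta, indent=2) + "\n")
        joblib.dump(self.forest, path / "model.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "MethylationModel":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported model format: {meta.get('format_version')}")
        return cls(
            forest=joblib.load(path / "model.joblib"),
            panel_cpgs=meta["panel_cpgs"],
            impute_medians=pd.Series(meta["impute_medians"]),
            cv_report=pd.DataFrame(meta["cv_report"]),
            best_params=meta["best_params"],
            seed=meta["seed"],
            min_coverage=meta["min_coverage"],
        )


@dataclass(frozen=True)
class Diagnosis:
    predicted_class: str
    combined: SubtypeProbs
    mrs: float | None  # methylation H3K27M probability; None without methylation
    evidence: str  # mutation_only | methylation_only | fused
    conflict_flag: bool = False


# small documented hyperparameter grid; the forest itself stays at 500 trees
_DEFAULT_GRID = [
    {"max_features": "sqrt", "min_samples_leaf": 1},
    {"max_features": "sqrt", "min_samples_leaf": 3},
    {"max_features": 0.3, "min_samples_leaf": 1},
    {"max_features": 0.3, "min_samples_leaf": 3},
]


def train_methylation_classifier(
    betas: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 10,
    seed: int = 0,
    grid: list[dict] | None = None,
    n_trees: int = 500,
) -> MethylationModel:
    """Fit the three-class forest with stratified CV model selection.

    Hyperparameters are chosen from a small grid by mean CV micro-AUC;
    the winning configuration is refit on all training data.  When the
    smallest class has fewer than ``n_folds`` members the fold count is
    reduced (with a warning) rather than failing.
    """
    labels = pd.Series(labels).reindex(betas.index)
    present = set(labels.dropna().unique())
    missing_classes = [c for c in CLASSES if c not in present]
    if missing_classes:
        raise ValueError(f"training labels lack class(es): {missing_classes}")

    x = betas.to_numpy(dtype=float)
    medians = betas.median(axis=0, skipna=True)
    col_med = medians.to_numpy()
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_med, inds[1])
    y = labels.to_numpy()

    min_class = int(pd.Series(y).value_counts().min())
    folds = n_folds
    if min_class < n_folds:
        folds = max(2, min_class)
        import warnings

        warnings.warn(
            f"reducing CV folds from {n_folds} to {folds}: smallest class has {min_class} samples",
            stacklevel=2,
        )

    grid = grid if grid is not None else _DEFAULT_GRID
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    report_rows = []
    for gi, params in enumerate(grid):
        fold_aucs = []
        for fi, (tr, te) in enumerate(splits):
            rf = _make_forest(n_trees, seed, params)
            rf.fit(x[tr], y[tr])
            probs = rf.predict_proba(x[te])
            probs = probs[:, [list(rf.classes_).index(c) for c in CLASSES]]
            onehot = np.stack([(y[te] == c).astype(float) for c in CLASSES], axis=1)
            auc = roc_auc_score(onehot.ravel(), probs.ravel())
            fold_aucs.append(auc)
            report_rows.append({"grid_index": gi, "fold": fi, "micro_auc": auc, **params})
        # mean AUC per grid point resolved below
    report = pd.DataFrame(report_rows)
    mean_auc = report.groupby("grid_index")["micro_auc"].mean()
    best_gi = int(mean_auc.idxmax())
    best_params = grid[best_gi]

    forest = _make_forest(n_trees, seed, best_params)
    forest.fit(x, y)
    return MethylationModel(
        forest=forest,
        panel_cpgs=list(betas.columns),
        impute_medians=medians,
        cv_report=report,
        best_params=dict(best_params),
        seed=seed,
    )


def _make_forest(n_trees: int, seed: int, params: dict) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1, **params)


def predict_methylation_probs(model: MethylationModel, sample_betas) -> SubtypeProbs:
    """Probability triple for one sample; MRS is the H3K27M component.

    Missing probes are imputed with the training-set medians; a sample
    with every panel probe missing is rejected.
    """
    betas = pd.Series(sample_betas, dtype=float).reindex(model.panel_cpgs)
    n_obs = int(betas.notna().sum())
    if n_obs == 0:
        raise ValueError("all panel probes missing; prediction undefined")
    coverage = n_obs / len(model.panel_cpgs)
    if coverage < model.min_coverage:
        raise ValueError(
            f"panel coverage {coverage:.2f} below model minimum {model.min_coverage:.2f}"
        )
    filled = betas.fillna(model.impute_medians).to_numpy(dtype=float)[None, :]
    raw = model.forest.predict_proba(filled)[0]
    order = [list(model.forest.classes_).index(c) for c in CLASSES]
    p = raw[order]
    return SubtypeProbs(p_h3=float(p[0]), p_idh=float(p[1]), p_dw=float(p[2]))


def predict_methylation_frame(model: MethylationModel, betas: pd.DataFrame) -> pd.DataFrame:
    """Per-sample probability table with an ``mrs`` column (= p_h3)."""
    rows = {}
    for sample_id, sample in betas.iterrows():
        p = predict_methylation_probs(model, sample)
        rows[sample_id] = {"p_h3": p.p_h3, "p_idh": p.p_idh, "p_dw": p.p_dw, "mrs": p.p_h3}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def mutation_probs(profile: MutationProfile | None) -> SubtypeProbs:
    """Deterministic mutation-predicted probability triple.

    An H3F3A or HIST1H3B/C K27M call sets p_h3 = 1; an IDH1/2 call sets
    p_idh = 1; the DW subtype has no positive mutation evidence, so p_dw
    is always 0.  If both (mutually exclusive in tumor biology) drivers
    are called, the triple resolves to H3K27M with ``conflict`` set.
    Unknown genes are ignored; an empty or None profile yields (0, 0, 0).
    """
    if profile is None:
        return SubtypeProbs(0.0, 0.0, 0.0)
    has_h3 = profile.has_h3_driver
    has_idh = profile.has_idh_driver
    conflict = has_h3 and has_idh
    if has_h3:
        return SubtypeProbs(1.0, 0.0, 0.0, conflict=conflict)
    if has_idh:
        return SubtypeProbs(0.0, 1.0, 0.0)
    return SubtypeProbs(0.0, 0.0, 0.0)


def fuse_bsgdiag(mut: SubtypeProbs | None, meth: SubtypeProbs | None) -> Diagnosis:
    """Fuse mutation and methylation evidence into the final diagnosis.

    Combined probability per class is max(mutation, methylation); the
    call is the argmax, ties broken H3K27M > IDH > DW.  The combined
    triple is deliberately not renormalized: a called driver certifies
    its class, and renormalizing would dilute that certainty without
    changing the argmax.  When one modality is absent (e.g. methylation
    only for a below-LOD CSF sample) the other passes through unchanged.
    """
    if mut is None and meth is None:
        raise ValueError("at least one evidence modality is required")
    if meth is not None:
        if not meth.is_normalized:
            raise ValueError(
                f"methylation probabilities must sum to 1; got {meth.as_array().sum():.6f}"
            )
        if meth.conflict:
            raise ValueError("conflict flag is only meaningful on mutation-derived triples")
    if mut is not None and not set(np.round(mut.as_array(), 12)).issubset({0.0, 1.0}):
        raise ValueError("mutation-derived probabilities must be 0/1 indicators")

    if mut is None:
        combined, evidence, conflict = meth, "methylation_only", False
    elif meth is None:
        combined, evidence, conflict = mut, "mutation_only", mut.conflict
    else:
        arr = np.maximum(mut.as_array(), meth.as_array())
        combined = SubtypeProbs(float(arr[0]), float(arr[1]), float(arr[2]))
        evidence, conflict = "fused", mut.conflict
    return Diagnosis(
        predicted_class=combined.argmax_class(),
        combined=combined,
        mrs=meth.p_h3 if meth is not None else None,
        evidence=evidence,
        conflict_flag=conflict,
    )


def classify_samples(
    model: MethylationModel,
    betas: pd.DataFrame,
    profiles: dict[str, MutationProfile] | None = None,
) -> pd.DataFrame:
    """Run the full per-sample diagnosis over a beta matrix.

    ``profiles`` may omit samples (below-LOD CSF: methylation only).
    Returns one row per sample with probabilities, MRS, the fused call,
    evidence source and the driver-conflict flag.
    """
    profiles = profiles or {}
    rows = {}
    for sample_id, sample in betas.iterrows():
        meth = predict_methylation_probs(model, sample)
        mut = mutation_probs(profiles[sample_id]) if sample_id in profiles else None
        d = fuse_bsgdiag(mut, meth)
        rows[sample_id] = {
            "predicted_class": d.predicted_class,
            "p_h3": d.combined.p_h3,
            "p_idh": d.combined.p_idh,
            "p_dw": d.combined.p_dw,
            "mrs": d.mrs,
            "evidence": d.evidence,
            "conflict_flag": d.conflict_flag,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
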