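"""File formats for the pipeline.

Beta matrices are tab-separated text: a header row of CpG ids, one row per
sample with the sample id in the first column, methylation ratios in [0, 1]
and ``NA`` for missing probes.  Mutation calls use a simplified MAF-like
TSV with columns ``sample_id``, ``gene``, ``variant``, ``vaf``; extra
columns are preserved.  All writers are atomic (temp file + rename) and
beta values are written with fixed 6-decimal precision so a write/read
round trip is exact.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MutationCall",
    "MutationProfile",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_mutation_table",
    "write_mutation_table",
    "atomic_write_text",
    "write_run_manifest",
    "H3_DRIVER_GENES",
    "IDH_DRIVER_GENES",
]

# Driver-gene vocabulary for the three-class molecular diagnosis.  The
# H3K27M subtype is defined by the K27M substitution in H3F3A or
# HIST1H3B/C; the IDH subtype by any IDH1/IDH2 call.
H3_DRIVER_GENES = frozenset({"H3F3A", "HIST1H3B", "HIST1H3C"})
IDH_DRIVER_GENES = frozenset({"IDH1", "IDH2"})

BETA_DECIMALS = 6
_MISSING = "NA"


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file in the same directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


@dataclass(frozen=True)
class MutationCall:
    gene: str
    variant: str
    vaf: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", str(self.gene).upper())
        if not np.isfinite(self.vaf) or not (0.0 <= self.vaf <= 1.0):
            raise ValueError(
                f"VAF must be in [0, 1]; got {self.vaf!r} for {self.gene} {self.variant}"
            )

    @property
    def is_h3_driver(self) -> bool:
        return self.gene in H3_DRIVER_GENES and "K27M" in self.variant.upper()

    @property
    def is_idh_driver(self) -> bool:
        return self.gene in IDH_DRIVER_GENES


@dataclass
class MutationProfile:
    """Per-sample gene-level mutation calls with driver summary flags."""

    sample_id: str
    calls: list[MutationCall] = field(default_factory=list)

    @property
    def has_h3_driver(self) -> bool:
        return any(c.is_h3_driver for c in self.calls)

    @property
    def has_idh_driver(self) -> bool:
        return any(c.is_idh_driver for c in self.calls)

    def vaf_of(self, genes: Iterable[str]) -> float | None:
        """Maximum VAF over calls in ``genes``, or None when absent."""
        genes = {g.upper() for g in genes}
        vafs = [c.vaf for c in self.calls if c.gene in genes]
        return max(vafs) if vafs else None


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a beta matrix TSV into a samples x CpGs DataFrame.

    Missing probes come back as NaN.  Raises ``ValueError`` on duplicate
    sample/CpG ids, malformed numerics, or values outside [0, 1]; the
    error message names the offending sample and CpG.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty beta matrix file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_MISSING], dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate CpG ids in {path}: {dups}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"malformed numeric value in {path}: {exc}") from exc
    bad = (values < 0) | (values > 1)
    if bad.any().any():
        sample = bad.index[bad.any(axis=1)][0]
        cpg = bad.columns[bad.loc[sample]][0]
        raise ValueError(
            f"beta value out of [0, 1] at sample {sample!r}, CpG {cpg!r}: "
            f"{values.loc[sample, cpg]}"
        )
    values.index.name = "sample_id"
    return values


def write_beta_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x CpGs DataFrame as TSV with NA for missing."""
    bad = ((matrix < 0) | (matrix > 1)).any()
    if bad.any():
        raise ValueError(f"beta values out of [0, 1] in columns: {list(bad[bad].index)}")
    out = matrix.copy()
    out.index.name = "sample_id"
    text = out.to_csv(sep="\t", na_rep=_MISSING, float_format=f"%.{BETA_DECIMALS}f")
    atomic_write_text(path, text)


_REQUIRED_MUT_COLS = ("sample_id", "gene", "variant", "vaf")


def read_mutation_table(path: str | Path) -> dict[str, MutationProfile]:
    """Read a MAF-like TSV into per-sample :class:`MutationProfile` objects.

    An empty table (header only) yields an empty dict.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str, "variant": str})
    missing = [c for c in _REQUIRED_MUT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table {path} lacks required column(s): {missing}")
    profiles: dict[str, MutationProfile] = {}
    for _, row in df.iterrows():
        call = MutationCall(gene=row["gene"], variant=str(row["variant"]), vaf=float(row["vaf"]))
        profiles.setdefault(row["sample_id"], MutationProfile(row["sample_id"])).calls.append(call)
    return profiles


def write_mutation_table(profiles: Mapping[str, MutationProfile], path: str | Path) -> None:
    rows = [
        {"sample_id": p.sample_id, "gene": c.gene, "variant": c.variant, "vaf": round(c.vaf, 6)}
        for p in profiles.values()
        for c in p.calls
    ]
    df = pd.DataFrame(rows, columns=list(_REQUIRED_MUT_COLS))
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def write_run_manifest(out_dir: str | Path, stage: str, params: Mapping) -> Path:
    """Record a stage's parameters (including seeds) for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"stage": stage, "params": {k: _jsonable(v) for k, v in params.items()}}
    path = out_dir / f"manifest_{stage}.json"
    atomic_write_text(path, json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    return v
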