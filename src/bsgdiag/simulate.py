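"""Synthetic brainstem-glioma cohorts for end-to-end pipeline testing.

The generator reproduces the statistical structure the analysis assumes,
so every downstream stage is exercisable without any data download:

* three tumor subtypes with the canonical targeted-panel methylation
  patterns — H3K27M tumors hypermethylated at H3-specific sites and low
  at IDH-specific sites, IDH tumors hypermethylated at all panel sites,
  double-wildtype tumors low almost everywhere;
* CSF samples as a dilution of the tumor profile into a low-methylation
  background, beta_csf = f * beta_tumor + (1 - f) * beta_background,
  with tumor fraction f, probe dropout, a DNA-mass draw and the 5 ng
  below/above-limit-of-detection (BLOD/ALOD) gate — BLOD samples carry
  methylation data only, never mutation calls;
* driver-mutation calls (H3F3A / HIST1H3B K27M, IDH1 R132H) with
  detection dropout and VAF ~ f/2 (heterozygous driver) times noise;
* Weibull overall survival whose scale shrinks with a latent risk score
  and with H3K27M status;
* longitudinal series whose tumor fraction follows per-phase multipliers,
  with distinct detection floors for mutation VAF and methylation signal
  (the methylation floor is lower, so minimal residual disease shows up
  as score-without-VAF).

Beta-value noise is a beta distribution parameterized by (mean,
concentration); ``dispersion=None`` switches noise off entirely (betas
equal their configured means), which the closed-form tests rely on.
All operations are byte-deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MutationCall, MutationProfile
from .markers import MarkerPanel
from .monitor import LongitudinalSeries, SeriesPoint
from .scores import compute_mss

__all__ = [
    "SUBTYPES",
    "TIMEPOINTS",
    "CohortConfig",
    "SyntheticCohort",
    "CsfSample",
    "SurvivalConfig",
    "PhasePoint",
    "TrajectoryConfig",
    "generate_tissue_cohort",
    "derive_csf_samples",
    "generate_survival",
    "generate_longitudinal",
    "csf_beta_matrix",
]

SUBTYPES = ("H3K27M", "IDH", "DW")
TIMEPOINTS = ("A", "B", "C", "D")  # pre-op, intra-op, post-op, follow-up
BLOD_THRESHOLD_NG = 5.0

# Panel-site mean methylation per (subtype x site class).  H3K27M: hyper
# at H3 sites, hypo at IDH sites; IDH: hyper at all panel sites; DW: low
# across most sites.  Noise sites are non-informative.
DEFAULT_SITE_MEANS: dict[str, dict[str, float]] = {
    "H3K27M": {"h3": 0.85, "idh": 0.15, "noise": 0.30},
    "IDH": {"h3": 0.60, "idh": 0.90, "noise": 0.35},
    "DW": {"h3": 0.15, "idh": 0.12, "noise": 0.25},
}

_SALT_TISSUE = 1
_SALT_CSF = 100
_SALT_SURVIVAL = 3
_SALT_LONGITUDINAL = 4


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    ``tumor_fraction_law`` and ``dna_mass_law`` are small dicts with a
    ``kind`` key: ``{"kind": "beta", "a", "b"}`` or ``{"kind": "fixed",
    "value"}`` for the tumor fraction; ``{"kind": "lognormal", "mu",
    "sigma", "f_coupling"}`` or ``fixed`` for the DNA mass (ng), where
    ``f_coupling`` shifts the log-mass with the tumor fraction so that
    ctDNA-poor samples tend to fall below the 5 ng mutation-library
    threshold.
    """

    n_per_subtype: tuple[int, int, int] = (45, 45, 45)  # (H3K27M, IDH, DW)
    n_h3_sites: int = 40
    n_idh_sites: int = 36
    n_noise_sites: int = 100
    subtype_site_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SITE_MEANS.items()}
    )
    dispersion: float | None = 40.0  # beta concentration; None = noise off
    background_mean: float = 0.10  # CSF mixing background at every site
    tumor_fraction_law: Mapping = field(
        default_factory=lambda: {"kind": "beta", "a": 4.0, "b": 2.0}
    )
    dna_mass_law: Mapping = field(
        default_factory=lambda: {"kind": "lognormal", "mu": 1.0, "sigma": 0.8, "f_coupling": 1.0}
    )
    missing_rate: float = 0.05
    mutation_detect_sens: float = 0.95
    h3f3a_fraction: float = 0.9  # isoform split among H3K27M drivers
    driver_vaf_beta: tuple[float, float] = (8.0, 12.0)  # tissue driver VAF law
    vaf_noise_sd: float = 0.15  # lognormal detection noise on CSF VAF
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_subtype):
            raise ValueError(f"n_per_subtype must be >= 0; got {self.n_per_subtype}")
        for name in ("n_h3_sites", "n_idh_sites", "n_noise_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for subtype, means in self.subtype_site_means.items():
            for cls, m in means.items():
                if not np.isfinite(m) or not (0.0 <= m <= 1.0):
                    raise ValueError(f"subtype_site_means[{subtype!r}][{cls!r}]={m} not in [0, 1]")
        for name in ("background_mean", "missing_rate", "mutation_detect_sens", "h3f3a_fraction"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} not in [0, 1]")
        if self.dispersion is not None and (
            not np.isfinite(self.dispersion) or self.dispersion <= 0
        ):
            raise ValueError(f"dispersion must be positive or None; got {self.dispersion}")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    tissue_betas: pd.DataFrame  # patients x sites
    subtype_labels: pd.Series  # per patient, in SUBTYPES
    mutation_profiles: dict[str, MutationProfile]
    truth_panel: MarkerPanel  # planted site classes (ground truth)
    noise_sites: list[str]
    config: CohortConfig

    @property
    def patient_ids(self) -> list[str]:
        return list(self.tissue_betas.index)


@dataclass
class CsfSample:
    sample_id: str
    patient_id: str
    timepoint: str
    betas: pd.Series  # per-site value, NaN = missing probe
    tumor_fraction: float
    dna_mass_ng: float
    lod_flag: str  # "BLOD" (< 5 ng) or "ALOD"
    mutation_calls: MutationProfile | None  # None when BLOD

    def __post_init__(self) -> None:
        expected = "BLOD" if self.dna_mass_ng < BLOD_THRESHOLD_NG else "ALOD"
        if self.lod_flag != expected:
            raise ValueError(
                f"lod_flag {self.lod_flag!r} inconsistent with mass {self.dna_mass_ng} ng"
            )
        if self.lod_flag == "BLOD" and self.mutation_calls is not None:
            raise ValueError("BLOD samples carry no mutation calls")


def _draw_betas(rng: np.random.Generator, means: np.ndarray, dispersion: float | None):
    if dispersion is None:
        return means.copy()
    m = np.clip(means, 1e-6, 1 - 1e-6)
    return rng.beta(m * dispersion, (1 - m) * dispersion)


def generate_tissue_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the tissue cohort with planted marker-site structure.

    Every H3K27M patient carries an H3F3A or HIST1H3B K27M call
    (isoform split per config), every IDH patient an IDH1 R132H call,
    and DW patients no driver; TP53/ATRX concurrency is sprinkled in for
    realism.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _SALT_TISSUE])

    h3_sites = [f"cg_h3_{i:04d}" for i in range(config.n_h3_sites)]
    idh_sites = [f"cg_idh_{i:04d}" for i in range(config.n_idh_sites)]
    noise_sites = [f"cg_ns_{i:04d}" for i in range(config.n_noise_sites)]
    all_sites = h3_sites + idh_sites + noise_sites

    rows, labels, profiles = [], {}, {}
    pids = []
    for subtype, n in zip(SUBTYPES, config.n_per_subtype):
        means_by_class = config.subtype_site_means[subtype]
        site_means = np.array(
            [means_by_class["h3"]] * len(h3_sites)
            + [means_by_class["idh"]] * len(idh_sites)
            + [means_by_class["noise"]] * len(noise_sites)
        )
        for i in range(n):
            pid = f"{subtype}_{i:03d}"
            pids.append(pid)
            labels[pid] = subtype
            rows.append(_draw_betas(rng, site_means, config.dispersion))
            profiles[pid] = _draw_mutation_profile(rng, pid, subtype, config)

    betas = pd.DataFrame(rows, index=pids, columns=all_sites, dtype=float)
    betas.index.name = "sample_id"
    truth = MarkerPanel.from_sites(h3_sites, idh_sites)
    return SyntheticCohort(
        tissue_betas=betas,
        subtype_labels=pd.Series(labels, name="subtype"),
        mutation_profiles=profiles,
        truth_panel=truth,
        noise_sites=noise_sites,
        config=config,
    )


def _draw_mutation_profile(
    rng: np.random.Generator, pid: str, subtype: str, config: CohortConfig
) -> MutationProfile:
    a, b = config.driver_vaf_beta
    calls: list[MutationCall] = []
    if subtype == "H3K27M":
        gene = "H3F3A" if rng.random() < config.h3f3a_fraction else "HIST1H3B"
        calls.append(MutationCall(gene, "K27M", float(rng.beta(a, b))))
        if rng.random() < 0.75:
            calls.append(MutationCall("TP53", "mut", float(rng.beta(a, b))))
        if rng.random() < 0.5:
            calls.append(MutationCall("ATRX", "mut", float(rng.beta(a, b))))
    elif subtype == "IDH":
        calls.append(MutationCall("IDH1", "R132H", float(rng.beta(a, b))))
        if rng.random() < 0.6:
            calls.append(MutationCall("TP53", "mut", float(rng.beta(a, b))))
    else:  # DW: no driver, occasional passenger
        if rng.random() < 0.2:
            calls.append(MutationCall("TERT", "promoter", float(rng.beta(a, b))))
    return MutationProfile(pid, calls)


def _draw_tumor_fraction(rng: np.random.Generator, law: Mapping) -> float:
    kind = law.get("kind", "beta")
    if kind == "fixed":
        return float(law["value"])
    if kind == "beta":
        return float(rng.beta(law["a"], law["b"]))
    raise ValueError(f"unknown tumor_fraction_law kind {kind!r}")


def _draw_dna_mass(rng: np.random.Generator, law: Mapping, f: float) -> float:
    kind = law.get("kind", "lognormal")
    if kind == "fixed":
        return float(law["value"])
    if kind == "lognormal":
        coupling = law.get("f_coupling", 0.0)
        return float(np.exp(law["mu"] + coupling * f + law["sigma"] * rng.standard_normal()))
    raise ValueError(f"unknown dna_mass_law kind {kind!r}")


def derive_csf_samples(
    cohort: SyntheticCohort, config: CohortConfig, timepoint: str = "A"
) -> list[CsfSample]:
    """Derive one CSF sample per patient at the given timepoint.

    Per patient: beta_csf = f * beta_tumor + (1 - f) * beta_background
    with f from the tumor-fraction law and a fresh background draw;
    probes masked missing at ``missing_rate``; DNA mass drawn and the
    BLOD/ALOD flag set at the 5 ng threshold.  For ALOD samples each
    true tumor call is emitted with probability ``mutation_detect_sens``
    and VAF = f/2 times lognormal detection noise.
    """
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}")
    if not len(cohort.tissue_betas):
        raise ValueError("cohort is empty")
    config.validate()
    rng = np.random.default_rng([config.seed, _SALT_CSF + TIMEPOINTS.index(timepoint)])

    sites = cohort.tissue_betas.columns
    bg_means = np.full(len(sites), config.background_mean)
    samples = []
    for pid in cohort.patient_ids:
        tumor = cohort.tissue_betas.loc[pid].to_numpy(dtype=float)
        f = _draw_tumor_fraction(rng, config.tumor_fraction_law)
        background = _draw_betas(rng, bg_means, config.dispersion)
        csf = f * tumor + (1 - f) * background
        if config.missing_rate > 0:
            mask = rng.random(len(sites)) < config.missing_rate
            csf = np.where(mask, np.nan, csf)
        mass = _draw_dna_mass(rng, config.dna_mass_law, f)
        lod = "BLOD" if mass < BLOD_THRESHOLD_NG else "ALOD"

        calls = None
        if lod == "ALOD":
            sample_calls = []
            for call in cohort.mutation_profiles[pid].calls:
                if rng.random() < config.mutation_detect_sens:
                    noise = float(np.exp(config.vaf_noise_sd * rng.standard_normal()))
                    sample_calls.append(
                        MutationCall(call.gene, call.variant, float(np.clip(f / 2 * noise, 0, 1)))
                    )
            calls = MutationProfile(f"{pid}_CSF_{timepoint}", sample_calls)
        samples.append(
            CsfSample(
                sample_id=f"{pid}_CSF_{timepoint}",
                patient_id=pid,
                timepoint=timepoint,
                betas=pd.Series(csf, index=sites),
                tumor_fraction=f,
                dna_mass_ng=mass,
                lod_flag=lod,
                mutation_calls=calls,
            )
        )
    return samples


def csf_beta_matrix(samples: Sequence[CsfSample]) -> pd.DataFrame:
    """Stack CSF samples into a samples x sites beta matrix."""
    mat = pd.DataFrame({s.sample_id: s.betas for s in samples}).T
    mat.index.name = "sample_id"
    return mat


@dataclass(frozen=True)
class SurvivalConfig:
    """Weibull overall-survival law with proportional-hazards structure.

    The baseline stratum (risk 0, non-H3) has the configured median;
    each unit of latent risk multiplies the hazard by exp(log_hr_risk)
    and H3K27M status by exp(log_hr_h3), shrinking the scale by
    HR^(-1/shape).  Administrative censoring at ``horizon_months``.
    """

    shape: float = 1.3
    median_baseline_months: float = 40.0
    log_hr_risk: float = 1.0
    log_hr_h3: float = 1.2
    horizon_months: float = 60.0
    seed: int = 0


def generate_survival(
    cohort: SyntheticCohort, latent_risk, config: SurvivalConfig
) -> pd.DataFrame:
    """Survival table (os_months, event, covariates) for the cohort."""
    if config.horizon_months <= 0:
        raise ValueError(f"horizon must be positive; got {config.horizon_months}")
    latent_risk = pd.Series(latent_risk).reindex(cohort.patient_ids)
    if latent_risk.isna().any():
        raise ValueError("latent_risk must cover every patient")
    rng = np.random.default_rng([config.seed, _SALT_SURVIVAL])

    k = config.shape
    lam0 = config.median_baseline_months / np.log(2) ** (1 / k)
    is_h3 = (cohort.subtype_labels.loc[cohort.patient_ids] == "H3K27M").astype(int)
    log_hr = config.log_hr_risk * latent_risk + config.log_hr_h3 * is_h3
    lam = lam0 * np.exp(-log_hr / k)

    t = lam * rng.weibull(k, size=len(lam))
    event = (t <= config.horizon_months).astype(int)
    os_months = np.minimum(t, config.horizon_months)
    table = pd.DataFrame(
        {
            "os_months": os_months,
            "event": event,
            "latent_risk": latent_risk,
            "is_h3": is_h3,
            "subtype": cohort.subtype_labels.loc[cohort.patient_ids],
        },
        index=pd.Index(cohort.patient_ids, name="patient_id"),
    )
    return table


@dataclass(frozen=True)
class PhasePoint:
    day: float
    phase: str  # e.g. pre-op, post-op, post-RT, progression
    multiplier: float  # tumor-fraction multiplier relative to f0
    timepoint: str = "D"


@dataclass(frozen=True)
class TrajectoryConfig:
    """Per-phase tumor-fraction trajectory for one monitored patient.

    The mutation VAF detection floor sits above the methylation signal
    floor, so a phase with tumor fraction between the two shows the MRD
    pattern: undetectable VAF with persisting methylation signal.
    """

    phases: tuple[PhasePoint, ...]
    f0: float = 0.5
    vaf_floor: float = 0.02  # VAF below this reports as undetectable
    seed: int = 0


def generate_longitudinal(
    cohort: SyntheticCohort,
    patient_id: str,
    traj: TrajectoryConfig,
    config: CohortConfig,
    panel: MarkerPanel,
    min_coverage: float = 0.5,
) -> LongitudinalSeries:
    """Simulate a monitored patient's MSS/VAF series across phases.

    At each phase the tumor fraction is f0 * multiplier; CSF betas come
    from the same mixture law as :func:`derive_csf_samples` and are
    scored over ``panel``.  The driver VAF is f/2 (with detection noise)
    or the undetectable sentinel when it falls below ``traj.vaf_floor``
    — methylation is still scored there, which is what makes minimal
    residual disease visible.
    """
    if patient_id not in cohort.tissue_betas.index:
        raise KeyError(f"unknown patient {patient_id!r}")
    days = [p.day for p in traj.phases]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError(f"phase days must be strictly increasing; got {days}")
    config.validate()
    rng = np.random.default_rng([config.seed, _SALT_LONGITUDINAL, traj.seed])

    tumor = cohort.tissue_betas.loc[patient_id].to_numpy(dtype=float)
    sites = cohort.tissue_betas.columns
    bg_means = np.full(len(sites), config.background_mean)

    points = []
    for phase in traj.phases:
        f = float(np.clip(traj.f0 * phase.multiplier, 0.0, 1.0))
        background = _draw_betas(rng, bg_means, config.dispersion)
        csf = f * tumor + (1 - f) * background
        if config.missing_rate > 0:
            mask = rng.random(len(sites)) < config.missing_rate
            csf = np.where(mask, np.nan, csf)
        mss = compute_mss(pd.Series(csf, index=sites), panel, min_coverage)

        noise = float(np.exp(config.vaf_noise_sd * rng.standard_normal()))
        raw_vaf = f / 2 * noise
        vaf = float(np.clip(raw_vaf, 0, 1)) if raw_vaf >= traj.vaf_floor else None
        points.append(
            SeriesPoint(day=phase.day, timepoint=phase.timepoint, mss=mss, vaf=vaf, phase=phase.phase)
        )
    return LongitudinalSeries(patient_id=patient_id, points=points)
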