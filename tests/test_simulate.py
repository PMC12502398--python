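"""Synthetic cohort generator: planted structure, dilution law, LOD
gating, survival law and longitudinal trajectories."""

import numpy as np
import pandas as pd
import pytest

from bsgdiag import (
    CohortConfig,
    PhasePoint,
    SurvivalConfig,
    TrajectoryConfig,
    compute_mss,
    csf_beta_matrix,
    derive_csf_samples,
    generate_longitudinal,
    generate_survival,
    generate_tissue_cohort,
    km_median,
)
from bsgdiag.simulate import BLOD_THRESHOLD_NG


class TestGenerateTissueCohort:
    def test_empty_cohort(self):
        cohort = generate_tissue_cohort(CohortConfig(n_per_subtype=(0, 0, 0)))
        assert cohort.tissue_betas.empty
        assert len(cohort.subtype_labels) == 0

    def test_configured_mean_recovered(self):
        """Law of large numbers: the empirical mean of H3-site betas in
        H3K27M samples approaches the configured 0.8."""
        cfg = CohortConfig(
            n_per_subtype=(50, 5, 5),
            subtype_site_means={
                "H3K27M": {"h3": 0.8, "idh": 0.15, "noise": 0.3},
                "IDH": {"h3": 0.6, "idh": 0.9, "noise": 0.35},
                "DW": {"h3": 0.15, "idh": 0.12, "noise": 0.25},
            },
            seed=21,
        )
        cohort = generate_tissue_cohort(cfg)
        h3_samples = cohort.subtype_labels[cohort.subtype_labels == "H3K27M"].index
        observed = cohort.tissue_betas.loc[h3_samples, cohort.truth_panel.h3_sites]
        assert observed.to_numpy().mean() == pytest.approx(0.8, abs=0.03)

    def test_seed_determinism(self):
        cfg = CohortConfig(n_per_subtype=(10, 10, 10), seed=5)
        a = generate_tissue_cohort(cfg)
        b = generate_tissue_cohort(cfg)
        pd.testing.assert_frame_equal(a.tissue_betas, b.tissue_betas)
        assert {p: [c.gene for c in prof.calls] for p, prof in a.mutation_profiles.items()} == {
            p: [c.gene for c in prof.calls] for p, prof in b.mutation_profiles.items()
        }

    def test_all_betas_in_unit_interval(self, cohort):
        vals = cohort.tissue_betas.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_driver_mutations_match_subtypes(self, cohort):
        for pid, subtype in cohort.subtype_labels.items():
            prof = cohort.mutation_profiles[pid]
            if subtype == "H3K27M":
                assert prof.has_h3_driver and not prof.has_idh_driver
            elif subtype == "IDH":
                assert prof.has_idh_driver and not prof.has_h3_driver
            else:
                assert not prof.has_h3_driver and not prof.has_idh_driver

    def test_planted_site_sets_disjoint(self, cohort):
        h3 = set(cohort.truth_panel.h3_sites)
        idh = set(cohort.truth_panel.idh_sites)
        ns = set(cohort.noise_sites)
        assert not (h3 & idh) and not (h3 & ns) and not (idh & ns)

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="missing_rate"):
            CohortConfig(missing_rate=1.5).validate()
        with pytest.raises(ValueError, match="dispersion"):
            CohortConfig(dispersion=-1.0).validate()


class TestDeriveCsfSamples:
    def test_pure_tumor_limit(self, small_cohort):
        """f forced to 1 with no missingness reproduces the tissue betas."""
        cfg = small_cohort.config.with_(
            tumor_fraction_law={"kind": "fixed", "value": 1.0}, missing_rate=0.0
        )
        csf = derive_csf_samples(small_cohort, cfg, "A")
        for s in csf:
            np.testing.assert_allclose(
                s.betas.to_numpy(), small_cohort.tissue_betas.loc[s.patient_id].to_numpy()
            )

    def test_zero_tumor_limit_erases_signal(self, small_cohort):
        """f = 0: CSF is pure background; the H3K27M signature score sits
        at the background value for every subtype."""
        cfg = small_cohort.config.with_(
            tumor_fraction_law={"kind": "fixed", "value": 0.0},
            missing_rate=0.0,
            dispersion=None,
        )
        csf = derive_csf_samples(small_cohort, cfg, "A")
        panel = small_cohort.truth_panel
        scores = [compute_mss(s.betas, panel).value for s in csf]
        bg = compute_mss(
            pd.Series(cfg.background_mean, index=small_cohort.tissue_betas.columns), panel
        ).value
        np.testing.assert_allclose(scores, bg, atol=1e-12)

    def test_mss_strictly_increasing_in_tumor_fraction(self, small_cohort):
        """With noise off, the signature score of an H3K27M patient is
        strictly increasing in the tumor fraction (mixture is linear and
        the H3-site gain dominates the IDH-site term)."""
        cfg0 = small_cohort.config.with_(missing_rate=0.0, dispersion=None)
        pid = small_cohort.subtype_labels[small_cohort.subtype_labels == "H3K27M"].index[0]
        panel = small_cohort.truth_panel
        values = []
        for f in np.arange(0.1, 1.0, 0.1):
            cfg = cfg0.with_(tumor_fraction_law={"kind": "fixed", "value": float(f)})
            (sample,) = [
                s for s in derive_csf_samples(small_cohort, cfg, "A") if s.patient_id == pid
            ]
            values.append(compute_mss(sample.betas, panel).value)
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_lod_gate_and_mutation_presence(self, cohort):
        csf = derive_csf_samples(cohort, cohort.config, "A")
        for s in csf:
            assert s.lod_flag == ("BLOD" if s.dna_mass_ng < BLOD_THRESHOLD_NG else "ALOD")
            if s.lod_flag == "BLOD":
                assert s.mutation_calls is None
            else:
                assert s.mutation_calls is not None

    def test_missingness_rate_matches_config(self, cohort):
        cfg = cohort.config.with_(missing_rate=0.1)
        csf = derive_csf_samples(cohort, cfg, "B")
        mat = csf_beta_matrix(csf)
        observed_rate = mat.isna().to_numpy().mean()
        n = mat.size
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(observed_rate - 0.1) < 4 * se

    def test_driver_call_rate_within_binomial_band(self):
        """With detection sensitivity 0.95 over ~200 ALOD H3K27M samples
        the observed driver-call rate lands in the 99% binomial band."""
        cfg = CohortConfig(
            n_per_subtype=(300, 0, 0),
            mutation_detect_sens=0.95,
            dna_mass_law={"kind": "fixed", "value": 10.0},
            seed=13,
        )
        cohort = generate_tissue_cohort(cfg)
        csf = derive_csf_samples(cohort, cfg, "A")
        alod = [s for s in csf if s.lod_flag == "ALOD"][:200]
        assert len(alod) == 200
        rate = np.mean([s.mutation_calls.has_h3_driver for s in alod])
        assert 0.91 <= rate <= 0.98

    def test_vaf_scales_with_tumor_fraction(self, cohort):
        cfg = cohort.config.with_(
            dna_mass_law={"kind": "fixed", "value": 10.0}, vaf_noise_sd=0.0
        )
        csf = derive_csf_samples(cohort, cfg, "A")
        for s in csf:
            for call in s.mutation_calls.calls:
                assert call.vaf == pytest.approx(s.tumor_fraction / 2)

    def test_unknown_timepoint(self, small_cohort):
        with pytest.raises(ValueError, match="timepoint"):
            derive_csf_samples(small_cohort, small_cohort.config, "Z")

    def test_seed_determinism(self, small_cohort):
        a = derive_csf_samples(small_cohort, small_cohort.config, "C")
        b = derive_csf_samples(small_cohort, small_cohort.config, "C")
        pd.testing.assert_frame_equal(csf_beta_matrix(a), csf_beta_matrix(b))
        assert [s.dna_mass_ng for s in a] == [s.dna_mass_ng for s in b]


class TestGenerateSurvival:
    def test_null_hazard_no_group_separation(self):
        """With risk and subtype coefficients at zero, every stratum has
        the same survival law."""
        cfg = CohortConfig(n_per_subtype=(150, 0, 150), seed=2)
        cohort = generate_tissue_cohort(cfg)
        scfg = SurvivalConfig(log_hr_risk=0.0, log_hr_h3=0.0, seed=4)
        risk = pd.Series(0.0, index=cohort.patient_ids)
        table = generate_survival(cohort, risk, scfg)
        from lifelines.statistics import logrank_test

        h3 = table["is_h3"] == 1
        res = logrank_test(
            table.loc[h3, "os_months"],
            table.loc[~h3, "os_months"],
            table.loc[h3, "event"],
            table.loc[~h3, "event"],
        )
        assert res.p_value > 0.01

    def test_km_median_matches_configured_weibull_median(self):
        """A 500-patient stratum configured to a median of 11 months
        shows a KM median within 1.5 months of it."""
        cfg = CohortConfig(n_per_subtype=(0, 0, 500), seed=6)
        cohort = generate_tissue_cohort(cfg)
        scfg = SurvivalConfig(
            median_baseline_months=11.0, log_hr_risk=0.0, log_hr_h3=0.0, seed=8
        )
        table = generate_survival(cohort, pd.Series(0.0, index=cohort.patient_ids), scfg)
        km = km_median(table["os_months"], table["event"])
        assert km.median == pytest.approx(11.0, abs=1.5)

    def test_negative_horizon_errors(self, small_cohort):
        with pytest.raises(ValueError, match="horizon"):
            generate_survival(
                small_cohort,
                pd.Series(0.0, index=small_cohort.patient_ids),
                SurvivalConfig(horizon_months=-1),
            )

    def test_seed_determinism(self, small_cohort):
        risk = pd.Series(0.5, index=small_cohort.patient_ids)
        a = generate_survival(small_cohort, risk, SurvivalConfig(seed=9))
        b = generate_survival(small_cohort, risk, SurvivalConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestGenerateLongitudinal:
    @pytest.fixture
    def h3_patient(self, small_cohort):
        return small_cohort.subtype_labels[small_cohort.subtype_labels == "H3K27M"].index[0]

    def test_flat_multipliers_constant_mss(self, small_cohort, h3_patient):
        cfg = small_cohort.config.with_(missing_rate=0.0, dispersion=None, vaf_noise_sd=0.0)
        traj = TrajectoryConfig(
            phases=tuple(
                PhasePoint(day=d, phase="baseline", multiplier=1.0) for d in (0, 30, 60)
            ),
            f0=0.5,
        )
        series = generate_longitudinal(
            small_cohort, h3_patient, traj, cfg, small_cohort.truth_panel
        )
        values = [p.mss.value for p in series.points]
        np.testing.assert_allclose(values, values[0], atol=1e-12)

    def test_resection_drop_matches_mixture_formula(self, small_cohort, h3_patient):
        """Post-op point with multiplier 0.1 equals the closed-form
        mixture score at f = 0.1 * f0 (noise off)."""
        cfg = small_cohort.config.with_(missing_rate=0.0, dispersion=None, vaf_noise_sd=0.0)
        panel = small_cohort.truth_panel
        f0 = 0.6
        traj = TrajectoryConfig(
            phases=(
                PhasePoint(0, "pre-op", 1.0, "A"),
                PhasePoint(20, "post-op", 0.1, "C"),
            ),
            f0=f0,
        )
        series = generate_longitudinal(small_cohort, h3_patient, traj, cfg, panel)
        tumor = small_cohort.tissue_betas.loc[h3_patient]
        f = 0.1 * f0
        expected = compute_mss(f * tumor + (1 - f) * cfg.background_mean, panel).value
        assert series.points[1].mss.value == pytest.approx(expected, abs=1e-12)

    def test_mrd_phase_has_zero_vaf_but_methylation_signal(self, small_cohort, h3_patient):
        """Tumor fraction below the VAF floor but above the methylation
        floor: VAF reads undetectable while MSS stays above background."""
        cfg = small_cohort.config.with_(missing_rate=0.0, dispersion=None, vaf_noise_sd=0.0)
        panel = small_cohort.truth_panel
        traj = TrajectoryConfig(
            phases=(
                PhasePoint(0, "pre-op", 1.0, "A"),
                PhasePoint(40, "post-op", 0.05, "C"),
            ),
            f0=0.6,
            vaf_floor=0.02,  # f=0.03 -> VAF 0.015 < floor
        )
        series = generate_longitudinal(small_cohort, h3_patient, traj, cfg, panel)
        mrd_point = series.points[1]
        background = compute_mss(
            pd.Series(cfg.background_mean, index=small_cohort.tissue_betas.columns), panel
        ).value
        assert mrd_point.vaf is None
        assert mrd_point.mss.value > background

    def test_non_monotone_days_error(self, small_cohort, h3_patient):
        traj = TrajectoryConfig(
            phases=(PhasePoint(10, "a", 1.0), PhasePoint(5, "b", 1.0))
        )
        with pytest.raises(ValueError, match="increasing"):
            generate_longitudinal(
                small_cohort,
                h3_patient,
                traj,
                small_cohort.config,
                small_cohort.truth_panel,
            )
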