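"""Synthetic-cohort generator: determinism, calibration of the error model,
planted-signal fidelity, arm-event arithmetic, and design bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import uroseek as u


class TestConfigValidation:
    def test_bad_probability_names_field(self):
        cfg = u.SimulationConfig(shed_probability=1.5)
        with pytest.raises(ValueError, match="shed_probability"):
            cfg.validate()

    def test_bad_loci_count(self):
        with pytest.raises(ValueError, match="n_loci"):
            u.CohortSimulator(u.SimulationConfig(n_loci=1000))

    def test_case_count_exceeding_size(self):
        cfg = u.SimulationConfig(cohort_design={"early_detection": (10, 11)})
        with pytest.raises(ValueError, match="case count"):
            cfg.validate()

    def test_negative_error_rate(self):
        with pytest.raises(ValueError, match="background_error_rate"):
            u.SimulationConfig(background_error_rate=-1e-5).validate()


class TestControlPanels:
    def test_zero_error_rate_gives_zero_mafs(self):
        sm = u.CohortSimulator(u.SimulationConfig(seed=5, background_error_rate=0.0,
                                                  n_control_wbc=10, n_control_urines=10))
        wbc, urine = sm.control_panels()
        assert (wbc.mutant_uids == 0).all()
        assert (urine.mutant_uids == 0).all()

    def test_panel_shape_and_counts(self, sim, control_panels):
        wbc, urine = control_panels
        assert urine.patient_id.nunique() == 188
        assert wbc.patient_id.nunique() == 188
        wells = urine.groupby(["patient_id", "assay"]).well.nunique()
        assert (wells == 2).all()
        # every queried position present in every well
        per_well = urine.groupby(["patient_id", "assay", "well"]).size()
        keys = sim.panel.to_frame().groupby("assay").size()
        for (pid, assay, w), n in per_well.items():
            assert n == keys[assay]

    def test_background_rate_is_calibrated(self, sim, control_panels):
        """Generated counts are unbiased for the per-position error rates.

        Position-specific rates are a fixed draw around 1e-4 (the configured
        mean), so the generated MAFs are compared against the realised rates
        of this panel; with 31 positions the panel-average rate itself sits
        within the configured dispersion of 1e-4.
        """
        wbc, _ = control_panels
        maf = (wbc.mutant_uids / wbc.total_uids).to_numpy()
        se = maf.std(ddof=1) / np.sqrt(len(maf))
        target = sim.position_error_rates.mean()
        assert abs(maf.mean() - target) < 3 * se
        # the fixed panel draw is itself consistent with the 1e-4 mean
        rates = sim.position_error_rates.to_numpy()
        panel_se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - 1e-4) < 3 * panel_se

    def test_determinism_is_byte_level(self):
        a = u.CohortSimulator(u.SimulationConfig(seed=9)).control_panels()[0]
        b = u.CohortSimulator(u.SimulationConfig(seed=9)).control_panels()[0]
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_technical_panel_size(self, sim):
        tech = sim.technical_wbc_panel()
        assert tech.patient_id.nunique() == 94


class TestSimulatePatient:
    def test_planted_fraction_lands_in_binomial_interval(self, sim):
        lab = "17:7577538:C>T"
        tr = u.TruthRecord(patient_id="px", cohort="early_detection", is_cancer=True,
                           planted_mutations=[(lab, 0.08)], tumor_mutations=[lab])
        obs, _ = sim.simulate_patient(tr)
        rows = obs[(obs.chrom == "17") & (obs.pos == 7577538)]
        assert len(rows) == 2
        for _, r in rows.iterrows():
            lo, hi = binom.ppf([0.005, 0.995], r.total_uids, 0.08)
            assert lo <= r.mutant_uids <= hi + r.total_uids * 2e-4  # background on top

    def test_bad_planted_fraction_rejected(self, sim):
        tr = u.TruthRecord.__new__(u.TruthRecord)  # bypass dataclass validation
        tr.__dict__.update(patient_id="pz", cohort="early_detection", is_cancer=True,
                           planted_mutations=[("17:7577538:C>T", 1.5)],
                           tumor_mutations=["17:7577538:C>T"], arm_events=[],
                           neoplastic_fraction=0.0, cytology="unavailable",
                           collection_day=0, diagnosis_day=None, grade=None, stage=None)
        with pytest.raises(ValueError, match="fraction"):
            sim.simulate_patient(tr)

    def test_no_signal_patient_is_background_only(self, sim, caller):
        tr = u.TruthRecord(patient_id="pneg", cohort="early_detection", is_cancer=False)
        obs, profile = sim.simulate_patient(tr)
        calls = u.call_mutations(obs, caller.reference)
        assert not calls.positive.any()
        assert profile.sum() > 0

    def test_arm_gain_scales_expected_share(self, sim):
        """A single-copy 8q gain at nf=0.10 lifts the 8q share by ~5%."""
        w = sim.locus_weights
        arm = sim.arm_map.arm
        euploid_share = w[arm == "8q"].sum() / w.sum()
        rng = np.random.default_rng(77)
        shares = []
        for _ in range(30):
            prof = sim._locus_profile(rng, [("8q", "gain")], 0.10)
            shares.append(prof[arm == "8q"].sum() / prof.sum())
        # expectation arithmetic: factor (1 + 0.10/2), diluted by renormalisation
        f = 1.05
        expect = f * euploid_share / (1 + (f - 1) * euploid_share)
        assert np.mean(shares) == pytest.approx(expect, rel=2e-3)
        assert np.mean(shares) / euploid_share == pytest.approx(1.05, abs=5e-3)

    def test_arm_event_direction_is_monotone(self, sim):
        arm = sim.arm_map.arm
        rng = np.random.default_rng(78)
        def mean_share(kind, nf, n=20):
            vals = []
            for _ in range(n):
                p = sim._locus_profile(rng, [("5q", kind)], nf)
                vals.append(p[arm == "5q"].sum() / p.sum())
            return np.mean(vals)
        gains = [mean_share("gain", nf) for nf in (0.02, 0.10, 0.30)]
        losses = [mean_share("loss", nf) for nf in (0.02, 0.10, 0.30)]
        assert gains == sorted(gains)
        assert losses == sorted(losses, reverse=True)

    def test_unknown_arm_rejected(self, sim):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="unknown arm"):
            sim._locus_profile(rng, [("13p", "gain")], 0.1)


class TestMarginalCalibration:
    def test_planted_maf_unbiased_over_many_wells(self):
        """Observed MAF of a planted fraction is unbiased within 3 SE."""
        sm = u.CohortSimulator(u.SimulationConfig(seed=21))
        f = 0.05
        lab = "9:21971120:C>T"
        mafs = []
        rng = np.random.default_rng(3)
        ids = [f"w{i}" for i in range(550)]
        obs = sm._sample_wells(ids, rng, {i: [(lab, f)] for i in ids})
        rows = obs[(obs.chrom == "9") & (obs.pos == 21971120)]
        mafs = (rows.mutant_uids / rows.total_uids).to_numpy()
        assert len(mafs) == 1100  # two wells per sample
        se = mafs.std(ddof=1) / np.sqrt(len(mafs))
        assert abs(mafs.mean() - f) < 3 * se + 2e-4  # 2e-4: background offset bound


class TestCohorts:
    def test_case_fraction_matches_design_exactly(self, early_cohort):
        assert len(early_cohort.truth) == 570
        assert int(early_cohort.truth.is_cancer.sum()) == 175

    def test_all_negative_design_flags_undefined_sensitivity(self):
        cfg = u.SimulationConfig(seed=4, cohort_design={"early_detection": (10, 0)},
                                 n_control_wbc=10, n_control_urines=10)
        data = u.CohortSimulator(cfg).simulate_cohort("early_detection")
        assert not data.truth.is_cancer.any()
        counts = u.confusion_from_calls(
            pd.Series(False, index=data.truth.patient_id),
            data.truth.set_index("patient_id").is_cancer,
        )
        perf = u.diagnostic_metrics(counts)
        assert "sensitivity" in perf.undefined

    def test_clinical_sheet_determinism(self):
        cfg = dict(seed=13, cohort_design={"utuc": (20, 20)},
                   n_control_wbc=10, n_control_urines=10)
        a = u.CohortSimulator(u.SimulationConfig(**cfg)).simulate_cohort("utuc")
        b = u.CohortSimulator(u.SimulationConfig(**cfg)).simulate_cohort("utuc")
        assert a.clinical.to_csv(index=False) == b.clinical.to_csv(index=False)
        assert a.mutation_obs.to_csv(index=False) == b.mutation_obs.to_csv(index=False)

    def test_truth_record_invariants_hold_cohort_wide(self, early_cohort):
        for rec in early_cohort.truth_records:
            planted = {m for m, _ in rec.planted_mutations}
            if rec.tumor_mutations:
                assert planted <= set(rec.tumor_mutations)
            if rec.is_cancer:
                assert rec.diagnosis_day is None or rec.diagnosis_day >= rec.collection_day
            else:
                assert rec.diagnosis_day is None
            assert rec.cytology in ("positive", "atypical", "negative", "unavailable")

    def test_locus_profiles_conserve_counts(self, early_cohort):
        counts = early_cohort.locus_counts
        assert (counts.to_numpy() >= 0).all()
        assert (counts.sum(axis=0) >= 10_000).all()
        assert counts.shape[0] == 3900

    def test_truth_record_validation(self):
        with pytest.raises(ValueError, match="diagnosis"):
            u.TruthRecord(patient_id="x", cohort="utuc", is_cancer=False, diagnosis_day=5)
        with pytest.raises(ValueError, match="subset"):
            u.TruthRecord(patient_id="x", cohort="utuc", is_cancer=True,
                          planted_mutations=[("k1", 0.1)], tumor_mutations=["k2"])
        with pytest.raises(ValueError, match="cohort"):
            u.TruthRecord(patient_id="x", cohort="nope", is_cancer=False)
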