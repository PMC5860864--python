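"""Mutation-calling statistics: MAF, normalisation, empirical p, Stouffer Z,
the two-criterion decision, threshold calibration, and identity checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import uroseek as u
from uroseek.calling import (
    MIN_MUTANT_FAMILIES,
    build_control_reference,
    call_mutations,
    compute_maf,
    difference_stat,
    empirical_pvalue,
    identity_concordance,
    normalized_score,
    stouffer_combine,
)


def _obs(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "assay", "well", "chrom", "pos", "ref", "alt",
                 "gene", "mutant_uids", "total_uids"],
    )


class TestComputeMaf:
    @pytest.mark.parametrize(
        "m,t,expect", [(5, 100, 0.05), (0, 10_000, 0.0), (8140, 100_000, 0.0814)]
    )
    def test_exact_ratio(self, m, t, expect):
        assert compute_maf(m, t) == pytest.approx(expect, abs=0)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError, match="total"):
            compute_maf(0, 0)

    def test_mutant_exceeding_total_is_an_error(self):
        with pytest.raises(ValueError):
            compute_maf(11, 10)


class TestControlReference:
    def _small_controls(self):
        rows = []
        for i in range(6):
            for w in (1, 2):
                rows.append((f"c{i}", "multiplex", w, "17", 100, "C", "T", "TP53", i % 3, 10_000))
                rows.append((f"c{i}", "multiplex", w, "4", 200, "A", "G", "FGFR3", 0, 10_000))
        return _obs(rows)

    def test_all_zero_key_gets_floored_scale_and_nonpositive_null(self):
        ref = build_control_reference(self._small_controls())
        assert ref.location("4:200:A>G") == 0.0
        assert ref.scale("4:200:A>G") >= 1e-6
        zeros = normalized_score(0.0, "4:200:A>G", ref)
        assert zeros <= 0

    def test_per_key_max(self):
        rows = []
        for i, maf in enumerate([0.0, 1e-4, 3e-4]):
            for w in (1, 2):
                rows.append((f"c{i}", "multiplex", w, "1", 1, "C", "T", "G1",
                             int(maf * 1e6), 1_000_000))
        ref = build_control_reference(_obs(rows))
        assert ref.max_maf("1:1:C>T") == pytest.approx(3e-4)

    def test_pooled_null_counts_every_control_well(self, sim, control_panels, caller):
        wbc, _ = control_panels
        n_keys = len(sim.panel)
        assert len(caller.reference.pooled_null) == n_keys * 188 * 2

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            build_control_reference(_obs([]))


class TestScores:
    def test_normalized_score_arithmetic(self):
        ref = build_control_reference(TestControlReference()._small_controls())
        object.__setattr__(ref, "per_key", ref.per_key.copy())
        ref.per_key.loc["17:100:C>T", ["location", "scale"]] = [1e-4, 5e-5]
        assert normalized_score(3.5e-4, "17:100:C>T", ref) == pytest.approx(5.0)

    def test_score_monotone_in_maf(self):
        ref = build_control_reference(TestControlReference()._small_controls())
        s = [normalized_score(m, "17:100:C>T", ref) for m in (0.0, 1e-4, 1e-3, 0.1)]
        assert s == sorted(s) and len(set(s)) == 4

    def test_empirical_pvalue_conventions(self):
        null = np.sort(np.linspace(-3, 3, 1000))
        assert empirical_pvalue(10.0, null) == pytest.approx(1 / 1001)
        assert empirical_pvalue(-10.0, null) == 1.0
        # at the median of an odd-sized null, brute-force the rank
        null = np.sort(np.arange(101, dtype=float))
        score = 50.0
        expect = (1 + sum(1 for v in null if v >= score)) / 102
        assert empirical_pvalue(score, null) == pytest.approx(expect)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=60), st.floats(-6, 6))
    @settings(max_examples=200, derandomize=True)
    def test_empirical_pvalue_matches_brute_force(self, null, score):
        null = np.sort(np.asarray(null))
        brute = (1 + sum(1 for v in null if v >= score)) / (len(null) + 1)
        assert empirical_pvalue(score, null) == pytest.approx(brute, abs=1e-12)

    def test_stouffer_equal_weights_identity(self):
        p = 0.01
        z = stouffer_combine(p, p, 500, 500)
        assert z == pytest.approx(np.sqrt(2) * norm.isf(p), abs=1e-12)

    def test_stouffer_degenerate_weight_limit(self):
        z1 = norm.isf(0.001)
        z = stouffer_combine(0.001, 0.5, 10_000_000, 1)
        assert z == pytest.approx(z1, abs=1e-3)

    def test_stouffer_worked_example(self):
        # w1 = 2 w2: Z = (2*z(0.01) + z(0.10)) / sqrt(5)
        z = stouffer_combine(0.01, 0.10, 400, 100)
        expect = (2 * norm.isf(0.01) + norm.isf(0.10)) / np.sqrt(5)
        assert z == pytest.approx(expect, abs=1e-12)
        assert round(z, 3) == 2.654

    def test_stouffer_rejects_bad_p(self):
        with pytest.raises(ValueError):
            stouffer_combine(0.0, 0.5, 10, 10)
        with pytest.raises(ValueError):
            stouffer_combine(0.5, 0.5, 0, 10)

    def test_linear_weight_mode(self):
        z = stouffer_combine(0.01, 0.10, 400, 100, weight_mode="linear")
        expect = (4 * norm.isf(0.01) + norm.isf(0.10)) / np.sqrt(17)
        assert z == pytest.approx(expect, abs=1e-12)

    def test_difference_stat(self):
        ref = build_control_reference(TestControlReference()._small_controls())
        mx = ref.max_maf("17:100:C>T")
        assert difference_stat(mx, "17:100:C>T", ref) == 0.0
        assert difference_stat(0.08, "17:100:C>T", ref) == pytest.approx(0.08 - mx)
        assert difference_stat(mx / 2, "17:100:C>T", ref) < 0


class TestCalibration:
    def test_exactly_one_calibration_positive_by_stouffer(self, caller, control_panels):
        _, urine = control_panels
        ref = caller.reference
        assert ref.provenance["n_calibration_positives"] == 1
        scored = call_mutations(urine, ref)
        max_z = scored.groupby("patient_id")["stouffer_z"].max()
        assert int((max_z > ref.t_z).sum()) == 1

    def test_t_diff_is_max_wbc_maf(self, caller, control_panels):
        wbc, _ = control_panels
        mafs = wbc["mutant_uids"] / wbc["total_uids"]
        assert caller.t_diff == pytest.approx(float(mafs.max()), abs=0)

    def test_t_diff_from_constructed_panel(self):
        rows = []
        for i in range(4):
            for w in (1, 2):
                rows.append((f"c{i}", "multiplex", w, "1", 1, "C", "T", "G1",
                             4 if i == 0 and w == 1 else 1, 10_000))
        wbc = _obs(rows)
        urine = wbc.assign(patient_id=wbc.patient_id.str.replace("c", "u"))
        fit = u.MutationCallerModel(wbc, urine).fit()
        assert fit.t_diff == pytest.approx(4e-4)

    def test_too_few_control_urines(self, control_panels):
        wbc, urine = control_panels
        one = urine[urine.patient_id == urine.patient_id.iloc[0]]
        with pytest.raises(ValueError, match="two control urines"):
            u.MutationCallerModel(wbc, one).fit()


class TestCallMutations:
    def test_single_well_signal_is_never_positive(self, caller):
        rows = []
        for key, m1, m2 in [(("17", 7577120, "C", "T", "TP53"), 800, 0)]:
            c, p, r, a, g = key
            rows.append(("pat1", "multiplex", 1, c, p, r, a, g, m1, 10_000))
            rows.append(("pat1", "multiplex", 2, c, p, r, a, g, m2, 10_000))
        calls = call_mutations(_obs(rows), caller.reference)
        assert len(calls) == 0  # not present in both wells -> no candidate

    def test_planted_high_maf_triggers_difference(self, sim, caller):
        lab = "17:7577538:C>T"
        tr = u.TruthRecord(
            patient_id="pt8", cohort="early_detection", is_cancer=True,
            planted_mutations=[(lab, 0.08)], tumor_mutations=[lab],
        )
        obs, _ = sim.simulate_patient(tr)
        calls = call_mutations(obs, caller.reference)
        hit = calls[(calls["label"] == lab) & calls["positive"]]
        assert len(hit) == 1
        assert hit.iloc[0]["triggering_criterion"] in ("difference", "both")
        assert hit.iloc[0]["avg_maf"] == pytest.approx(0.08, abs=0.02)

    def test_all_zero_wells_give_negative_sample(self, caller):
        rows = []
        for w in (1, 2):
            rows.append(("patz", "multiplex", w, "17", 7577120, "C", "T", "TP53", 0, 10_000))
        calls = call_mutations(_obs(rows), caller.reference)
        assert len(calls) == 0

    def test_missing_well_is_an_error(self, caller):
        rows = [("patm", "multiplex", 1, "17", 7577120, "C", "T", "TP53", 5, 10_000)]
        with pytest.raises(ValueError, match="patm"):
            call_mutations(_obs(rows), caller.reference)

    @given(m=st.integers(MIN_MUTANT_FAMILIES, 5000), extra=st.integers(0, 4000))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_mutant_families(self, caller, m, extra):
        """More mutant UID families never weakens either statistic."""
        ref = caller.reference
        total = 10_000
        lab = "17:7577538:C>T"

        def stats(mm):
            maf = mm / total
            s = normalized_score(maf, lab, ref)
            p = empirical_pvalue(s, ref.pooled_null)
            z = stouffer_combine(p, p, total, total)
            d = difference_stat(maf, lab, ref)
            return z, d

        z1, d1 = stats(m)
        z2, d2 = stats(min(m + extra, total))
        assert z2 >= z1 - 1e-12
        assert d2 >= d1 - 1e-12
        pos1 = d1 > ref.t_diff or z1 > ref.t_z
        pos2 = d2 > ref.t_diff or z2 > ref.t_z
        assert pos2 or not pos1

    def test_sample_flags_cover_all_patients(self, caller, early_cohort):
        _, flags = caller.call(early_cohort.mutation_obs)
        assert len(flags) == len(early_cohort.truth)
        assert set(flags.columns) >= {"multiplex_positive", "tert_positive"}


class TestSensitivityLimit:
    def test_low_fraction_detection_at_high_depth(self):
        """0.03% planted fraction at ~100k UID families is usually called."""
        cfg = u.SimulationConfig(seed=3, uid_depth_median=1e5, uid_depth_sigma=0.05)
        sm = u.CohortSimulator(cfg)
        wbc, urine = sm.control_panels()
        fit = u.MutationCallerModel(wbc, urine).fit()
        lab = "17:7577538:C>T"
        called = 0
        for r in range(30):
            tr = u.TruthRecord(
                patient_id=f"P{r}", cohort="early_detection", is_cancer=True,
                planted_mutations=[(lab, 0.0003)], tumor_mutations=[lab],
            )
            obs, _ = sm.simulate_patient(tr)
            calls = call_mutations(obs, fit.reference)
            called += len(calls[(calls["label"] == lab) & calls["positive"]]) > 0
        assert called > 15


class TestOracleEquivalence:
    def test_small_instance_brute_force(self):
        """p-values and Z agree with an exhaustive rank computation."""
        rng = np.random.default_rng(11)
        keys = [("1", 10, "C", "T", "G1"), ("2", 20, "A", "G", "G2"), ("3", 30, "G", "A", "G3")]
        rows = []
        for i in range(8):
            for w in (1, 2):
                for c, p, r, a, g in keys:
                    rows.append((f"c{i}", "multiplex", w, c, p, r, a, g,
                                 int(rng.integers(0, 5)), 10_000))
        controls = _obs(rows)
        ref = build_control_reference(controls)

        # brute-force reference from first principles
        df = controls.copy()
        df["maf"] = df.mutant_uids / df.total_uids
        df["label"] = df.chrom + ":" + df.pos.astype(str) + ":" + df.ref + ">" + df.alt
        floor = max(0.2 / len(df), 1e-6)
        stats = {}
        null = []
        for lab, grp in df.groupby("label"):
            med = float(np.median(grp.maf))
            mad = float(np.median(np.abs(grp.maf - med))) * 1.4826
            stats[lab] = (med, max(mad, floor))
        for _, row in df.iterrows():
            med, sc = stats[row.label]
            null.append((row.maf - med) / sc)

        for lab in stats:
            med, sc = stats[lab]
            assert ref.location(lab) == pytest.approx(med, abs=1e-15)
            assert ref.scale(lab) == pytest.approx(sc, abs=1e-15)
        assert np.allclose(np.sort(null), ref.pooled_null, atol=1e-15)

        for maf1, maf2, u1, u2 in [(3e-4, 5e-4, 9000, 11000), (0.0, 1e-4, 12000, 8000)]:
            lab = "1:10:C>T"
            s1 = (maf1 - stats[lab][0]) / stats[lab][1]
            s2 = (maf2 - stats[lab][0]) / stats[lab][1]
            p1 = (1 + sum(1 for v in null if v >= s1)) / (len(null) + 1)
            p2 = (1 + sum(1 for v in null if v >= s2)) / (len(null) + 1)
            w1, w2 = np.sqrt(u1), np.sqrt(u2)
            zz = (w1 * norm.isf(p1) + w2 * norm.isf(p2)) / np.sqrt(w1**2 + w2**2)
            assert empirical_pvalue(normalized_score(maf1, lab, ref), ref.pooled_null) == pytest.approx(p1, abs=1e-12)
            assert stouffer_combine(p1, p2, u1, u2) == pytest.approx(zz, abs=1e-12)


class TestIdentity:
    def test_identical_and_half_matching(self):
        a = {f"s{i}": i % 3 for i in range(30)}
        frac, flag = identity_concordance(a, dict(a))
        assert frac == 1.0 and not flag
        b = dict(a)
        for i in range(15):
            b[f"s{i}"] = (a[f"s{i}"] + 1) % 3
        frac, flag = identity_concordance(a, b)
        assert frac == 0.5 and flag

    def test_too_few_compared_flags(self):
        a = {f"s{i}": 1 for i in range(5)}
        frac, flag = identity_concordance(a, dict(a))
        assert flag  # fewer than 10 comparable SNPs

    def test_disjoint_sets_error(self):
        with pytest.raises(ValueError):
            identity_concordance({"a": 1}, {"b": 1})

    def test_planted_swap_detected(self, sim):
        g = sim.identity_genotypes(["p1", "p2", "p3"], swap=("p1", "p2"))
        flagged = []
        for pid, grp in g.groupby("patient_id"):
            urine = dict(zip(grp.snp, grp.urine))
            tumor = dict(zip(grp.snp, grp.tumor))
            _, flag = identity_concordance(urine, tumor)
            if flag:
                flagged.append(pid)
        assert sorted(flagged) == ["p1", "p2"]
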