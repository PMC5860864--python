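"""Synthetic cohort generation for the urinary-cell detection pipeline.

The simulator emulates the data the calling pipeline consumes, with known
truth:

* **Control panels** — WBC and urine UID-family tables from healthy
  individuals, carrying only the background error process.  Errors are
  overdispersed: each queried position gets a persistent position-specific
  error rate (Gamma-distributed around the global rate, reflecting
  context-dependent PCR/sequencing error heterogeneity — the reason the
  caller normalises per mutation), and each well adds a Gamma-Poisson
  (negative-binomial) draw on top.
* **Patient assay bundles** — two multiplex wells, two TERT wells and one
  repeat-locus count profile per patient.  Planted mutations appear in both
  wells, binomially sampled per well at the planted urine fraction on top of
  background; arm-level events scale the expected representation of an arm's
  loci by (1 ± nf/2) for a single-copy gain/loss at neoplastic fraction nf
  (diploid baseline, one copy changed).
* **Cohorts** — case/non-case assignment exactly matching the design,
  two-stage urine shedding (is the tumour mutated? does the urine contain
  assay-detectable tumour DNA?) so that both false-negative modes arise
  naturally, cytology categories, and collection/diagnosis dates in days.

Identical configuration (including seed) gives bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import (
    IDENTITY_SNPS,
    NON_ACROCENTRIC_ARMS,
    Panel,
    default_panel,
    uniform_arm_map,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "CohortSimulator",
    "CohortData",
    "simulate_control_panels",
    "simulate_patient",
    "simulate_cohort",
]

CYTOLOGY_CATEGORIES = ("positive", "atypical", "negative", "unavailable")
COHORTS = ("early_detection", "utuc", "surveillance")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"configuration error: {name} must be in [0, 1], got {value}")


def _check_pos(name: str, value: float) -> None:
    if value <= 0:
        raise ValueError(f"configuration error: {name} must be positive, got {value}")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    Defaults reproduce the study conditions the pipeline was built around:
    188 healthy-control urines and WBC panels, UID depths log-normal with
    median ~10,000 families per position per well, a 1e-4 background
    substitution rate with position-to-position variation, case urine MAFs
    log-normal with median 8% (multiplex) / 6% (TERT) spanning roughly
    0.003-0.8, 95% of case tumours carrying >=1 queried mutation, cohort
    designs of 570 (175 cancers), 56 UTUC (all cancers) and 322 surveillance
    (187 recurrences), and a desk-scale 3,900-locus aneuploidy assay (100
    loci per arm; the full-scale 38,000 is a configuration change).
    """

    seed: int = 0
    n_control_urines: int = 188
    n_control_wbc: int = 188
    n_control_wbc_technical: int = 94

    # UID-family depth per position per well: log-normal, median uid_depth_median.
    uid_depth_median: float = 10_000.0
    uid_depth_sigma: float = 0.5

    # Background error process.
    background_error_rate: float = 1e-4
    position_dispersion: float = 1.0   # Gamma shape of position-specific rates (mean 1)
    well_dispersion: float = 5.0       # Gamma shape of the per-well factor (mean 1)

    # Planted urine mutant fractions: log-normal, clipped to case_maf_range.
    case_maf_median_multiplex: float = 0.08
    case_maf_median_tert: float = 0.06
    case_maf_sigma: float = 1.1
    case_maf_range: tuple[float, float] = (0.003, 0.8)

    # Tumour genotype and shedding.
    tumor_mutation_probability: float = 0.95
    tert_given_mutated: float = 0.65
    extra_multiplex_rate: float = 1.4  # Poisson mean of multiplex mutation count
    shed_probability: float = 0.8
    noncase_mutation_probability: float = 0.05  # low-level clonal signal in non-cases
    noncase_maf_median: float = 0.01

    # Aneuploidy assay.
    n_loci: int = 3900
    locus_depth_median: float = 8e6
    locus_depth_sigma: float = 0.25
    locus_weight_sigma: float = 0.3    # fixed per-locus amplification bias
    recurrent_arms: tuple[str, ...] = ("5q", "8q", "9p")
    recurrent_arm_weight: float = 8.0  # relative draw weight of recurrent arms
    max_arm_events: int = 5
    tumor_aneuploid_probability: float = 0.9
    neoplastic_fraction_range: tuple[float, float] = (0.002, 0.30)

    # Cohort designs: name -> (size, number of cancers).
    cohort_design: dict = field(
        default_factory=lambda: {
            "early_detection": (570, 175),
            "utuc": (56, 56),
            "surveillance": (322, 187),
        }
    )

    # Cytology: availability, and category rates given availability.
    cytology_availability: dict = field(
        default_factory=lambda: {"early_detection": 0.61, "utuc": 0.75, "surveillance": 0.61}
    )
    cytology_sensitivity: dict = field(
        default_factory=lambda: {"early_detection": 0.43, "utuc": 0.10, "surveillance": 0.25}
    )
    cytology_atypical_case: float = 0.30
    cytology_atypical_noncase: float = 0.25

    # Diagnosis delay after collection (days): log-normal.
    diagnosis_delay_median_days: float = 40.0
    diagnosis_delay_sigma: float = 1.1

    def validate(self) -> None:
        for name in (
            "tumor_mutation_probability", "tert_given_mutated", "shed_probability",
            "noncase_mutation_probability", "tumor_aneuploid_probability",
            "cytology_atypical_case", "cytology_atypical_noncase",
        ):
            _check_prob(name, getattr(self, name))
        for cohort, p in self.cytology_availability.items():
            _check_prob(f"cytology_availability[{cohort}]", p)
        for cohort, p in self.cytology_sensitivity.items():
            _check_prob(f"cytology_sensitivity[{cohort}]", p)
        for name in (
            "uid_depth_median", "uid_depth_sigma", "position_dispersion",
            "well_dispersion", "case_maf_sigma", "locus_depth_median",
            "diagnosis_delay_median_days", "extra_multiplex_rate",
        ):
            _check_pos(name, getattr(self, name))
        if self.background_error_rate < 0:
            raise ValueError("configuration error: background_error_rate must be >= 0")
        if self.n_loci % 39 != 0:
            raise ValueError(f"configuration error: n_loci must be divisible by 39, got {self.n_loci}")
        lo, hi = self.case_maf_range
        if not 0 < lo < hi <= 1:
            raise ValueError(f"configuration error: case_maf_range invalid: {self.case_maf_range}")
        lo, hi = self.neoplastic_fraction_range
        if not 0 < lo < hi <= 1:
            raise ValueError(
                f"configuration error: neoplastic_fraction_range invalid: {self.neoplastic_fraction_range}"
            )
        for cohort, (size, cases) in self.cohort_design.items():
            if size <= 0:
                raise ValueError(f"configuration error: cohort_design[{cohort}] size must be positive")
            if cases > size or cases < 0:
                raise ValueError(
                    f"configuration error: cohort_design[{cohort}] case count {cases} > size {size}"
                )
        unknown = set(self.recurrent_arms) - set(NON_ACROCENTRIC_ARMS)
        if unknown:
            raise ValueError(f"configuration error: unknown recurrent_arms {sorted(unknown)}")


@dataclass
class TruthRecord:
    """Ground truth for one simulated patient."""

    patient_id: str
    cohort: str
    is_cancer: bool
    planted_mutations: list = field(default_factory=list)  # [(label, urine fraction)]
    tumor_mutations: list = field(default_factory=list)    # [label]
    arm_events: list = field(default_factory=list)         # [(arm, "gain"|"loss")]
    neoplastic_fraction: float = 0.0
    cytology: str = "unavailable"
    collection_day: int = 0
    diagnosis_day: int | None = None
    grade: str | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.cytology not in CYTOLOGY_CATEGORIES:
            raise ValueError(f"unknown cytology category {self.cytology!r}")
        if self.is_cancer:
            if self.diagnosis_day is not None and self.diagnosis_day < self.collection_day:
                raise ValueError("diagnosis_day must be >= collection_day")
        elif self.diagnosis_day is not None:
            raise ValueError("non-cases cannot have a diagnosis date")
        planted = {m for m, _ in self.planted_mutations}
        if self.tumor_mutations and not planted <= set(self.tumor_mutations):
            raise ValueError("planted urine mutations must be a subset of tumour mutations")
        for _, f in self.planted_mutations:
            if not 0 < f <= 1:
                raise ValueError(f"planted fraction {f} outside (0, 1]")


@dataclass
class CohortData:
    """One simulated cohort: truth, assay tables, clinical sheet."""

    cohort: str
    truth_records: list
    truth: pd.DataFrame
    mutation_obs: pd.DataFrame
    locus_counts: pd.DataFrame  # loci x patients
    clinical: pd.DataFrame


class CohortSimulator:
    """Deterministic generator for control panels, patients and cohorts.

    Position-specific error rates and per-locus amplification weights are
    drawn once at construction (from the config seed) and shared by every
    sample the instance generates, so controls and patients see the same
    error landscape — the property the caller's per-mutation normalisation
    exists to absorb.
    """

    def __init__(self, config: SimulationConfig | None = None, panel: Panel | None = None) -> None:
        self.config = config if config is not None else SimulationConfig()
        self.config.validate()
        self.panel = panel if panel is not None else default_panel()
        self.arm_map = uniform_arm_map(self.config.n_loci)

        root = np.random.SeedSequence(self.config.seed)
        (s_panel, s_loci, self._ss_controls, self._ss_cohorts,
         self._ss_profiles, self._ss_misc) = root.spawn(6)
        rng = np.random.default_rng(s_panel)
        n_keys = len(self.panel)
        shape = self.config.position_dispersion
        if self.config.background_error_rate > 0:
            factors = rng.gamma(shape, 1.0 / shape, size=n_keys)
        else:
            factors = np.zeros(n_keys)
        self.position_error_rates = pd.Series(
            self.config.background_error_rate * factors,
            index=[k.label for k in self.panel],
        )
        rng_l = np.random.default_rng(s_loci)
        w = rng_l.lognormal(0.0, self.config.locus_weight_sigma, size=self.config.n_loci)
        self.locus_weights = pd.Series(w, index=self.arm_map.index)

    # ---------------------------------------------------------------- wells

    def _key_frame(self) -> pd.DataFrame:
        return self.panel.to_frame()

    def _sample_wells(
        self,
        sample_ids: Sequence[str],
        rng: np.random.Generator,
        planted: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    ) -> pd.DataFrame:
        """UID-family tables for a batch of samples (two wells per assay)."""
        cfg = self.config
        keys = self._key_frame()
        n_s, n_k = len(sample_ids), len(keys)
        mu = np.log(cfg.uid_depth_median)
        totals = rng.lognormal(mu, cfg.uid_depth_sigma, size=(n_s, n_k, 2))
        totals = np.maximum(np.rint(totals), 100).astype(np.int64)
        rates = self.position_error_rates.to_numpy()[None, :, None]
        disp = rng.gamma(cfg.well_dispersion, 1.0 / cfg.well_dispersion, size=(n_s, n_k, 2))
        lam = totals * rates * disp
        mutant = rng.poisson(lam)
        if planted:
            labels = keys["chrom"].astype(str) + ":" + keys["pos"].astype(str) + ":" + \
                keys["ref"] + ">" + keys["alt"]
            idx_of = {lab: i for i, lab in enumerate(labels)}
            for s_i, sid in enumerate(sample_ids):
                for lab, frac in planted.get(sid, ()):  # independent binomial per well
                    if not 0 < frac <= 1:
                        raise ValueError(f"planted fraction {frac} outside (0, 1] for {sid}/{lab}")
                    k_i = idx_of[lab]
                    mutant[s_i, k_i, :] += rng.binomial(totals[s_i, k_i, :], frac)
        mutant = np.minimum(mutant, totals)

        frames = []
        for w in (0, 1):
            f = keys.copy()
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": np.repeat(sample_ids, n_k),
                        "assay": np.tile(f["assay"].to_numpy(), n_s),
                        "well": w + 1,
                        "chrom": np.tile(f["chrom"].to_numpy(), n_s),
                        "pos": np.tile(f["pos"].to_numpy(), n_s),
                        "ref": np.tile(f["ref"].to_numpy(), n_s),
                        "alt": np.tile(f["alt"].to_numpy(), n_s),
                        "gene": np.tile(f["gene"].to_numpy(), n_s),
                        "mutant_uids": mutant[:, :, w].reshape(-1),
                        "total_uids": totals[:, :, w].reshape(-1),
                    }
                )
            )
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["patient_id", "assay", "well", "chrom", "pos"], ignore_index=True)

    # ------------------------------------------------------------- controls

    def control_panels(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(control WBC table, control urine table); background errors only."""
        ss = np.random.SeedSequence(entropy=self._ss_controls.entropy, spawn_key=(0,))
        rng = np.random.default_rng(ss)
        wbc_ids = [f"WBC{i:04d}" for i in range(self.config.n_control_wbc)]
        urine_ids = [f"CTRLU{i:04d}" for i in range(self.config.n_control_urines)]
        wbc = self._sample_wells(wbc_ids, rng)
        urine = self._sample_wells(urine_ids, rng)
        return wbc, urine

    def technical_wbc_panel(self) -> pd.DataFrame:
        """The smaller WBC set used for technical-specificity checks."""
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self._ss_controls.entropy, spawn_key=(1,))
        )
        ids = [f"TWBC{i:04d}" for i in range(self.config.n_control_wbc_technical)]
        return self._sample_wells(ids, rng)

    def holdout_control_urines(self, n: int | None = None, stream: int = 0) -> pd.DataFrame:
        """An independent control-urine set (new random stream)."""
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self._ss_controls.entropy, spawn_key=(2, stream))
        )
        n = n if n is not None else self.config.n_control_urines
        ids = [f"HOLD{stream}_{i:04d}" for i in range(n)]
        return self._sample_wells(ids, rng)

    # ------------------------------------------------------- locus profiles

    def _locus_profile(
        self,
        rng: np.random.Generator,
        arm_events: Sequence[tuple[str, str]] = (),
        neoplastic_fraction: float = 0.0,
        depth: int | None = None,
    ) -> pd.Series:
        cfg = self.config
        w = self.locus_weights.to_numpy().copy()
        for arm, kind in arm_events:
            if kind not in ("gain", "loss"):
                raise ValueError(f"arm event must be gain or loss, got {kind!r}")
            mask = (self.arm_map["arm"] == arm).to_numpy()
            if not mask.any():
                raise ValueError(f"unknown arm {arm!r}")
            factor = 1.0 + neoplastic_fraction / 2.0 if kind == "gain" else 1.0 - neoplastic_fraction / 2.0
            w[mask] *= factor
        p = w / w.sum()
        if depth is None:
            depth = int(max(np.rint(rng.lognormal(np.log(cfg.locus_depth_median), cfg.locus_depth_sigma)), 10_000))
        counts = rng.multinomial(depth, p)
        return pd.Series(counts, index=self.arm_map.index)

    def euploid_profiles(self, n: int, prefix: str = "EUP", stream: int = 0) -> pd.DataFrame:
        """n euploid locus-count profiles (columns = samples)."""
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self._ss_profiles.entropy, spawn_key=(stream,))
        )
        cols = {f"{prefix}{i:04d}": self._locus_profile(rng) for i in range(n)}
        return pd.DataFrame(cols, index=self.arm_map.index)

    # -------------------------------------------------------------- patients

    def simulate_patient(
        self, truth: TruthRecord, rng: np.random.Generator | None = None
    ) -> tuple[pd.DataFrame, pd.Series]:
        """Assay bundle for one patient: 4 mutation wells + 1 locus profile."""
        if rng is None:
            tag = zlib.crc32(truth.patient_id.encode()) % 2**31
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=self._ss_misc.entropy, spawn_key=(tag,))
            )
        obs = self._sample_wells([truth.patient_id], rng, {truth.patient_id: truth.planted_mutations})
        profile = self._locus_profile(rng, truth.arm_events, truth.neoplastic_fraction)
        profile.name = truth.patient_id
        return obs, profile

    # --------------------------------------------------------------- truth

    def _draw_tumor_mutations(self, rng: np.random.Generator) -> list[str]:
        cfg = self.config
        mult_keys = self.panel.subset("multiplex")
        tert_keys = self.panel.subset("tert")
        gene_weights = {
            "TP53": 0.45, "FGFR3": 0.20, "PIK3CA": 0.08, "HRAS": 0.05, "KRAS": 0.05,
            "ERBB2": 0.04, "CDKN2A": 0.05, "MET": 0.03, "VHL": 0.02, "KMT2A": 0.03,
        }
        by_gene: dict[str, list] = {}
        for k in mult_keys:
            by_gene.setdefault(k.gene, []).append(k)
        genes = [g for g in gene_weights if g in by_gene]
        gw = np.array([gene_weights[g] for g in genes])
        gw = gw / gw.sum()

        muts: set[str] = set()
        n_mult = rng.poisson(cfg.extra_multiplex_rate)
        has_tert = rng.random() < cfg.tert_given_mutated
        if n_mult == 0 and not has_tert:
            n_mult = 1
        for _ in range(n_mult):
            g = genes[rng.choice(len(genes), p=gw)]
            muts.add(rng.choice(by_gene[g]).label)
        if has_tert:
            tw = np.array([0.79, 0.02, 0.19])  # g.1295228, g.1295242, g.1295250 in panel order
            order = sorted(tert_keys, key=lambda k: k.pos)
            muts.add(order[rng.choice(3, p=tw)].label)
        return sorted(muts)

    def _draw_arm_events(self, rng: np.random.Generator) -> list[tuple[str, str]]:
        cfg = self.config
        n_events = int(rng.integers(1, cfg.max_arm_events + 1))
        weights = np.ones(len(NON_ACROCENTRIC_ARMS))
        for arm in cfg.recurrent_arms:
            weights[NON_ACROCENTRIC_ARMS.index(arm)] = cfg.recurrent_arm_weight
        weights /= weights.sum()
        arms = rng.choice(len(NON_ACROCENTRIC_ARMS), size=n_events, replace=False, p=weights)
        events = []
        for a in arms:
            arm = NON_ACROCENTRIC_ARMS[a]
            # p arms (9p and friends) are predominantly lost, q arms gained
            p_loss = 0.7 if arm.endswith("p") else 0.3
            kind = "loss" if rng.random() < p_loss else "gain"
            events.append((arm, kind))
        return events

    def _draw_maf(self, rng: np.random.Generator, label: str) -> float:
        cfg = self.config
        median = cfg.case_maf_median_tert if label.startswith("5:1295") else cfg.case_maf_median_multiplex
        f = rng.lognormal(np.log(median), cfg.case_maf_sigma)
        return float(np.clip(f, *cfg.case_maf_range))

    def _cytology(self, rng: np.random.Generator, cohort: str, is_cancer: bool) -> str:
        cfg = self.config
        if rng.random() >= cfg.cytology_availability[cohort]:
            return "unavailable"
        if is_cancer:
            if rng.random() < cfg.cytology_sensitivity[cohort]:
                return "positive"
            return "atypical" if rng.random() < cfg.cytology_atypical_case else "negative"
        # cytology read by an expert is essentially never falsely positive
        return "atypical" if rng.random() < cfg.cytology_atypical_noncase else "negative"

    def simulate_truth(self, cohort: str) -> list[TruthRecord]:
        """Truth records for one cohort; case count matches the design exactly."""
        cfg = self.config
        if cohort not in cfg.cohort_design:
            raise ValueError(f"no design for cohort {cohort!r}")
        size, n_cases = cfg.cohort_design[cohort]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self._ss_cohorts.entropy, spawn_key=(COHORTS.index(cohort),))
        )
        is_cancer = np.zeros(size, dtype=bool)
        is_cancer[:n_cases] = True
        rng.shuffle(is_cancer)

        lo_nf, hi_nf = cfg.neoplastic_fraction_range
        records = []
        for i in range(size):
            pid = f"{cohort[:2].upper()}{i:04d}"
            cancer = bool(is_cancer[i])
            tumor_muts: list[str] = []
            planted: list[tuple[str, float]] = []
            arm_events: list[tuple[str, str]] = []
            nf = 0.0
            diagnosis = None
            grade = stage = None
            if cancer:
                if rng.random() < cfg.tumor_mutation_probability:
                    tumor_muts = self._draw_tumor_mutations(rng)
                aneuploid = rng.random() < cfg.tumor_aneuploid_probability
                shed = rng.random() < cfg.shed_probability
                if shed:
                    planted = [(m, self._draw_maf(rng, m)) for m in tumor_muts]
                    if aneuploid:
                        arm_events = self._draw_arm_events(rng)
                        nf = float(np.exp(rng.uniform(np.log(lo_nf), np.log(hi_nf))))
                delay = int(max(np.rint(rng.lognormal(np.log(cfg.diagnosis_delay_median_days),
                                                      cfg.diagnosis_delay_sigma)), 0))
                diagnosis = delay
                grade = "low" if rng.random() < 0.3 else "high"
                stage = str(rng.choice(["Ta", "T1", "T2+"], p=[0.45, 0.30, 0.25]))
            cytology = self._cytology(rng, cohort, cancer)
            records.append(
                TruthRecord(
                    patient_id=pid, cohort=cohort, is_cancer=cancer,
                    planted_mutations=planted, tumor_mutations=tumor_muts,
                    arm_events=arm_events, neoplastic_fraction=nf,
                    cytology=cytology, collection_day=0, diagnosis_day=diagnosis,
                    grade=grade, stage=stage,
                )
            )
            # low-level clonal signal in a small fraction of non-cases
            if not cancer and rng.random() < cfg.noncase_mutation_probability:
                lab = self._draw_tumor_mutations(rng)[0]
                f = float(np.clip(rng.lognormal(np.log(cfg.noncase_maf_median), cfg.case_maf_sigma),
                                  *cfg.case_maf_range))
                rec = records[-1]
                rec.tumor_mutations = []
                rec.planted_mutations = [(lab, f)]
        return records

    def simulate_cohort(self, cohort: str) -> CohortData:
        """Full assay bundle + clinical sheet for one cohort."""
        records = self.simulate_truth(cohort)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=self._ss_cohorts.entropy, spawn_key=(100 + COHORTS.index(cohort),)
            )
        )
        ids = [r.patient_id for r in records]
        planted = {r.patient_id: r.planted_mutations for r in records}
        obs = self._sample_wells(ids, rng, planted)
        profiles = {}
        for r in records:
            profiles[r.patient_id] = self._locus_profile(rng, r.arm_events, r.neoplastic_fraction)
        locus_counts = pd.DataFrame(profiles, index=self.arm_map.index)

        truth = pd.DataFrame(
            {
                "patient_id": ids,
                "cohort": cohort,
                "is_cancer": [r.is_cancer for r in records],
                "cytology": [r.cytology for r in records],
                "collection_day": [r.collection_day for r in records],
                "diagnosis_day": [r.diagnosis_day for r in records],
                "grade": [r.grade for r in records],
                "stage": [r.stage for r in records],
                "neoplastic_fraction": [r.neoplastic_fraction for r in records],
                "n_tumor_mutations": [len(r.tumor_mutations) for r in records],
                "tumor_mutations": [";".join(r.tumor_mutations) for r in records],
                "planted_mutations": [
                    ";".join(f"{m}@{f:.6g}" for m, f in r.planted_mutations) for r in records
                ],
                "arm_events": [";".join(f"{a}:{k}" for a, k in r.arm_events) for r in records],
            }
        )
        clinical = truth[
            ["patient_id", "cohort", "is_cancer", "cytology", "collection_day",
             "diagnosis_day", "grade", "stage"]
        ].copy()
        return CohortData(cohort, records, truth, obs, locus_counts, clinical)

    # ------------------------------------------------------------ genotypes

    def identity_genotypes(
        self, patient_ids: Sequence[str], swap: tuple[str, str] | None = None
    ) -> pd.DataFrame:
        """Urine/tumour genotype pairs over the 31 identity SNPs.

        Each patient's urine and tumour genotypes are identical draws from
        Hardy-Weinberg at a per-SNP allele frequency; ``swap=(a, b)``
        exchanges the *tumour* genotypes of two patients, planting a sample
        mix-up.  Returns a tidy frame: patient_id, snp, urine, tumor.
        """
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self._ss_misc.entropy, spawn_key=(7,))
        )
        freqs = rng.uniform(0.2, 0.8, size=len(IDENTITY_SNPS))
        geno = {
            pid: rng.binomial(2, freqs) for pid in patient_ids
        }
        tumor = {pid: g.copy() for pid, g in geno.items()}
        if swap is not None:
            a, b = swap
            tumor[a], tumor[b] = tumor[b], tumor[a]
        rows = []
        for pid in patient_ids:
            for j, snp in enumerate(IDENTITY_SNPS):
                rows.append((pid, snp, int(geno[pid][j]), int(tumor[pid][j])))
        return pd.DataFrame(rows, columns=["patient_id", "snp", "urine", "tumor"])


# ------------------------------------------------------- functional surface

def simulate_control_panels(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(control WBC table, control urine table) under ``config``."""
    return CohortSimulator(config).control_panels()


def simulate_patient(truth: TruthRecord, config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """One patient's assay bundle under ``config``."""
    return CohortSimulator(config).simulate_patient(truth)


def simulate_cohort(config: SimulationConfig, cohort: str = "early_detection") -> CohortData:
    """One cohort's truth records, assay bundle and clinical sheet."""
    return CohortSimulator(config).simulate_cohort(cohort)
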