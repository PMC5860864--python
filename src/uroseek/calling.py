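"""UID-family mutation calling with control-based calibration.

The caller works on UID-family count tables: for each queried position the
mutant allele frequency (MAF) is the number of mutant UID families divided by
the total UID families in that well.  A candidate mutation in a patient sample
is scored against a panel of normal controls by two complementary criteria:

``difference``
    the average MAF across the sample's two independent PCR wells minus the
    maximum MAF observed for that same mutation in the control WBC panel;
    positive when the difference exceeds the highest MAF seen at *any*
    position in any control WBC.

``stouffer``
    each well's MAF is normalised by the mutation-specific control
    distribution (robust location/scale), converted to a one-sided empirical
    p-value against the pooled normalised control null, mapped to a z-score,
    and the two wells combined with a Stouffer Z weighted by the wells' UID
    depths; positive when Z exceeds a threshold calibrated to allow exactly
    one positive among the control urine panel.

A mutation is only ever called when both wells show mutant UID families; a
sample is mutation-positive when any queried position is called.

The model/results split follows the usual statistical-modelling idiom:
:class:`MutationCallerModel` holds the control data, :meth:`~MutationCallerModel.fit`
builds the control reference and calibrates both thresholds, and the returned
:class:`MutationCallerResults` scores patient samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import Panel, default_panel

__all__ = [
    "compute_maf",
    "ControlReference",
    "build_control_reference",
    "normalized_score",
    "empirical_pvalue",
    "stouffer_combine",
    "difference_stat",
    "calibrate_thresholds",
    "call_mutations",
    "identity_concordance",
    "MutationCallerModel",
    "MutationCallerResults",
]

logger = logging.getLogger(__name__)

#: Columns of a mutation observation table.
OBSERVATION_COLUMNS = (
    "patient_id", "assay", "well", "chrom", "pos", "ref", "alt", "gene",
    "mutant_uids", "total_uids",
)

_KEY_COLS = ["assay", "chrom", "pos", "ref", "alt", "gene"]

#: Minimum mutant UID families per well for a position to enter scoring.
MIN_MUTANT_FAMILIES = 2

#: Robust-scale floor terms: max(MAD*1.4826, SCALE_FLOOR_OVER_N / n, SCALE_FLOOR_ABS).
SCALE_FLOOR_OVER_N = 0.2
SCALE_FLOOR_ABS = 1e-6


def compute_maf(mutant_uid_families: int, total_uid_families: int) -> float:
    """Mutant allele frequency: mutant UID families / total UID families."""
    if total_uid_families <= 0:
        raise ValueError("MAF undefined: total UID families must be positive")
    if not 0 <= mutant_uid_families <= total_uid_families:
        raise ValueError(
            f"mutant families ({mutant_uid_families}) outside [0, total={total_uid_families}]"
        )
    return mutant_uid_families / total_uid_families


def _label(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":"
        + df["ref"].astype(str) + ">" + df["alt"].astype(str)
    )


@dataclass(frozen=True)
class ControlReference:
    """Per-mutation control summaries, pooled null, and calibrated thresholds.

    ``per_key`` is indexed by mutation label with columns location (median
    control MAF), scale (MAD * 1.4826, floored), max_maf (per-key maximum
    control MAF), n_obs.  ``pooled_null`` is the sorted vector of normalised
    control values over all keys, controls and wells.  ``t_diff`` / ``t_z``
    are None until calibrated.
    """

    per_key: pd.DataFrame
    pooled_null: np.ndarray
    fallback_location: float
    fallback_scale: float
    fallback_max_maf: float
    t_diff: float | None = None
    t_z: float | None = None
    min_mutant_families: int = MIN_MUTANT_FAMILIES
    weight_mode: str = "sqrt"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pooled_null) == 0:
            raise ValueError("pooled null is empty")
        if (self.per_key["scale"] <= 0).any():
            raise ValueError("control scale must be positive for every key")

    @property
    def calibrated(self) -> bool:
        return self.t_diff is not None and self.t_z is not None

    def location(self, label: str) -> float:
        if label in self.per_key.index:
            return float(self.per_key.at[label, "location"])
        return self.fallback_location

    def scale(self, label: str) -> float:
        if label in self.per_key.index:
            return float(self.per_key.at[label, "scale"])
        return self.fallback_scale

    def max_maf(self, label: str) -> float:
        if label in self.per_key.index:
            return float(self.per_key.at[label, "max_maf"])
        return self.fallback_max_maf


def _robust_scale(values: np.ndarray) -> float:
    mad = np.median(np.abs(values - np.median(values)))
    return float(mad * 1.4826)


def build_control_reference(
    control_obs: pd.DataFrame,
    panel: Panel | None = None,
    min_mutant_families: int = MIN_MUTANT_FAMILIES,
    weight_mode: str = "sqrt",
) -> ControlReference:
    """Build the per-mutation control reference from control WBC observations.

    For each queried position the location is the median control MAF and the
    scale is MAD * 1.4826, floored at max(0.2/N, 1e-6) where N is the total
    number of control observations in the panel; keys in the panel with
    fewer than two control observations fall back to panel-wide pooled
    statistics (logged).  The pooled null collects every normalised control
    value (both wells of every control) over all keys.
    """
    if control_obs is None or len(control_obs) == 0:
        raise ValueError("control observation set is empty")
    obs = control_obs.copy()
    obs = obs[obs["total_uids"] > 0]
    obs["maf"] = obs["mutant_uids"] / obs["total_uids"]
    obs["label"] = _label(obs)

    all_mafs = obs["maf"].to_numpy()
    n_pooled = len(all_mafs)
    floor = max(SCALE_FLOOR_OVER_N / n_pooled, SCALE_FLOOR_ABS)
    fb_loc = float(np.median(all_mafs))
    fb_scale = max(_robust_scale(all_mafs), floor)
    fb_max = float(all_mafs.max())

    rows = {}
    for label, grp in obs.groupby("label", sort=True):
        mafs = grp["maf"].to_numpy()
        n = len(mafs)
        if n < 2:
            logger.warning("key %s has %d control observations; using pooled fallback", label, n)
            continue
        scale = max(_robust_scale(mafs), floor)
        rows[label] = {
            "location": float(np.median(mafs)),
            "scale": scale,
            "max_maf": float(mafs.max()),
            "n_obs": n,
        }
    if panel is not None:
        panel_labels = {k.label for k in panel}
        for lab in sorted(panel_labels - set(rows)):
            logger.warning("panel key %s absent from controls; pooled fallback applies", lab)
    per_key = pd.DataFrame.from_dict(rows, orient="index")
    per_key.index.name = "label"

    loc = obs["label"].map(per_key["location"]).fillna(fb_loc).to_numpy()
    scl = obs["label"].map(per_key["scale"]).fillna(fb_scale).to_numpy()
    pooled = np.sort((obs["maf"].to_numpy() - loc) / scl)

    return ControlReference(
        per_key=per_key,
        pooled_null=pooled,
        fallback_location=fb_loc,
        fallback_scale=fb_scale,
        fallback_max_maf=fb_max,
        min_mutant_families=min_mutant_families,
        weight_mode=weight_mode,
        provenance={"n_control_observations": int(len(obs))},
    )


def normalized_score(maf, key_label: str, reference: ControlReference):
    """Mutation-specific robust normalisation: (maf - location) / scale."""
    return (np.asarray(maf, dtype=float) - reference.location(key_label)) / reference.scale(key_label)


def empirical_pvalue(score, pooled_null: np.ndarray):
    """One-sided add-one-smoothed empirical p: (1 + #{null >= score}) / (N + 1)."""
    null = np.asarray(pooled_null)
    n = len(null)
    if n < 1:
        raise ValueError("pooled null must be non-empty")
    score = np.asarray(score, dtype=float)
    n_ge = n - np.searchsorted(null, score, side="left")
    p = (1.0 + n_ge) / (n + 1.0)
    return p if p.ndim else float(p)


def _weights(uid1, uid2, mode: str):
    uid1 = np.asarray(uid1, dtype=float)
    uid2 = np.asarray(uid2, dtype=float)
    if np.any(uid1 <= 0) or np.any(uid2 <= 0):
        raise ValueError("UID counts must be positive")
    if mode == "sqrt":
        return np.sqrt(uid1), np.sqrt(uid2)
    if mode == "linear":
        return uid1, uid2
    raise ValueError(f"unknown weight mode {mode!r}")


def stouffer_combine(p1, p2, uid1, uid2, weight_mode: str = "sqrt"):
    """UID-weighted Stouffer combination of two wells' one-sided p-values.

    z_i = Phi^-1(1 - p_i); weights w_i = sqrt(UID_i) by default (the
    information in a proportion grows linearly in the number of templates, so
    its z-scale weight is sqrt(n)); ``weight_mode="linear"`` uses w_i = UID_i.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 <= 0) | (p1 > 1)) or np.any((p2 <= 0) | (p2 > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    z1 = norm.isf(p1)
    z2 = norm.isf(p2)
    w1, w2 = _weights(uid1, uid2, weight_mode)
    z = (w1 * z1 + w2 * z2) / np.sqrt(w1 * w1 + w2 * w2)
    return z if z.ndim else float(z)


def difference_stat(avg_maf, key_label: str, reference: ControlReference):
    """Average sample MAF minus the per-mutation maximum control MAF."""
    return np.asarray(avg_maf, dtype=float) - reference.max_maf(key_label)


def _check_wells(obs: pd.DataFrame) -> None:
    wells = obs.groupby(["patient_id", "assay"])["well"].agg(lambda s: set(s))
    bad = wells[wells.apply(lambda s: s != {1, 2})]
    if len(bad):
        detail = "; ".join(f"{p}/{a}: wells {sorted(w)}" for (p, a), w in bad.items())
        raise ValueError(f"each sample needs exactly wells {{1, 2}} per assay — {detail}")


def _score_table(obs: pd.DataFrame, reference: ControlReference) -> pd.DataFrame:
    """Vectorised two-criterion scoring of an observation table.

    Returns one row per (patient, key) with both wells present and at least
    ``min_mutant_families`` mutant UID families in each well.
    """
    obs = obs[obs["total_uids"] > 0].copy()
    obs["label"] = _label(obs)
    wide = obs.pivot_table(
        index=["patient_id", *_KEY_COLS, "label"],
        columns="well",
        values=["mutant_uids", "total_uids"],
        aggfunc="first",
    )
    wide.columns = [f"{v}_{w}" for v, w in wide.columns]
    wide = wide.reset_index()
    needed = {"mutant_uids_1", "mutant_uids_2", "total_uids_1", "total_uids_2"}
    for col in needed - set(wide.columns):
        wide[col] = np.nan
    floor = reference.min_mutant_families
    cand = wide[
        (wide["mutant_uids_1"] >= floor)
        & (wide["mutant_uids_2"] >= floor)
        & wide["total_uids_1"].notna()
        & wide["total_uids_2"].notna()
    ].copy()
    if len(cand) == 0:
        return cand.assign(
            maf_1=[], maf_2=[], avg_maf=[], diff_stat=[], p_1=[], p_2=[],
            z_1=[], z_2=[], stouffer_z=[], present_in_both_wells=[],
        )
    cand["maf_1"] = cand["mutant_uids_1"] / cand["total_uids_1"]
    cand["maf_2"] = cand["mutant_uids_2"] / cand["total_uids_2"]
    cand["avg_maf"] = (cand["maf_1"] + cand["maf_2"]) / 2.0

    loc = cand["label"].map(reference.per_key["location"]).fillna(reference.fallback_location).to_numpy()
    scl = cand["label"].map(reference.per_key["scale"]).fillna(reference.fallback_scale).to_numpy()
    mx = cand["label"].map(reference.per_key["max_maf"]).fillna(reference.fallback_max_maf).to_numpy()

    s1 = (cand["maf_1"].to_numpy() - loc) / scl
    s2 = (cand["maf_2"].to_numpy() - loc) / scl
    cand["p_1"] = empirical_pvalue(s1, reference.pooled_null)
    cand["p_2"] = empirical_pvalue(s2, reference.pooled_null)
    cand["z_1"] = norm.isf(cand["p_1"])
    cand["z_2"] = norm.isf(cand["p_2"])
    cand["stouffer_z"] = stouffer_combine(
        cand["p_1"], cand["p_2"], cand["total_uids_1"], cand["total_uids_2"],
        reference.weight_mode,
    )
    cand["diff_stat"] = cand["avg_maf"].to_numpy() - mx
    cand["present_in_both_wells"] = True
    return cand


def _apply_thresholds(scored: pd.DataFrame, reference: ControlReference) -> pd.DataFrame:
    if not reference.calibrated:
        raise ValueError("thresholds not calibrated; fit the model first")
    out = scored.copy()
    by_diff = out["diff_stat"] > reference.t_diff
    by_z = out["stouffer_z"] > reference.t_z
    out["positive"] = by_diff | by_z
    crit = np.where(
        by_diff & by_z, "both",
        np.where(by_diff, "difference", np.where(by_z, "stouffer", "none")),
    )
    out["triggering_criterion"] = crit
    return out


def _per_sample_max_z(scored: pd.DataFrame, patient_ids: Iterable[str]) -> pd.Series:
    """Max Stouffer Z per sample over candidate keys; -inf with no candidates."""
    maxima = scored.groupby("patient_id")["stouffer_z"].max() if len(scored) else pd.Series(dtype=float)
    return maxima.reindex(list(patient_ids), fill_value=-np.inf)


def calibrate_thresholds(
    reference: ControlReference,
    control_wbc_obs: pd.DataFrame,
    control_urine_obs: pd.DataFrame,
) -> ControlReference:
    """Set the difference and Stouffer-Z thresholds from control panels.

    ``t_diff`` is the highest MAF observed at any position in any control
    WBC well.  ``t_z`` is calibrated to allow exactly one false positive
    among the control urines: each control urine is scored end-to-end, and
    the threshold is set at the second-largest per-sample maximum Z, with a
    positive call requiring Z strictly greater.
    """
    urine_ids = sorted(control_urine_obs["patient_id"].unique())
    if len(urine_ids) < 2:
        raise ValueError("threshold calibration needs at least two control urines")
    wbc = control_wbc_obs[control_wbc_obs["total_uids"] > 0]
    t_diff = float((wbc["mutant_uids"] / wbc["total_uids"]).max())

    scored = _score_table(control_urine_obs, reference)
    max_z = _per_sample_max_z(scored, urine_ids)
    t_z = float(np.sort(max_z.to_numpy())[-2])
    n_pos = int((max_z > t_z).sum())
    return replace(
        reference,
        t_diff=t_diff,
        t_z=t_z,
        provenance={
            **reference.provenance,
            "n_calibration_urines": len(urine_ids),
            "n_calibration_positives": n_pos,
        },
    )


def call_mutations(patient_obs: pd.DataFrame, reference: ControlReference) -> pd.DataFrame:
    """Score patient observation tables with calibrated thresholds.

    Expects exactly two wells per (patient, assay); returns one row per
    candidate mutation with MAFs, p-values, Stouffer Z, difference statistic,
    the positive flag and the triggering criterion.  Sample-level flags are
    derived by :meth:`MutationCallerResults.call`.
    """
    _check_wells(patient_obs)
    scored = _score_table(patient_obs, reference)
    return _apply_thresholds(scored, reference)


def identity_concordance(
    genotypes_a: Mapping[str, int | None],
    genotypes_b: Mapping[str, int | None],
    min_fraction: float = 0.90,
    min_compared: int = 10,
) -> tuple[float, bool]:
    """Genotype concordance over the identity-check SNP set.

    Compares genotype calls (0/1/2 alternate-allele dosage; None = missing)
    at SNPs present in both inputs, returning the matching fraction over
    positions non-missing in both and a mismatch flag raised when the
    fraction falls below ``min_fraction`` or fewer than ``min_compared``
    positions could be compared.
    """
    shared = set(genotypes_a) & set(genotypes_b)
    if not shared:
        raise ValueError("genotype vectors share no SNPs")
    matches = 0
    compared = 0
    for snp in shared:
        a, b = genotypes_a[snp], genotypes_b[snp]
        if a is None or b is None:
            continue
        compared += 1
        matches += a == b
    fraction = matches / compared if compared else float("nan")
    flag = compared < min_compared or (compared > 0 and fraction < min_fraction)
    return fraction, flag


class MutationCallerModel:
    """Control-calibrated two-criterion mutation caller.

    Parameters
    ----------
    control_wbc_obs : DataFrame
        Control WBC UID-family table (columns as in mutation tables); builds
        the per-mutation reference, the pooled null and the difference
        threshold.
    control_urine_obs : DataFrame
        Control urine table; calibrates the Stouffer-Z threshold so that
        exactly one control urine scores positive.
    panel : Panel, optional
        Queried positions (defaults to the built-in hotspot panel); used to
        warn about panel keys without control coverage.
    weight_mode : {"sqrt", "linear"}
        Stouffer weights as sqrt(UID) (default) or UID.
    """

    def __init__(
        self,
        control_wbc_obs: pd.DataFrame,
        control_urine_obs: pd.DataFrame,
        panel: Panel | None = None,
        min_mutant_families: int = MIN_MUTANT_FAMILIES,
        weight_mode: str = "sqrt",
    ) -> None:
        self.control_wbc_obs = control_wbc_obs
        self.control_urine_obs = control_urine_obs
        self.panel = panel if panel is not None else default_panel()
        self.min_mutant_families = min_mutant_families
        self.weight_mode = weight_mode

    def fit(self) -> "MutationCallerResults":
        reference = build_control_reference(
            self.control_wbc_obs, self.panel, self.min_mutant_families, self.weight_mode
        )
        reference = calibrate_thresholds(reference, self.control_wbc_obs, self.control_urine_obs)
        return MutationCallerResults(self, reference)


class MutationCallerResults:
    """A fitted mutation caller: control reference plus calibrated thresholds."""

    def __init__(self, model: MutationCallerModel, reference: ControlReference) -> None:
        self.model = model
        self.reference = reference

    @property
    def t_diff(self) -> float:
        return self.reference.t_diff

    @property
    def t_z(self) -> float:
        return self.reference.t_z

    def call(self, patient_obs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Score patients; returns (per-mutation calls, per-sample flags).

        Sample flags carry ``multiplex_positive`` / ``tert_positive`` (any
        positive queried position in the assay) for every patient in the
        input, including all-negative ones.
        """
        calls = call_mutations(patient_obs, self.reference)
        patients = pd.Index(sorted(patient_obs["patient_id"].unique()), name="patient_id")
        flags = pd.DataFrame(index=patients)
        for assay in ("multiplex", "tert"):
            sub = calls[(calls["assay"] == assay) & calls["positive"]]
            flags[f"{assay}_positive"] = flags.index.isin(sub["patient_id"])
        return calls, flags

    def summary(self) -> str:
        ref = self.reference
        prov = ref.provenance
        lines = [
            "Mutation caller (control-calibrated, two criteria)",
            f"  panel keys with control reference: {len(ref.per_key)}",
            f"  pooled null size:                  {len(ref.pooled_null)}",
            f"  difference threshold t_diff:       {ref.t_diff:.3e} (max control WBC MAF)",
            f"  Stouffer-Z threshold t_z:          {ref.t_z:.3f} "
            f"(1 positive allowed among {prov.get('n_calibration_urines', '?')} control urines)",
            f"  calibration positives:             {prov.get('n_calibration_positives', '?')}",
            f"  candidate floor:                   >={ref.min_mutant_families} mutant UID families/well",
            f"  Stouffer weights:                  {ref.weight_mode}(UID)",
        ]
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover
        return self.summary()
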