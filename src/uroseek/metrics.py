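"""Cohort-level diagnostic evaluation.

Implements 2x2 tabulation of test calls against clinical truth, the four
standard diagnostic metrics (sensitivity, specificity, PPV, NPV) with
modified-Wald (Agresti-Coull) 95% confidence intervals, lead-time analysis,
urine-tumour mutation concordance, false-negative attribution, and
substitution-spectrum summaries.

The modified Wald interval for x successes in n trials uses

    p~ = (x + z^2/2) / (n + z^2),   half-width = z * sqrt(p~ (1 - p~) / (n + z^2))

with z = 1.96 for a 95% interval, clipped to [0, 1].  An exact
(Clopper-Pearson) mode is available but modified Wald is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "PerformanceSummary",
    "confusion_from_calls",
    "diagnostic_metrics",
    "modified_wald_ci",
    "clopper_pearson_ci",
    "lead_time_months",
    "cohort_lead_times",
    "tumor_urine_concordance",
    "false_negative_attribution",
    "mutation_spectrum",
]

DAYS_PER_MONTH = 30.44

#: The six substitution classes, keyed by the pyrimidine member of the pair.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class ConfusionCounts:
    """A 2x2 table of test calls against truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n


def confusion_from_calls(
    calls: Mapping[str, bool] | pd.Series,
    truth: Mapping[str, bool] | pd.Series,
) -> ConfusionCounts:
    """Tabulate per-patient boolean calls against per-patient truth labels.

    Every patient in ``calls`` must have a truth label; subset filtering
    (cohort, cytology availability) is the caller's job.
    """
    calls = pd.Series(calls)
    truth = pd.Series(truth)
    missing = calls.index.difference(truth.index)
    if len(missing):
        raise ValueError(f"patients without truth labels: {sorted(missing)[:5]}")
    t = truth.loc[calls.index].astype(bool)
    c = calls.astype(bool)
    return ConfusionCounts(
        tp=int((c & t).sum()),
        fp=int((c & ~t).sum()),
        tn=int((~c & ~t).sum()),
        fn=int((~c & t).sum()),
    )


def modified_wald_ci(x: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Modified Wald (Agresti-Coull) 95% CI for a binomial proportion."""
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if n <= 0:
        raise ValueError("n must be positive")
    p_tilde = (x + z * z / 2.0) / (n + z * z)
    half = z * math.sqrt(p_tilde * (1.0 - p_tilde) / (n + z * z))
    return (max(0.0, p_tilde - half), min(1.0, p_tilde + half))


def clopper_pearson_ci(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI; optional alternative to modified Wald."""
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    lower = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
    upper = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    return (float(lower), float(upper))


_CI_METHODS = {"modified_wald": modified_wald_ci, "clopper_pearson": clopper_pearson_ci}


@dataclass
class PerformanceSummary:
    """Point estimates and 95% CIs for the four diagnostic metrics.

    Metrics with a zero denominator are undefined: their point estimate and
    CI are NaN and the metric name appears in ``undefined``.
    """

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ci: dict[str, tuple[float, float]]
    ci_method: str
    undefined: tuple[str, ...] = ()
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            point = getattr(self, name)
            lo, hi = self.ci.get(name, (float("nan"), float("nan")))
            rows.append((name, point, lo, hi))
        df = pd.DataFrame(rows, columns=["metric", "estimate", "ci_lower", "ci_upper"])
        return df.set_index("metric")

    def summary(self) -> str:
        c = self.counts
        head = f"Diagnostic performance{' — ' + self.label if self.label else ''}\n"
        head += f"  n={c.n}  tp={c.tp} fp={c.fp} tn={c.tn} fn={c.fn}  (CI: {self.ci_method})\n"
        lines = []
        for name, row in self.to_frame().iterrows():
            if name in self.undefined:
                lines.append(f"  {name:<12} undefined (zero denominator)")
            else:
                lines.append(
                    f"  {name:<12} {row.estimate * 100:6.1f}%  "
                    f"(95% CI {row.ci_lower * 100:.1f}% to {row.ci_upper * 100:.1f}%)"
                )
        return head + "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover
        return self.summary()


def diagnostic_metrics(
    counts: ConfusionCounts, ci_method: str = "modified_wald", label: str = ""
) -> PerformanceSummary:
    """Sensitivity, specificity, PPV and NPV with 95% CIs from a 2x2 table."""
    if ci_method not in _CI_METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}; choose from {sorted(_CI_METHODS)}")
    ci_fn = _CI_METHODS[ci_method]
    nan = float("nan")
    pairs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
    }
    points: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    undefined: list[str] = []
    for name, (x, n) in pairs.items():
        if n == 0:
            points[name] = nan
            cis[name] = (nan, nan)
            undefined.append(name)
        else:
            points[name] = x / n
            cis[name] = ci_fn(x, n)
    return PerformanceSummary(
        counts=counts,
        sensitivity=points["sensitivity"],
        specificity=points["specificity"],
        ppv=points["ppv"],
        npv=points["npv"],
        ci=cis,
        ci_method=ci_method,
        undefined=tuple(undefined),
        label=label,
    )


def lead_time_months(collection_day: float, diagnosis_day: float) -> float:
    """Months between a positive urine test and subsequent diagnosis.

    Days are converted at 30.44 days/month.  Negative intervals are a data
    error (diagnosis preceding the tested sample).
    """
    delta = diagnosis_day - collection_day
    if delta < 0:
        raise ValueError(f"diagnosis precedes collection by {-delta} days")
    return delta / DAYS_PER_MONTH


def cohort_lead_times(
    truth: pd.DataFrame, positive_ids: Iterable[str]
) -> dict[str, float | int | pd.Series]:
    """Lead times for test-positive cases with a diagnosis date.

    ``truth`` needs columns patient_id, is_cancer, collection_day,
    diagnosis_day.  Returns per-patient lead times (months), their mean, and
    the count exceeding 12 months.
    """
    pos = set(positive_ids)
    sub = truth[truth["is_cancer"] & truth["patient_id"].isin(pos)]
    sub = sub.dropna(subset=["diagnosis_day"])
    leads = pd.Series(
        [lead_time_months(c, d) for c, d in zip(sub["collection_day"], sub["diagnosis_day"])],
        index=sub["patient_id"].to_list(),
        dtype=float,
    )
    return {
        "lead_months": leads,
        "mean_months": float(leads.mean()) if len(leads) else float("nan"),
        "n_over_12_months": int((leads > 12).sum()),
    }


def tumor_urine_concordance(
    urine_calls: Mapping[str, Sequence[str]],
    tumor_mutations: Mapping[str, Sequence[str]],
) -> tuple[pd.Series, float]:
    """Shared-mutation concordance between urine calls and tumour genotypes.

    A patient is concordant when at least one identical mutation key occurs
    in both the urine call set and the tumour set.  The cohort fraction is
    computed over patients with >=1 urine mutation and an available tumour;
    patients without tumour data are excluded (and absent from the returned
    per-patient series).
    """
    flags = {}
    for pid, urine in urine_calls.items():
        if not urine:
            continue
        if pid not in tumor_mutations:
            continue
        tumor = set(tumor_mutations[pid])
        flags[pid] = bool(set(urine) & tumor)
    series = pd.Series(flags, dtype=bool)
    frac = float(series.mean()) if len(series) else float("nan")
    return series, frac


def false_negative_attribution(
    fn_patient_ids: Iterable[str],
    tumor_mutations: Mapping[str, Sequence[str]],
) -> dict[str, float | int]:
    """Attribute urine-negative cancers to one of two failure modes.

    A false negative whose tumour carries >=1 queried mutation failed for
    lack of neoplastic DNA in the urine ("insufficient cells"); one whose
    tumour is wild-type across the panel could never have been detected
    ("no queried mutation").  Fractions sum to 1 over attributable patients.
    """
    ids = list(fn_patient_ids)
    insufficient = 0
    no_mutation = 0
    missing_tumor = 0
    for pid in ids:
        muts = tumor_mutations.get(pid)
        if muts is None:
            missing_tumor += 1
        elif len(muts) > 0:
            insufficient += 1
        else:
            no_mutation += 1
    total = insufficient + no_mutation
    return {
        "n_false_negative": len(ids),
        "n_attributable": total,
        "n_missing_tumor": missing_tumor,
        "n_insufficient_cells": insufficient,
        "n_no_queried_mutation": no_mutation,
        "frac_insufficient_cells": insufficient / total if total else float("nan"),
        "frac_no_queried_mutation": no_mutation / total if total else float("nan"),
    }


def _substitution_class(ref: str, alt: str) -> str | None:
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    if ref in "AG":  # fold onto the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def mutation_spectrum(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene substitution-class counts, including the A:T>T:A fraction.

    ``calls`` needs columns gene, ref, alt (one row per called mutation).
    Returns one row per gene with the six pyrimidine-strand class counts, the
    SNV total, a count of skipped non-SNV records, and ``at_ta_fraction``
    (the A:T>T:A transversion share; A>T mutations fold onto the T>A class).
    """
    records: dict[str, dict[str, int]] = {}
    for _, row in calls.iterrows():
        gene = row["gene"]
        rec = records.setdefault(
            gene, {c: 0 for c in SUBSTITUTION_CLASSES} | {"non_snv": 0}
        )
        cls = _substitution_class(str(row["ref"]), str(row["alt"]))
        if cls is None:
            rec["non_snv"] += 1
        else:
            rec[cls] += 1
    rows = []
    for gene, rec in sorted(records.items()):
        total = sum(rec[c] for c in SUBSTITUTION_CLASSES)
        rows.append(
            {"gene": gene, **rec, "n_snv": total,
             "at_ta_fraction": rec["T>A"] / total if total else float("nan")}
        )
    cols = ["gene", *SUBSTITUTION_CLASSES, "n_snv", "non_snv", "at_ta_fraction"]
    if not rows:
        return pd.DataFrame(columns=cols).set_index("gene")
    return pd.DataFrame(rows, columns=cols).set_index("gene")
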