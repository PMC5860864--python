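"""Combination of the three assay calls, with and without cytology.

The combined test is a logical OR: a positive result in any one of the
multiplex mutation assay, the TERT singleplex assay, or the aneuploidy assay
scores the sample positive.  Cytology integrates the same way, except that
an equivocal ("atypical"/suspicious) cytology reading does not count as
positive, and patients without cytology are excluded from combined-subset
metrics while remaining in the assay-only metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["UroSEEKResult", "combine", "combine_with_cytology", "combine_cohort"]

_CYTOLOGY = ("positive", "atypical", "negative", "unavailable")


def combine(multiplex: bool, tert: bool, aneuploidy: bool) -> bool:
    """OR of the three assay flags; every flag must be an actual boolean."""
    for name, v in (("multiplex", multiplex), ("tert", tert), ("aneuploidy", aneuploidy)):
        if v is None or not isinstance(v, (bool,)):
            raise ValueError(f"missing or non-boolean {name} call: {v!r}")
    return multiplex or tert or aneuploidy


def combine_with_cytology(test_positive: bool, cytology: str) -> bool | None:
    """Combined flag: test OR positive cytology; atypical is non-positive.

    Returns None when cytology is unavailable — such patients belong in the
    assay-only metrics but not in combined-subset metrics.
    """
    if cytology not in _CYTOLOGY:
        raise ValueError(f"unknown cytology category {cytology!r}")
    if cytology == "unavailable":
        return None
    return bool(test_positive) or cytology == "positive"


@dataclass(frozen=True)
class UroSEEKResult:
    """Per-patient combined result."""

    patient_id: str
    multiplex_positive: bool
    tert_positive: bool
    aneuploidy_positive: bool
    cytology: str = "unavailable"

    @property
    def uroseek_positive(self) -> bool:
        return combine(self.multiplex_positive, self.tert_positive, self.aneuploidy_positive)

    @property
    def combined_with_cytology_positive(self) -> bool | None:
        return combine_with_cytology(self.uroseek_positive, self.cytology)


def combine_cohort(
    mutation_flags: pd.DataFrame,
    aneuploidy_flags: pd.DataFrame,
    cytology: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble per-patient combined results for a cohort.

    ``mutation_flags`` carries multiplex_positive/tert_positive (indexed by
    patient), ``aneuploidy_flags`` carries aneuploidy_positive; indices must
    agree.  The returned frame adds uroseek_positive and, when cytology is
    given, the combined-with-cytology flag (NA where unavailable).
    """
    missing = mutation_flags.index.symmetric_difference(aneuploidy_flags.index)
    if len(missing):
        raise ValueError(f"assay results disagree on patients: {sorted(missing)[:5]}")
    out = mutation_flags.copy()
    out["aneuploidy_positive"] = aneuploidy_flags["aneuploidy_positive"].reindex(out.index)
    if out["aneuploidy_positive"].isna().any():
        raise ValueError("aneuploidy call missing for some patients")
    out["uroseek_positive"] = (
        out["multiplex_positive"] | out["tert_positive"] | out["aneuploidy_positive"]
    )
    if cytology is not None:
        cyt = cytology.reindex(out.index).fillna("unavailable")
        out["cytology"] = cyt
        out["combined_with_cytology_positive"] = [
            combine_with_cytology(u, c) for u, c in zip(out["uroseek_positive"], cyt)
        ]
    return out
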