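"""Assay panel definitions: queried mutations, chromosome arms, identity SNPs.

The mutation panel covers selected hotspot positions in ten genes recurrently
mutated in urothelial tumours (the "multiplex" assay) plus the three TERT
promoter hotspots, which are amplified separately (the "tert" assay) because
of the GC-rich promoter context.  All coordinates are hg19, 1-based.

The aneuploidy assay amplifies repeat loci spread over the 39 non-acrocentric
autosomal chromosome arms; :func:`uniform_arm_map` builds an equal-loci-per-arm
map for synthetic work, and real arm maps with uneven locus counts can be
loaded from TSV via :mod:`uroseek.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "MutationKey",
    "Panel",
    "default_panel",
    "NON_ACROCENTRIC_ARMS",
    "uniform_arm_map",
    "TERT_HOTSPOTS",
    "IDENTITY_SNPS",
]

_VALID_ASSAYS = ("multiplex", "tert")

#: TERT promoter hotspots (hg19, chr5), 66/88/80 bp upstream of the TSS.
TERT_HOTSPOTS = ((5, 1295228, "G", "A"), (5, 1295250, "G", "A"), (5, 1295242, "G", "A"))


@dataclass(frozen=True, order=True)
class MutationKey:
    """One queried single-base substitution.

    Attributes
    ----------
    chrom : str
        Chromosome name without "chr" prefix (e.g. "17", "5").
    pos : int
        1-based hg19 coordinate.
    ref, alt : str
        Reference and alternate base; must differ.
    gene : str
        Gene symbol the position belongs to.
    assay : str
        "multiplex" for the ten-gene panel, "tert" for the promoter singleplex.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = field(compare=False, default="")
    assay: str = field(compare=False, default="multiplex")

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.assay not in _VALID_ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.assay == "tert":
            allowed = {(str(c), p) for c, p, _, _ in TERT_HOTSPOTS}
            if (str(self.chrom), self.pos) not in allowed:
                raise ValueError(
                    f"tert assay restricted to TERT promoter hotspots, got {self.chrom}:{self.pos}"
                )

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def from_label(cls, label: str, gene: str = "", assay: str = "multiplex") -> "MutationKey":
        chrom, pos, change = label.split(":")
        ref, alt = change.split(">")
        return cls(chrom, int(pos), ref, alt, gene, assay)


@dataclass(frozen=True)
class Panel:
    """An ordered collection of queried :class:`MutationKey` positions."""

    keys: tuple[MutationKey, ...]

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate keys in panel")

    def __len__(self) -> int:
        return len(self.keys)

    def __iter__(self):
        return iter(self.keys)

    def subset(self, assay: str) -> tuple[MutationKey, ...]:
        return tuple(k for k in self.keys if k.assay == assay)

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for k in self.keys:
            seen.setdefault(k.gene)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [k.chrom for k in self.keys],
                "pos": [k.pos for k in self.keys],
                "ref": [k.ref for k in self.keys],
                "alt": [k.alt for k in self.keys],
                "gene": [k.gene for k in self.keys],
                "assay": [k.assay for k in self.keys],
            }
        )


# Default hotspot panel: representative hg19 hotspot positions in the ten
# multiplex genes.  The exact queried positions of a production panel are
# supplied via a panel spec file; this built-in set carries the gene spectrum
# (TP53-heavy, with A:T>T:A transversion sites in TP53/HRAS) that the cohort
# simulator plants mutations from.
_DEFAULT_MULTIPLEX: tuple[tuple[str, int, str, str, str], ...] = (
    ("17", 7577120, "C", "T", "TP53"),
    ("17", 7577538, "C", "T", "TP53"),
    ("17", 7578406, "C", "T", "TP53"),
    ("17", 7577058, "A", "T", "TP53"),
    ("17", 7578190, "T", "A", "TP53"),
    ("17", 7577094, "G", "A", "TP53"),
    ("4", 1803568, "C", "G", "FGFR3"),
    ("4", 1806099, "A", "G", "FGFR3"),
    ("4", 1808916, "A", "T", "FGFR3"),
    ("4", 1807894, "G", "T", "FGFR3"),
    ("3", 178936082, "G", "A", "PIK3CA"),
    ("3", 178936091, "G", "A", "PIK3CA"),
    ("3", 178952085, "A", "G", "PIK3CA"),
    ("11", 534289, "A", "T", "HRAS"),
    ("11", 533874, "T", "A", "HRAS"),
    ("11", 534286, "C", "A", "HRAS"),
    ("12", 25398284, "C", "T", "KRAS"),
    ("12", 25398281, "C", "A", "KRAS"),
    ("17", 37880220, "T", "C", "ERBB2"),
    ("17", 37879588, "G", "A", "ERBB2"),
    ("9", 21971120, "C", "T", "CDKN2A"),
    ("9", 21971186, "G", "A", "CDKN2A"),
    ("7", 116411990, "T", "C", "MET"),
    ("7", 116412043, "G", "A", "MET"),
    ("3", 10188200, "C", "T", "VHL"),
    ("3", 10191485, "G", "T", "VHL"),
    ("11", 118352430, "C", "T", "KMT2A"),
    ("11", 118373862, "A", "G", "KMT2A"),
)


def default_panel() -> Panel:
    """The built-in 10-gene + TERT hotspot panel used by the simulator."""
    keys = [MutationKey(c, p, r, a, g, "multiplex") for c, p, r, a, g in _DEFAULT_MULTIPLEX]
    keys += [MutationKey(str(c), p, r, a, "TERT", "tert") for c, p, r, a in TERT_HOTSPOTS]
    return Panel(tuple(keys))


def _arms() -> tuple[str, ...]:
    # Autosomes have 44 arms; the five acrocentric p arms (13p, 14p, 15p,
    # 21p, 22p) carry no usable loci, leaving 39.
    acrocentric = {13, 14, 15, 21, 22}
    arms: list[str] = []
    for chrom in range(1, 23):
        if chrom not in acrocentric:
            arms.append(f"{chrom}p")
        arms.append(f"{chrom}q")
    return tuple(arms)


#: The 39 non-acrocentric autosomal chromosome arms, in genomic order.
NON_ACROCENTRIC_ARMS: tuple[str, ...] = _arms()
assert len(NON_ACROCENTRIC_ARMS) == 39


def uniform_arm_map(n_loci: int = 3900) -> pd.DataFrame:
    """Assign ``n_loci`` synthetic loci evenly across the 39 arms.

    Returns a DataFrame with columns ``locus_id``, ``chrom``, ``arm``,
    indexed by ``locus_id``.  ``n_loci`` must be divisible by 39.
    """
    if n_loci % 39 != 0:
        raise ValueError(f"n_loci must be divisible by 39, got {n_loci}")
    per_arm = n_loci // 39
    rows = []
    for arm in NON_ACROCENTRIC_ARMS:
        chrom = arm[:-1]
        for i in range(per_arm):
            rows.append((f"L{arm}_{i:05d}", chrom, arm))
    df = pd.DataFrame(rows, columns=["locus_id", "chrom", "arm"])
    return df.set_index("locus_id", drop=False)


def validate_arm_map(arm_map: pd.DataFrame) -> None:
    """Check the 39-arm contract: exactly 39 arms, >=10 loci each."""
    arms = arm_map["arm"].unique()
    if set(arms) != set(NON_ACROCENTRIC_ARMS):
        missing = set(NON_ACROCENTRIC_ARMS) - set(arms)
        extra = set(arms) - set(NON_ACROCENTRIC_ARMS)
        raise ValueError(f"arm map must cover the 39 arms (missing={sorted(missing)}, extra={sorted(extra)})")
    counts = arm_map["arm"].value_counts()
    thin = counts[counts < 10]
    if len(thin):
        raise ValueError(f"arms with <10 loci: {list(thin.index)}")


def _identity_snps() -> tuple[str, ...]:
    # 31 common SNPs on chromosomes 10 and 20 (26 amplicons; some amplicons
    # cover two SNPs).  Synthetic identifiers; real rs numbers are assay-level
    # configuration.
    snps = [f"snp10_{i:02d}" for i in range(1, 17)] + [f"snp20_{i:02d}" for i in range(1, 16)]
    return tuple(snps)


#: Identity-check SNP identifiers (31 SNPs, chromosomes 10 and 20).
IDENTITY_SNPS: tuple[str, ...] = _identity_snps()
assert len(IDENTITY_SNPS) == 31
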