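"""File formats and configuration.

All tabular interchange is tab-separated text with a header; structured
results (control reference, models, run provenance) are versioned JSON.
Mutation tables use 1-based hg19 positions; panel specs are BED-like
(0-based half-open) and converted on read, so the interval
``[1295227, 1295228)`` covers position g.1295228.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import OBSERVATION_COLUMNS, ControlReference
from .panel import MutationKey, Panel

__all__ = [
    "read_mutation_table",
    "write_mutation_table",
    "read_locus_counts",
    "write_locus_counts",
    "read_arm_map",
    "write_arm_map",
    "read_clinical_sheet",
    "write_clinical_sheet",
    "read_panel_spec",
    "write_panel_spec",
    "save_reference",
    "load_reference",
    "RunConfig",
    "write_provenance",
]

REFERENCE_FORMAT = "uroseek-control-reference"
REFERENCE_VERSION = 1


# ------------------------------------------------------------ mutation tables

def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a UID-family mutation table (TSV).

    Enforces the declared header, non-negative integer counts with
    mutant <= total, wells in {1, 2}, and uniqueness of
    (patient, assay, well, position, ref, alt); failures report the
    offending line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("pos", "well", "mutant_uids", "total_uids"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: line {bad.index[0] + 2}: non-numeric {col}")
        df[col] = df[col].astype(np.int64)
    bad = df[~df["well"].isin((1, 2))]
    if len(bad):
        raise ValueError(f"{path}: line {bad.index[0] + 2}: well must be 1 or 2")
    bad = df[(df["mutant_uids"] < 0) | (df["total_uids"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: line {bad.index[0] + 2}: negative UID count")
    bad = df[df["mutant_uids"] > df["total_uids"]]
    if len(bad):
        raise ValueError(f"{path}: line {bad.index[0] + 2}: mutant_uids > total_uids")
    key_cols = ["patient_id", "assay", "well", "chrom", "pos", "ref", "alt"]
    dup = df[df.duplicated(key_cols)]
    if len(dup):
        raise ValueError(f"{path}: line {dup.index[0] + 2}: duplicate (patient, well, mutation) row")
    return df


def write_mutation_table(df: pd.DataFrame, path: str | Path) -> None:
    df = df[list(OBSERVATION_COLUMNS)]
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- locus counts

def write_locus_counts(counts: pd.DataFrame, arm_map: pd.DataFrame, path: str | Path) -> None:
    """Locus-count matrix: locus_id, chrom, arm, then one column per sample."""
    out = arm_map[["locus_id", "chrom", "arm"]].join(counts)
    out.to_csv(path, sep="\t", index=False)


def read_locus_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (counts: loci x samples, arm_map)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
    for col in ("locus_id", "chrom", "arm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    df = df.set_index("locus_id", drop=False)
    arm_map = df[["locus_id", "chrom", "arm"]]
    counts = df.drop(columns=["locus_id", "chrom", "arm"]).astype(np.int64)
    return counts, arm_map


def write_arm_map(arm_map: pd.DataFrame, path: str | Path) -> None:
    arm_map[["locus_id", "chrom", "arm"]].to_csv(path, sep="\t", index=False)


def read_arm_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
    return df.set_index("locus_id", drop=False)


# -------------------------------------------------------------- clinical sheet

_CLINICAL_COLUMNS = (
    "patient_id", "cohort", "is_cancer", "cytology", "collection_day",
    "diagnosis_day", "grade", "stage",
)


def write_clinical_sheet(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["is_cancer"] = df["is_cancer"].astype(bool)
    return df


# ----------------------------------------------------------------- panel spec

def write_panel_spec(panel: Panel, path: str | Path) -> None:
    """BED-like panel spec: 0-based half-open single-base intervals."""
    rows = [
        {
            "chrom": k.chrom, "start": k.pos - 1, "end": k.pos,
            "ref": k.ref, "alt": k.alt, "gene": k.gene, "assay": k.assay,
        }
        for k in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel_spec(path: str | Path) -> Panel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    keys = []
    for i, row in df.iterrows():
        if row["end"] - row["start"] != 1:
            raise ValueError(f"{path}: line {i + 2}: panel intervals must be single-base")
        keys.append(
            MutationKey(
                str(row["chrom"]), int(row["start"]) + 1, row["ref"], row["alt"],
                row["gene"], row["assay"],
            )
        )
    return Panel(tuple(keys))


# ----------------------------------------------------- reference persistence

def save_reference(reference: ControlReference, path: str | Path) -> None:
    """Persist a (possibly calibrated) control reference as JSON."""
    doc = {
        "format": REFERENCE_FORMAT,
        "version": REFERENCE_VERSION,
        "per_key": {
            "label": reference.per_key.index.to_list(),
            "location": reference.per_key["location"].to_list(),
            "scale": reference.per_key["scale"].to_list(),
            "max_maf": reference.per_key["max_maf"].to_list(),
            "n_obs": [int(v) for v in reference.per_key["n_obs"]],
        },
        "pooled_null": reference.pooled_null.tolist(),
        "fallback_location": reference.fallback_location,
        "fallback_scale": reference.fallback_scale,
        "fallback_max_maf": reference.fallback_max_maf,
        "t_diff": reference.t_diff,
        "t_z": reference.t_z,
        "min_mutant_families": reference.min_mutant_families,
        "weight_mode": reference.weight_mode,
        "provenance": reference.provenance,
    }
    Path(path).write_text(json.dumps(doc))


def load_reference(path: str | Path) -> ControlReference:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != REFERENCE_FORMAT:
        raise ValueError(f"{path} is not a control reference file")
    if doc.get("version") != REFERENCE_VERSION:
        raise ValueError(f"unsupported reference version {doc.get('version')}")
    pk = doc["per_key"]
    per_key = pd.DataFrame(
        {"location": pk["location"], "scale": pk["scale"],
         "max_maf": pk["max_maf"], "n_obs": pk["n_obs"]},
        index=pd.Index(pk["label"], name="label"),
    )
    return ControlReference(
        per_key=per_key,
        pooled_null=np.asarray(doc["pooled_null"], dtype=float),
        fallback_location=doc["fallback_location"],
        fallback_scale=doc["fallback_scale"],
        fallback_max_maf=doc["fallback_max_maf"],
        t_diff=doc["t_diff"],
        t_z=doc["t_z"],
        min_mutant_families=doc["min_mutant_families"],
        weight_mode=doc["weight_mode"],
        provenance=doc.get("provenance", {}),
    )


# ------------------------------------------------------------------- config

_RUNCONFIG_KEYS = {
    "seed", "output_dir", "log_level", "panel_spec", "control_wbc_table",
    "control_urine_table", "patient_table", "arm_map", "locus_counts",
    "clinical_sheet", "simulator", "caller", "aneuploidy", "metrics",
}


@dataclass
class RunConfig:
    """Pipeline run configuration (paths + per-module parameter blocks)."""

    seed: int = 0
    output_dir: str = "uroseek_out"
    log_level: str = "INFO"
    panel_spec: str | None = None
    control_wbc_table: str | None = None
    control_urine_table: str | None = None
    patient_table: str | None = None
    arm_map: str | None = None
    locus_counts: str | None = None
    clinical_sheet: str | None = None
    simulator: dict = field(default_factory=dict)
    caller: dict = field(default_factory=dict)
    aneuploidy: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path, check_paths: bool = True) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if check_paths:
            base = Path(path).parent
            for name in ("panel_spec", "control_wbc_table", "control_urine_table",
                         "patient_table", "arm_map", "locus_counts", "clinical_sheet"):
                p = getattr(cfg, name)
                if p is not None and not (base / p).exists() and not Path(p).exists():
                    raise FileNotFoundError(f"configured path does not exist: {name} = {p}")
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_provenance(path: str | Path, config: RunConfig | None, seed: int, extra: dict | None = None) -> None:
    """Record what produced an output directory: config hash, seed, version."""
    from . import __version__

    doc = {
        "tool": "uroseek",
        "version": __version__,
        "seed": seed,
        "config_digest": config.digest() if config is not None else None,
        **(extra or {}),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
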