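"""Delimited-table dialects, Oxford HAPS/SAMPLE files, and run configuration.

All pipeline tables are UTF-8 comma-delimited text with '.' decimals and
empty fields for missing values. Every file written by the package starts
with '#'-prefixed metadata lines recording the package version, pipeline
stage, and seed, so a run is reproducible byte for byte from its config.

Haplotype panels use the Oxford convention: each HAPS row carries five
leading fields (chrom, snp_id, position, allele_a, allele_b) followed by
2N phased 0/1 allele columns; the SAMPLE file has the two-line header
(column names, then the type row) followed by one row per sample.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FormatError, InputError, SchemaError

__all__ = [
    "PHENOTYPE_COLUMNS", "HLA_COLUMNS", "KIR_COLUMNS", "RESULT_COLUMNS",
    "write_table", "read_table",
    "read_phenotypes", "read_hla_calls", "read_kir_posteriors",
    "write_haps_sample", "read_haps_sample", "haps_allele_frequencies",
    "RunConfig",
]

PHENOTYPE_COLUMNS = (
    "pair_id", "mother_id", "cohort_id", "birth_weight", "sex",
    "gestational_age", "batch",
    "mother_pc1", "mother_pc2", "mother_pc3", "mother_pc4", "mother_pc5",
    "child_pc1", "child_pc2", "child_pc3", "child_pc4", "child_pc5",
)
PHENOTYPE_OPTIONAL = ("year_of_birth", "reported_weights")
HLA_COLUMNS = ("sample_id", "pair_id", "role", "c2_dosage", "quality")
HLA_OPTIONAL = ("allele1", "allele2")
KIR_COLUMNS = ("sample_id", "locus", "state", "posterior")
RESULT_COLUMNS = ("cohort", "model_id", "term", "estimate", "se",
                  "ci_low", "ci_high", "p", "n_used", "note")


def _header(stage: str, seed: Optional[int], config_hash: Optional[str]) -> str:
    parts = [f"kirhla={__version__}", f"stage={stage}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    return "# " + " ".join(parts) + "\n"


def write_table(df: pd.DataFrame, path, stage: str,
                seed: Optional[int] = None, config_hash: Optional[str] = None) -> None:
    """Write a pipeline table with its metadata header line."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header(stage, seed, config_hash))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path, required: Sequence[str] = (),
               optional: Sequence[str] = (), unique_key: Optional[str] = None) -> pd.DataFrame:
    """Read a pipeline table, validating its schema.

    Columns must be a superset of ``required`` and a subset of
    ``required + optional`` (unknown columns are a schema error naming the
    expected dialect). ``unique_key`` enforces key uniqueness.
    """
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    missing = [c for c in required if c not in cols]
    allowed = set(required) | set(optional)
    unknown = [c for c in cols if allowed and c not in allowed]
    if missing or unknown:
        raise SchemaError(
            f"{path}: missing columns {missing}, unknown columns {unknown}; "
            f"expected schema: {list(required)} (+ optional {list(optional)})"
        )
    if unique_key is not None and df[unique_key].duplicated().any():
        dup = df.loc[df[unique_key].duplicated(), unique_key].iloc[0]
        raise SchemaError(f"{path}: duplicated {unique_key} {dup!r}")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    return read_table(path, PHENOTYPE_COLUMNS, PHENOTYPE_OPTIONAL, unique_key="pair_id")


def read_hla_calls(path) -> pd.DataFrame:
    return read_table(path, HLA_COLUMNS, HLA_OPTIONAL)


def read_kir_posteriors(path, tol: float = 1e-6) -> pd.DataFrame:
    """Read a KIR posterior table; posterior rows per sample x locus must
    sum to 1 within ``tol``."""
    df = read_table(path, KIR_COLUMNS)
    sums = df.groupby(["sample_id", "locus"])["posterior"].sum()
    off = sums[(sums - 1.0).abs() > tol]
    if len(off):
        sid, loc = off.index[0]
        raise InputError(
            f"{path}: posteriors for sample {sid!r} locus {loc!r} sum to "
            f"{off.iloc[0]:.8g}, not 1 (tolerance {tol})"
        )
    return df


def read_results(path) -> pd.DataFrame:
    return read_table(path, RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# Oxford HAPS / SAMPLE
# ---------------------------------------------------------------------------

def write_haps_sample(variants: pd.DataFrame, haplotypes: np.ndarray,
                      samples: pd.DataFrame, haps_path, sample_path) -> None:
    """Write an Oxford haplotype panel.

    ``variants`` columns: chrom, snp_id, position, allele_a, allele_b;
    ``haplotypes`` is an (m variants x 2N) 0/1 array; ``samples`` needs
    ID_1, ID_2, missing columns.
    """
    haplotypes = np.asarray(haplotypes, dtype=int)
    if haplotypes.shape[1] != 2 * len(samples):
        raise FormatError(
            f"haplotype columns ({haplotypes.shape[1]}) != 2 x samples ({len(samples)})"
        )
    with Path(haps_path).open("w", encoding="utf-8", newline="\n") as fh:
        for i, v in enumerate(variants.itertuples(index=False)):
            lead = f"{v.chrom} {v.snp_id} {v.position} {v.allele_a} {v.allele_b}"
            fh.write(lead + " " + " ".join(map(str, haplotypes[i])) + "\n")
    with Path(sample_path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in samples.itertuples(index=False):
            fh.write(f"{s.ID_1} {s.ID_2} {s.missing}\n")


def read_haps_sample(haps_path, sample_path) -> Tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Read an Oxford haplotype panel; returns (variants, haplotypes, samples)."""
    rows, haps = [], []
    ncols = None
    with Path(haps_path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 7:
                raise FormatError(f"{haps_path}:{lineno}: fewer than 5+2 fields")
            alleles = fields[5:]
            if ncols is None:
                ncols = len(alleles)
                if ncols % 2:
                    raise FormatError(f"{haps_path}: odd haplotype column count {ncols}")
            elif len(alleles) != ncols:
                raise FormatError(f"{haps_path}:{lineno}: ragged haplotype columns")
            if any(a not in ("0", "1") for a in alleles):
                raise FormatError(f"{haps_path}:{lineno}: non 0/1 haplotype value")
            rows.append({"chrom": fields[0], "snp_id": fields[1],
                         "position": int(fields[2]),
                         "allele_a": fields[3], "allele_b": fields[4]})
            haps.append([int(a) for a in alleles])
    variants = pd.DataFrame(rows)
    hap = np.array(haps, dtype=int) if haps else np.empty((0, ncols or 0), dtype=int)

    with Path(sample_path).open(encoding="utf-8") as fh:
        header = fh.readline().split()
        fh.readline()  # the Oxford type row
        sample_rows = [dict(zip(header, line.split())) for line in fh if line.strip()]
    samples = pd.DataFrame(sample_rows)
    if ncols is not None and len(samples) * 2 != ncols:
        raise FormatError(
            f"sample count {len(samples)} inconsistent with {ncols} haplotype columns"
        )
    return variants, hap, samples


def haps_allele_frequencies(haplotypes: np.ndarray) -> np.ndarray:
    """Frequency of allele_b (coded 1) per variant row."""
    return np.asarray(haplotypes, dtype=float).mean(axis=1)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for a CLI run (documented key-value YAML file)."""

    out_dir: str = "kirhla_out"
    seed: int = 0
    cohort_id: str = "SIM"
    simulation: Dict = field(default_factory=dict)   # SimulationConfig overrides
    kir_accuracy: float = 1.0
    hla_accuracy: float = 1.0
    has_gestational_age: bool = True
    include_year_of_birth: bool = False
    sd_k_override: Optional[int] = None
    model_ids: Tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    power: Dict = field(default_factory=dict)        # PowerGrid overrides
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}; "
                              f"expected {sorted(known)}")
        if "model_ids" in raw:
            raw["model_ids"] = tuple(raw["model_ids"])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:10]
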