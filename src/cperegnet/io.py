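"""Shared domain types and file I/O.

Everything downstream operates on RNA sequences ({A,C,G,U}), labelled
matrices with explicit missingness, and simple tab-separated tables.
Coordinates are 1-based inclusive internally and in TSV output; BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
# IUPAC one-letter nucleotide codes accepted on input (canonicalized to ACGU
# where unambiguous; ambiguity codes are rejected because every scanner
# downstream needs a concrete base).
_ACCEPTED = frozenset("ACGTU")

DEFAULT_SEED = 1729


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class UTRRecord:
    """A single 3' UTR sequence in canonical RNA form."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal characters {sorted(bad)} after canonicalization"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def canonicalize(seq: str, *, where: str = "") -> str:
    """Fold to upper case and map DNA T to RNA U; reject non-ACGTU letters."""
    up = seq.upper()
    bad = set(up) - _ACCEPTED
    if bad:
        raise ParseError(f"{where}: illegal character(s) {sorted(bad)}")
    return up.replace("T", "U")


def read_fasta(path: str | Path) -> list[UTRRecord]:
    """Read a FASTA file into canonical-form :class:`UTRRecord` objects.

    T is mapped to U and case folded to upper; record order is preserved.
    Raises :class:`ParseError` on characters outside IUPAC ACGTU.
    """
    records: list[UTRRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(UTRRecord(rec.id, canonicalize(str(rec.seq), where=f"record {rec.id!r}")))
    return records


def write_fasta(records: Iterable[UTRRecord], path: str | Path, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Sample sheets


@dataclass(frozen=True)
class SampleSheet:
    """Maps sample ids to experimental conditions and replicates."""

    table: pd.DataFrame  # columns: sample_id, condition, replicate[, batch]

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"sample sheet missing columns {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ParseError("duplicate sample_id in sample sheet")
        pairs = self.table[["condition", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise ParseError("duplicate (condition, replicate) pair in sample sheet")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(self, condition: str) -> list[str]:
        sel = self.table[self.table["condition"] == condition]
        return list(sel["sample_id"])

    @classmethod
    def from_conditions(cls, conditions: dict[str, int], prefix: str = "") -> "SampleSheet":
        """Build a sheet from {condition: n_replicates}."""
        rows = [
            {"sample_id": f"{prefix}{cond}_r{i + 1}", "condition": cond, "replicate": i + 1}
            for cond, n in conditions.items()
            for i in range(n)
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrices


def read_matrix(path: str | Path, sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Read a feature x sample TSV; empty cells become NaN (missing != 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate feature id(s) {dups} in {path}")
    if sheet is not None:
        absent = [s for s in sheet.sample_ids if s not in df.columns]
        if absent:
            raise ParseError(f"samples {absent} from sheet absent from matrix header")
        df = df[sheet.sample_ids]
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV; NaN is written as an empty cell."""
    df.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# BED export of motif hits


def write_hits_bed(hits: Sequence, path: str | Path) -> None:
    """Write motif hits (1-based inclusive) as BED6 (0-based half-open).

    ``name`` is the motif class, score 0, strand '+'. Input order preserved.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.record_id}\t{h.start - 1}\t{h.end}\t{h.motif_class}\t0\t+\n"
            )


# ---------------------------------------------------------------------------
# Config


@dataclass
class Config:
    """Pipeline-wide thresholds; every stochastic stage derives from ``seed``."""

    seed: int = DEFAULT_SEED
    # utr_scan
    max_pas_to_end: int = 60
    # rip_targets
    fc_input: float = 4.0
    fc_ni: float = 2.0
    alpha: float = 0.05
    pref_lfc: float = 2.0
    min_total_count: int = 10
    # bioid_calls
    knn_k: int = 10
    max_missing_impute: int = 2
    abundance_pct: float = 25.0
    # phospho
    loc_prob_min: float = 0.75
    pooling: str = "sum"
    # frap
    discard_initial: int = 20
    posthoc: str = "holm"

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if isinstance(value, float) and not math.isfinite(value):
                raise ValueError(f"config field {name} must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(vars(self), fh, sort_keys=False)
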