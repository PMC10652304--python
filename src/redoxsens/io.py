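"""File formats: FASTA sequences, STRING-style edge lists, evidence tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

EVIDENCE_COLUMNS = ["protein_id", "site", "modification", "condition", "replicate", "quantity"]
LFQ_COLUMNS = ["protein_id", "condition", "replicate", "intensity"]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier."""

    protein_id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> Iterator[ProteinRecord]:
    """Iterate protein records from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield ProteinRecord(rec.id, str(rec.seq), rec.description)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read a PTM-evidence CSV (protein_id, site, modification, condition,
    replicate, quantity)."""
    df = pd.read_csv(path)
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence file {path} missing columns: {sorted(missing)}")
    if (df["quantity"] < 0).any():
        raise ValueError("evidence quantities must be non-negative")
    return df[EVIDENCE_COLUMNS + [c for c in df.columns if c not in EVIDENCE_COLUMNS]]


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_lfq(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LFQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"LFQ file {path} missing columns: {sorted(missing)}")
    return df


def write_lfq(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
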