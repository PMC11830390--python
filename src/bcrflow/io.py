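"""Readers and writers for the on-disk formats used across the pipeline.

Internally every coordinate is a 0-based half-open integer; AIRR-style
rearrangement TSVs are exported with 1-based closed coordinates and ``T``/``F``
booleans, following the AIRR rearrangement standard, and converted back on
read.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Columns holding 0-based start positions internally (exported as 1-based).
_START_COLUMNS = (
    "v_sequence_start",
    "v_germline_start",
    "j_sequence_start",
    "j_germline_start",
    "junction_start",
)
_BOOL_COLUMNS = ("productive", "mutated")


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Return ``(record_id, uppercase_sequence)`` pairs from a FASTA file."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, path, "fasta")


def read_fastq(path: str) -> list[tuple[str, str, list[int]]]:
    """Return ``(read_id, sequence, phred_quality)`` triples."""
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        out.append(
            (rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
        )
    return out


def write_fastq(
    reads: Iterable[tuple[str, str, Sequence[int]]], path: str
) -> None:
    records = []
    for read_id, seq, qual in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = list(qual)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def write_airr(df: pd.DataFrame, path: str) -> None:
    """Write a rearrangement table as AIRR-style TSV (1-based closed coords)."""
    out = df.copy()
    for col in _START_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype("Int64") + 1
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda x: "T" if bool(x) else "F")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def read_airr(path: str) -> pd.DataFrame:
    """Read an AIRR-style TSV back into the internal 0-based representation."""
    df = pd.read_csv(path, sep="\t", dtype={"v_call": str, "j_call": str})
    for col in _START_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("Int64") - 1
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map({"T": True, "F": False})
    if "d_call" in df.columns:
        df["d_call"] = df["d_call"].fillna("")
    return df
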