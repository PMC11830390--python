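"""UMI-based read preprocessing: quality filter, per-UMI consensus,
missing-base filter, and exact duplicate collapse.

Reads are single-end amplicons laid out as ``MID (8 nt) + UMI (9 nt) +
primer + payload``; paired-end assembly and primer masking happen upstream
of this package (the simulator emits assembled reads).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import read_fastq


@dataclass
class ReadLayout:
    """Fixed offsets used to parse MID/UMI/payload out of a raw read."""

    mid_length: int = 8
    umi_length: int = 9
    primer_length: int = 20

    @property
    def payload_offset(self) -> int:
        return self.mid_length + self.umi_length + self.primer_length


def parse_reads(
    reads: list[tuple[str, str, list[int]]], layout: ReadLayout | None = None
) -> pd.DataFrame:
    """Split raw reads into (mid, umi, payload, payload quality) columns."""
    layout = layout or ReadLayout()
    rows = []
    for read_id, seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError(f"{read_id}: sequence/quality length mismatch")
        off = layout.payload_offset
        rows.append(
            {
                "read_id": read_id,
                "mid": seq[: layout.mid_length],
                "umi": seq[layout.mid_length : layout.mid_length + layout.umi_length],
                "sequence": seq[off:],
                "quality": qual[off:],
            }
        )
    return pd.DataFrame(rows)


def load_fastq(path: str, layout: ReadLayout | None = None) -> pd.DataFrame:
    return parse_reads(read_fastq(path), layout)


def filter_quality(reads: pd.DataFrame, min_mean_phred: float = 20.0) -> pd.DataFrame:
    """Retain reads whose arithmetic mean Phred score is >= the threshold."""
    for row in reads.itertuples():
        if len(row.quality) != len(row.sequence):
            raise ValueError(f"{row.read_id}: sequence/quality length mismatch")
    means = reads["quality"].map(lambda q: float(np.mean(q)) if len(q) else 0.0)
    return reads[means >= min_mean_phred].reset_index(drop=True)


def _consensus(seqs: list[str], quals: list[list[int]]) -> str:
    """Position-wise plurality base; ties go to the highest summed Phred for
    the tied base, then alphabetically."""
    length = len(seqs[0])
    out = []
    for i in range(length):
        counts: Counter[str] = Counter()
        qsum: dict[str, int] = defaultdict(int)
        for s, q in zip(seqs, quals):
            counts[s[i]] += 1
            qsum[s[i]] += q[i]
        best = sorted(counts, key=lambda b: (-counts[b], -qsum[b], b))[0]
        out.append(best)
    return "".join(out)


def consensus_by_umi(
    reads: pd.DataFrame, min_reads: int = 1
) -> pd.DataFrame:
    """One consensus sequence per (MID, UMI) group.

    Groups whose reads disagree in length are majority-length filtered
    first; read counts of the group are aggregated into ``read_support``.
    ``min_reads`` drops groups with fewer reads (no minimum by default —
    singleton UMIs pass).
    """
    if reads.empty:
        raise ValueError("no reads to build consensus from")
    rows = []
    for (mid, umi), grp in reads.groupby(["mid", "umi"], sort=True):
        if len(grp) < min_reads:
            continue
        lengths = grp["sequence"].str.len()
        major_len = lengths.mode().min()
        grp = grp[lengths == major_len]
        cons = _consensus(grp["sequence"].tolist(), grp["quality"].tolist())
        rows.append(
            {"mid": mid, "umi": umi, "sequence": cons, "read_support": len(grp)}
        )
    return pd.DataFrame(rows)


def discard_gappy(consensus: pd.DataFrame, max_missing: int = 20) -> pd.DataFrame:
    """Drop consensus sequences with more than ``max_missing`` N characters."""
    keep = consensus["sequence"].str.count("N") <= max_missing
    return consensus[keep].reset_index(drop=True)


def collapse_duplicates(consensus: pd.DataFrame) -> pd.DataFrame:
    """Exact-string deduplication per MID; supports are summed.

    Returns unique sequences with ``umi_support`` (number of UMI groups
    collapsed) and ``read_support`` (total reads).
    """
    out = (
        consensus.groupby(["mid", "sequence"], sort=True)
        .agg(umi_support=("umi", "size"), read_support=("read_support", "sum"))
        .reset_index()
    )
    return out


def cross_sample_contamination_report(
    unique: pd.DataFrame, junctions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Report identical sequences appearing under more than one MID.

    This mirrors a contamination assessment between unrelated samples; it is
    a report, not a filter.
    """
    counts = unique.groupby("sequence")["mid"].nunique()
    flagged = counts[counts > 1].index
    return unique[unique["sequence"].isin(flagged)].reset_index(drop=True)


def preprocess_reads(
    reads: pd.DataFrame,
    min_mean_phred: float = 20.0,
    max_missing: int = 20,
    min_reads_per_umi: int = 1,
) -> pd.DataFrame:
    """Full preprocessing chain: quality filter -> UMI consensus ->
    missing-base filter -> duplicate collapse."""
    passed = filter_quality(reads, min_mean_phred)
    cons = consensus_by_umi(passed, min_reads=min_reads_per_umi)
    cons = discard_gappy(cons, max_missing)
    return collapse_duplicates(cons)
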