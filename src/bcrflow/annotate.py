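"""V/J gene assignment, junction extraction, productivity, and masked
germline reconstruction against the bundled stub reference.

V genes are assigned by glocal alignment (the germline must be consumed,
read overhangs are free), J genes by local alignment on the read suffix;
scoring is match +1, mismatch -1, gap open -4, extend -1.  D genes are not
assigned: the downstream statistics are V/J-only and the reconstructed
germline masks the D segment anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Align import PairwiseAligner

from .germline import GermlineGene, GermlineReference
from .sequtils import translate

V_SCORE_FLOOR = 20.0
J_SCORE_FLOOR = 10.0


def _make_aligner(glocal: bool) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    if glocal:
        aligner.mode = "global"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # free end gaps on the read (target); germline ends are penalized
            aligner.open_end_deletion_score = 0
            aligner.extend_end_deletion_score = 0
    else:
        aligner.mode = "local"
    return aligner


_V_ALIGNER = _make_aligner(glocal=True)
_J_ALIGNER = _make_aligner(glocal=False)


@dataclass
class GeneAssignment:
    """Best-scoring germline gene for one read segment."""

    gene: GermlineGene
    score: float
    n_mismatches: int
    identity: float  # matches / aligned germline positions
    read_blocks: list[tuple[int, int]]
    germ_blocks: list[tuple[int, int]]

    @property
    def read_start(self) -> int:
        return self.read_blocks[0][0]

    @property
    def read_end(self) -> int:
        return self.read_blocks[-1][1]

    @property
    def germ_start(self) -> int:
        return self.germ_blocks[0][0]

    @property
    def germ_end(self) -> int:
        return self.germ_blocks[-1][1]

    def germ_to_read(self, germ_pos: int) -> int | None:
        """Map a germline position to the read, None when unaligned."""
        for (rs, re_), (gs, ge) in zip(self.read_blocks, self.germ_blocks):
            if gs <= germ_pos < ge:
                return rs + (germ_pos - gs)
        return None


def _score_candidate(query: str, gene: GermlineGene, segment: str) -> GeneAssignment:
    aligner = _V_ALIGNER if segment == "V" else _J_ALIGNER
    aln = aligner.align(query, gene.sequence)[0]
    read_blocks = [tuple(map(int, b)) for b in aln.aligned[0]]
    germ_blocks = [tuple(map(int, b)) for b in aln.aligned[1]]
    matches = mismatches = 0
    for (rs, re_), (gs, ge) in zip(read_blocks, germ_blocks):
        for r, g in zip(query[rs:re_], gene.sequence[gs:ge]):
            if r == g:
                matches += 1
            else:
                mismatches += 1
    aligned_germ = sum(ge - gs for gs, ge in germ_blocks)
    identity = matches / aligned_germ if aligned_germ else 0.0
    return GeneAssignment(
        gene=gene,
        score=float(aln.score),
        n_mismatches=mismatches,
        identity=identity,
        read_blocks=read_blocks,
        germ_blocks=germ_blocks,
    )


def assign_gene(
    query: str, reference: GermlineReference, segment: str
) -> GeneAssignment | None:
    """Best V or J gene for ``query``; None when no candidate clears the
    score floor (the record is then unassignable).

    Ties on score break to fewest mismatches, then smallest gene name.
    """
    if segment == "V":
        candidates, floor, min_len = reference.v_genes, V_SCORE_FLOOR, 30
    elif segment == "J":
        candidates, floor, min_len = reference.j_genes, J_SCORE_FLOOR, 15
    else:
        raise ValueError("segment must be 'V' or 'J'")
    if len(query) < min_len:
        return None
    best = None
    for gene in sorted(candidates, key=lambda g: g.name):
        result = _score_candidate(query, gene, segment)
        if best is None or (result.score, -result.n_mismatches) > (
            best.score,
            -best.n_mismatches,
        ):
            best = result
    if best is None or best.score < floor:
        return None
    return best


def extract_junction(
    read: str, v: GeneAssignment, j: GeneAssignment, j_offset: int = 0
) -> tuple[str, int, int] | None:
    """Junction (conserved V cysteine codon through conserved J codon,
    inclusive) as ``(junction, start, end)`` in read coordinates.

    Returns None when either conserved codon is not covered by its
    alignment; the record is then non-productive.
    """
    cys_read = v.germ_to_read(v.gene.anchor_start)
    j_anchor_read = j.germ_to_read(j.gene.anchor_start)
    if cys_read is None or j_anchor_read is None:
        return None
    start = cys_read
    end = j_anchor_read + j_offset + 3
    if end > len(read) or end <= start:
        return None
    return read[start:end], start, end


def check_productive(
    junction: str, sequence_alignment: str, frame_offset: int = 0
) -> bool:
    """True iff the junction is in frame, both conserved residues are present
    (C ... W/F), and the translated V-through-J read is stop-free."""
    if not junction or len(junction) % 3:
        return False
    junction_aa = translate(junction)
    if not junction_aa or junction_aa[0] != "C" or junction_aa[-1] not in "WF":
        return False
    aa = translate(sequence_alignment[frame_offset:].replace("-", ""))
    return "*" not in aa


def reconstruct_germline(
    read: str, v: GeneAssignment, j: GeneAssignment, j_offset: int = 0
) -> tuple[str, str, int]:
    """Build aligned (sequence_alignment, germline_alignment, junction_mask_note)
    strings of equal length spanning the V start through the J end.

    The germline carries the assigned V over its aligned span, N-fill across
    the junction interior (D and N/P regions), and the assigned J over its
    span; read insertions appear as ``-`` in the germline and germline
    deletions as ``-`` in the read row.  Returns
    ``(sequence_alignment, germline_alignment, alignment_offset)`` where the
    offset is the read position of the first alignment column.
    """
    cols_seq: list[str] = []
    cols_germ: list[str] = []

    def emit_segment(assign: GeneAssignment, germ_seq: str, read_off: int) -> None:
        prev_r = assign.read_blocks[0][0] + read_off
        prev_g = assign.germ_blocks[0][0]
        for (rs, re_), (gs, ge) in zip(assign.read_blocks, assign.germ_blocks):
            rs, re_ = rs + read_off, re_ + read_off
            # germline deletion (read gap)
            for g in range(prev_g, gs):
                cols_seq.append("-")
                cols_germ.append(germ_seq[g])
            # read insertion (germline gap)
            for r in range(prev_r, rs):
                cols_seq.append(read[r])
                cols_germ.append("-")
            for r, g in zip(range(rs, re_), range(gs, ge)):
                cols_seq.append(read[r])
                cols_germ.append(germ_seq[g])
            prev_r, prev_g = re_, ge

    emit_segment(v, v.gene.sequence, 0)
    v_read_end = v.read_end
    j_read_start = j.read_start + j_offset
    for r in range(v_read_end, j_read_start):
        cols_seq.append(read[r])
        cols_germ.append("N")
    emit_segment(j, j.gene.sequence, j_offset)
    return "".join(cols_seq), "".join(cols_germ), v.read_start


def annotate_sequence(
    read: str, reference: GermlineReference
) -> dict[str, object] | None:
    """Annotate one nucleotide sequence; None when V or J is unassignable."""
    v = assign_gene(read, reference, "V")
    if v is None:
        return None
    j_region_start = v.read_end
    j = assign_gene(read[j_region_start:], reference, "J")
    if j is None:
        return None
    junction_info = extract_junction(read, v, j, j_offset=j_region_start)
    seq_aln, germ_aln, aln_offset = reconstruct_germline(
        read, v, j, j_offset=j_region_start
    )
    # v_identity over the aligned V region up to the junction start (the
    # mutation-count domain): recompute matches below the cysteine codon.
    matches = compared = 0
    for (rs, re_), (gs, ge) in zip(v.read_blocks, v.germ_blocks):
        for r, g in zip(range(rs, re_), range(gs, ge)):
            if g >= v.gene.anchor_start:
                break
            compared += 1
            if read[r] == v.gene.sequence[g]:
                matches += 1
    v_identity = matches / compared if compared else 0.0
    if junction_info is None:
        junction, junction_start, junction_end = "", -1, -1
        productive = False
    else:
        junction, junction_start, junction_end = junction_info
        frame_offset = (3 - v.germ_start % 3) % 3
        productive = check_productive(junction, seq_aln, frame_offset)
    junction_aa = translate(junction) if junction else ""
    return {
        "sequence": read,
        "sequence_alignment": seq_aln,
        "germline_alignment": germ_aln,
        "v_call": v.gene.name,
        "d_call": "",
        "j_call": j.gene.name,
        "v_identity": round(v_identity, 6),
        "junction": junction,
        "junction_aa": junction_aa,
        "junction_length": len(junction),
        "junction_start": junction_start - aln_offset,
        "v_sequence_start": v.read_start,
        "v_germline_start": v.germ_start,
        "j_sequence_start": j.read_start + j_region_start,
        "j_germline_start": j.germ_start,
        "productive": productive,
    }


def annotate_table(
    unique: pd.DataFrame,
    reference: GermlineReference,
    keep_nonproductive: bool = False,
) -> pd.DataFrame:
    """Annotate a table of unique sequences (column ``sequence``).

    Unassignable records are dropped (their count is stored in
    ``df.attrs['n_unassignable']``); non-productive records are excluded
    unless ``keep_nonproductive`` is set
    (``df.attrs['n_nonproductive']``).
    """
    carried = [
        c
        for c in ("sequence_id", "individual_id", "subset", "umi_support", "read_support", "mid")
        if c in unique.columns
    ]
    rows = []
    n_unassignable = 0
    for i, row in enumerate(unique.itertuples(index=False)):
        ann = annotate_sequence(getattr(row, "sequence"), reference)
        if ann is None:
            n_unassignable += 1
            continue
        for c in carried:
            ann[c] = getattr(row, c)
        ann.setdefault("sequence_id", f"S{i + 1:06d}")
        rows.append(ann)
    df = pd.DataFrame(rows)
    n_nonproductive = 0
    if not df.empty and not keep_nonproductive:
        n_nonproductive = int((~df["productive"]).sum())
        df = df[df["productive"]].reset_index(drop=True)
    df.attrs["n_unassignable"] = n_unassignable
    df.attrs["n_nonproductive"] = n_nonproductive
    return df
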