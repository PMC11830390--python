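"""Bundled stub germline gene reference.

The package ships a small fixed set of invented IGHV/IGHD/IGHJ genes with
realistic lengths and family structure (the analysis logic is
reference-agnostic, so no external database is required).  V genes carry
half-open framework/CDR region intervals tiling the sequence up to the
conserved cysteine codon; J genes carry the position of the conserved
tryptophan/phenylalanine codon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .io import read_fasta, write_fasta
from .sequtils import CODON_TABLE

V_REGION_NAMES = ("fr1", "cdr1", "fr2", "cdr2", "fr3")

_NAME_RE = re.compile(r"^IGH([VDJ])(\d+)")


def family_of(gene_name: str) -> str:
    """Family label of an IGH gene name, e.g. ``IGHV3-64*01`` -> ``IGHV3``."""
    m = _NAME_RE.match(gene_name)
    if m is None:
        raise ValueError(f"unparseable IGH gene name: {gene_name!r}")
    return f"IGH{m.group(1)}{m.group(2)}"


def gene_of(call: str) -> str:
    """Collapse an allele-level call to gene level (``IGHV3-S1*01`` -> ``IGHV3-S1``)."""
    if not call:
        return call
    return call.split("*")[0]


@dataclass(frozen=True)
class GermlineGene:
    """One reference V, D, or J allele.

    ``regions`` (V only) maps FR1/CDR1/FR2/CDR2/FR3 to 0-based half-open
    intervals tiling ``[0, anchor_start)``.  ``anchor_start`` is the start of
    the conserved cysteine codon (V) or tryptophan/phenylalanine codon (J).
    """

    name: str
    segment_type: str  # "V", "D" or "J"
    sequence: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    anchor_start: int = -1

    @property
    def family(self) -> str:
        return family_of(self.name)

    def anchor_codon(self) -> str:
        return self.sequence[self.anchor_start : self.anchor_start + 3]


class GermlineReference:
    """A validated collection of germline genes."""

    def __init__(self, genes: list[GermlineGene]):
        self.genes = {g.name: g for g in genes}
        self._validate()

    def _validate(self) -> None:
        for g in self.genes.values():
            if not g.sequence or set(g.sequence) - set("ACGT"):
                raise ValueError(f"{g.name}: sequence contains non-ACGT characters")
            if g.segment_type not in "VDJ":
                raise ValueError(f"{g.name}: bad segment type {g.segment_type}")
            family_of(g.name)  # raises when unparseable
            if g.segment_type == "V":
                if g.anchor_start < 0 or g.anchor_start + 3 > len(g.sequence):
                    raise ValueError(f"{g.name}: cysteine codon outside sequence")
                if CODON_TABLE.get(g.anchor_codon()) != "C":
                    raise ValueError(f"{g.name}: anchor codon is not cysteine")
                pos = 0
                for rname in V_REGION_NAMES:
                    if rname not in g.regions:
                        raise ValueError(f"{g.name}: missing region {rname}")
                    start, end = g.regions[rname]
                    if start != pos or end <= start:
                        raise ValueError(
                            f"{g.name}: region {rname} does not tile the V sequence"
                        )
                    pos = end
                if pos != g.anchor_start:
                    raise ValueError(
                        f"{g.name}: regions do not reach the cysteine codon"
                    )
                if g.anchor_start + 3 > len(g.sequence):
                    raise ValueError(f"{g.name}: region beyond sequence length")
            elif g.segment_type == "J":
                if g.anchor_start < 0 or g.anchor_start + 3 > len(g.sequence):
                    raise ValueError(f"{g.name}: conserved codon outside sequence")
                if CODON_TABLE.get(g.anchor_codon()) not in ("W", "F"):
                    raise ValueError(f"{g.name}: anchor codon is not W or F")

    # -- accessors ---------------------------------------------------------
    def by_segment(self, segment_type: str) -> list[GermlineGene]:
        return [g for g in self.genes.values() if g.segment_type == segment_type]

    @property
    def v_genes(self) -> list[GermlineGene]:
        return self.by_segment("V")

    @property
    def d_genes(self) -> list[GermlineGene]:
        return self.by_segment("D")

    @property
    def j_genes(self) -> list[GermlineGene]:
        return self.by_segment("J")

    def families(self, segment_type: str | None = None) -> set[str]:
        genes = self.genes.values()
        if segment_type:
            genes = [g for g in genes if g.segment_type == segment_type]
        return {g.family for g in genes}

    def __getitem__(self, name: str) -> GermlineGene:
        # Accept gene-level (allele-collapsed) lookups as well.
        if name in self.genes:
            return self.genes[name]
        for g in self.genes.values():
            if gene_of(g.name) == gene_of(name):
                return g
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.genes)

    # -- persistence -------------------------------------------------------
    def write(self, fasta_path: str, regions_path: str) -> None:
        """Write FASTA + sidecar region table (0-based half-open coords)."""
        write_fasta(
            [(g.name, g.sequence) for g in sorted(self.genes.values(), key=lambda g: g.name)],
            fasta_path,
        )
        rows = []
        for g in sorted(self.genes.values(), key=lambda g: g.name):
            row: dict[str, object] = {
                "gene": g.name,
                "segment_type": g.segment_type,
                "family": g.family,
                "anchor_start": g.anchor_start if g.anchor_start >= 0 else "",
            }
            for rname in V_REGION_NAMES:
                if rname in g.regions:
                    row[f"{rname}_start"], row[f"{rname}_end"] = g.regions[rname]
                else:
                    row[f"{rname}_start"] = row[f"{rname}_end"] = ""
            rows.append(row)
        pd.DataFrame(rows).to_csv(regions_path, sep="\t", index=False)


def load_reference(
    fasta_path: str | None = None, regions_path: str | None = None
) -> GermlineReference:
    """Load a germline reference; with no arguments, the bundled stub set."""
    if fasta_path is None:
        data = resources.files("bcrflow") / "data"
        fasta_path = str(data / "stub_reference.fasta")
        regions_path = str(data / "stub_reference_regions.tsv")
    if regions_path is None:
        raise ValueError("a region-annotation table is required alongside the FASTA")
    try:
        seqs = dict(read_fasta(fasta_path))
    except ValueError as exc:  # Biopython names the offending record
        raise ValueError(f"malformed FASTA {fasta_path}: {exc}") from exc
    table = pd.read_csv(regions_path, sep="\t")
    genes = []
    for _, row in table.iterrows():
        name = row["gene"]
        if name not in seqs:
            raise ValueError(f"region table names {name} absent from FASTA")
        regions = {}
        if row["segment_type"] == "V":
            for rname in V_REGION_NAMES:
                start, end = int(row[f"{rname}_start"]), int(row[f"{rname}_end"])
                if end > len(seqs[name]):
                    raise ValueError(
                        f"{name}: region {rname} end {end} beyond sequence length"
                    )
                regions[rname] = (start, end)
        anchor = row["anchor_start"]
        anchor_start = int(anchor) if pd.notna(anchor) and anchor != "" else -1
        genes.append(
            GermlineGene(
                name=name,
                segment_type=row["segment_type"],
                sequence=seqs[name],
                regions=regions,
                anchor_start=anchor_start,
            )
        )
    missing = set(seqs) - {g.name for g in genes}
    if missing:
        raise ValueError(f"FASTA records missing from region table: {sorted(missing)}")
    return GermlineReference(genes)
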