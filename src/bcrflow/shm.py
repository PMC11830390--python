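"""Somatic hypermutation profiling.

Mutations are substitutions of the observed sequence against the masked
germline, counted over aligned V positions strictly before the junction
start (masked Ns and alignment gaps are skipped in both numerator and
denominator).  Units of analysis are clones and singletons: each clone
contributes the arithmetic mean over its members, so large clones do not
dominate per-subset summaries.  Replacement/silent status of CDR1+CDR2
substitutions is evaluated codon-by-codon against the germline codon with
only the observed substitution applied (one at a time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .clonal import CloneSet
from .germline import GermlineReference
from .sequtils import CODON_TABLE

MUTATED_THRESHOLD = 2  # > 2 mutations => mutated (absolute count, not rate)

_VALID = frozenset("ACGT")


def count_v_mutations(
    sequence_alignment: str, germline_alignment: str, junction_start: int
) -> tuple[int, int]:
    """``(mismatches, compared_positions)`` over V positions before the
    junction, skipping masked (N) and gap positions."""
    if len(sequence_alignment) != len(germline_alignment):
        raise ValueError("alignment strings differ in length")
    count = compared = 0
    stop = min(junction_start, len(sequence_alignment))
    for s, g in zip(sequence_alignment[:stop], germline_alignment[:stop]):
        if s not in _VALID or g not in _VALID:
            continue
        compared += 1
        if s != g:
            count += 1
    if compared == 0:
        raise ValueError("no comparable V positions before the junction")
    return count, compared


def classify_mutated(count_or_mean: float) -> str:
    """<=2 mutations (or clone-mean <=2) => unmutated; >2 => mutated."""
    return "mutated" if count_or_mean > MUTATED_THRESHOLD else "unmutated"


def is_replacement(germline_codon: str, offset: int, new_base: str) -> bool:
    """One-at-a-time R/S call: substitute ``new_base`` at ``offset`` within
    the germline codon and compare amino acids."""
    mutated = germline_codon[:offset] + new_base + germline_codon[offset + 1 :]
    return CODON_TABLE.get(germline_codon) != CODON_TABLE.get(mutated)


def _cdr_intervals_in_alignment(
    v_call: str, v_germline_start: int, reference: GermlineReference
) -> list[tuple[int, int]]:
    """CDR1/CDR2 intervals mapped into alignment coordinates (alignment
    column 0 corresponds to germline position ``v_germline_start``)."""
    gene = reference[v_call]
    out = []
    for rname in ("cdr1", "cdr2"):
        start, end = gene.regions[rname]
        out.append((start - v_germline_start, end - v_germline_start))
    return out


def rs_counts(
    sequence_alignment: str,
    germline_alignment: str,
    v_call: str,
    reference: GermlineReference,
    v_germline_start: int = 0,
) -> tuple[int, int]:
    """Replacement and silent substitution counts within CDR1+CDR2.

    Codons are anchored on the germline reading frame; codons containing
    gaps or Ns are skipped.
    """
    frame_shift = v_germline_start % 3
    r = s = 0
    for lo, hi in _cdr_intervals_in_alignment(v_call, v_germline_start, reference):
        for pos in range(max(lo, 0), min(hi, len(sequence_alignment))):
            sb, gb = sequence_alignment[pos], germline_alignment[pos]
            if sb not in _VALID or gb not in _VALID or sb == gb:
                continue
            codon_start = pos - (pos + frame_shift) % 3
            codon = germline_alignment[codon_start : codon_start + 3]
            if len(codon) < 3 or any(c not in _VALID for c in codon):
                continue
            if is_replacement(codon, pos - codon_start, sb):
                r += 1
            else:
                s += 1
    return r, s


def add_mutation_columns(
    records: pd.DataFrame, reference: GermlineReference
) -> pd.DataFrame:
    """Add per-record mu_count, mu_freq, r_cdr, s_cdr columns."""
    counts, freqs, rs_r, rs_s = [], [], [], []
    for row in records.itertuples():
        count, compared = count_v_mutations(
            row.sequence_alignment, row.germline_alignment, row.junction_start
        )
        v_germ_start = int(getattr(row, "v_germline_start", 0) or 0)
        r, s = rs_counts(
            row.sequence_alignment,
            row.germline_alignment,
            row.v_call,
            reference,
            v_germ_start,
        )
        counts.append(count)
        freqs.append(count / compared)
        rs_r.append(r)
        rs_s.append(s)
    out = records.copy()
    out["mu_count"] = counts
    out["mu_freq"] = freqs
    out["r_cdr"] = rs_r
    out["s_cdr"] = rs_s
    return out


def clone_unit_table(records: pd.DataFrame) -> pd.DataFrame:
    """One row per clone/singleton unit: clone-mean mutation count and
    frequency, summed CDR R and S counts, subset spectrum, mutated flag."""
    required = {"clone_id", "mu_count", "mu_freq"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    units = (
        records.groupby(["individual_id", "subset", "clone_id"], sort=True)
        .agg(
            size=("sequence_id", "size"),
            mean_count=("mu_count", "mean"),
            mean_freq=("mu_freq", "mean"),
            r_cdr=("r_cdr", "sum"),
            s_cdr=("s_cdr", "sum"),
        )
        .reset_index()
    )
    units["mutated"] = units["mean_count"] > MUTATED_THRESHOLD
    return units


def subset_mutation_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per individual x subset: mean unit mutation frequency (each clone
    contributes its member mean once, singletons their own value), the mean
    frequency restricted to mutated units, and the percent of units
    mutated."""
    units = clone_unit_table(records)
    rows = []
    for (individual, subset), grp in units.groupby(
        ["individual_id", "subset"], sort=True
    ):
        mutated = grp[grp["mutated"]]
        rows.append(
            {
                "individual_id": individual,
                "subset": subset,
                "n_units": len(grp),
                "mean_freq_all_units": grp["mean_freq"].mean(),
                "mean_freq_mutated_units": (
                    mutated["mean_freq"].mean() if len(mutated) else np.nan
                ),
                "percent_mutated": 100.0 * grp["mutated"].mean(),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RsRatioSummary:
    per_individual: pd.DataFrame  # individual x subset mean unit R:S ratio
    n_excluded_zero_silent: int  # mutated units with S = 0 (ratio undefined)


def rs_ratio(records: pd.DataFrame) -> RsRatioSummary:
    """CDR1+CDR2 replacement:silent ratio over mutated units only.

    The ratio is formed per unit (clone or singleton, summed member counts)
    and averaged per individual and subset; units with zero silent
    mutations are excluded and counted.
    """
    units = clone_unit_table(records)
    units = units[units["mutated"]].copy()
    excluded = int((units["s_cdr"] == 0).sum())
    units = units[units["s_cdr"] > 0]
    units["rs_ratio"] = units["r_cdr"] / units["s_cdr"]
    summary = (
        units.groupby(["individual_id", "subset"], sort=True)["rs_ratio"]
        .mean()
        .reset_index()
    )
    return RsRatioSummary(per_individual=summary, n_excluded_zero_silent=excluded)


@dataclass
class SharedMutationComparison:
    per_individual: pd.DataFrame
    statistic: float | None
    p_value: float | None
    n_individuals: int
    skipped: list[str]  # individuals without both categories, with reasons


def shared_vs_nonshared_mutation(
    records: pd.DataFrame,
    clone_sets: dict[str, CloneSet],
    subset_x: str,
    subset_y: str,
) -> SharedMutationComparison:
    """Compare clone-level mutation frequency of subset-X units shared with
    subset Y against non-shared units (singletons included) per individual,
    with a Wilcoxon signed-rank test across individuals.

    Expects full-data (not subsampled) clone assignments, with
    ``records['clone_id']`` consistent with ``clone_sets``.
    """
    units = clone_unit_table(records)
    rows = []
    skipped: list[str] = []
    for individual, clone_set in sorted(clone_sets.items()):
        shared_ids = {
            c.clone_id
            for c in clone_set.clones
            if subset_x in c.subsets and subset_y in c.subsets
        }
        sub = units[
            (units["individual_id"] == individual) & (units["subset"] == subset_x)
        ]
        shared = sub[sub["clone_id"].isin(shared_ids)]
        nonshared = sub[~sub["clone_id"].isin(shared_ids)]
        if shared.empty or nonshared.empty:
            skipped.append(f"{individual}: no shared clones for {subset_x}/{subset_y}")
            continue
        rows.append(
            {
                "individual_id": individual,
                "subset": subset_x,
                "shared_with": subset_y,
                "mean_freq_shared": shared["mean_freq"].mean(),
                "mean_freq_nonshared": nonshared["mean_freq"].mean(),
                "n_shared_units": len(shared),
                "n_nonshared_units": len(nonshared),
            }
        )
    table = pd.DataFrame(rows)
    stat = p = None
    if len(table) >= 2:
        diffs = table["mean_freq_shared"] - table["mean_freq_nonshared"]
        if (diffs != 0).any():
            res = wilcoxon(
                table["mean_freq_shared"], table["mean_freq_nonshared"]
            )
            stat, p = float(res.statistic), float(res.pvalue)
    return SharedMutationComparison(
        per_individual=table,
        statistic=stat,
        p_value=p,
        n_individuals=len(table),
        skipped=skipped,
    )
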