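"""Ground-truthed synthetic repertoire generator.

Generates cohorts of individuals x sorted B-cell subsets with the statistical
structure the downstream analysis assumes: per-subset clone-size
distributions (singleton-dominated in CD27-CD21lo, highly clonal in
plasmablasts), per-subset somatic-hypermutation loads, clonal sharing across
subsets within an individual, and optionally UMI-tagged reads with
sequencing error.  Every simulated cell is recorded in a truth ledger
(individual, subset, true clone id, naive sequence, implanted mutations),
so each downstream stage can be tested against ground truth.

Default profile values encode the study conditions the analysis targets:
3195 cells per subset (the uniform subsample depth), clonal fractions of
roughly 0.50 / 0.85 / 0.95 for CD27-CD21lo / CD27+CD21lo / plasmablasts,
unmutated fractions 0.6 / 0.15 / 0.09, and mutated-cell V mutation rates of
4.3% / 5.9% / 7.3%.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .germline import GermlineGene, GermlineReference
from .sequtils import CODON_TABLE, NUCLEOTIDES, STOP_CODONS, has_stop, translate

SUBSETS = ("CD27neg_CD21lo", "CD27pos_CD21lo", "PB", "total_B")
# Developmental ordering used for extra mutations in shared clones.
_SUBSET_RANK = {"CD27neg_CD21lo": 0, "CD27pos_CD21lo": 1, "PB": 2, "total_B": 0}

MAX_REARRANGEMENT_ATTEMPTS = 200


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic 31-bit child seed for a named pipeline stage."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass
class SubsetProfile:
    """Generative parameters for one sorted B-cell subset.

    ``singleton_fraction`` is the expected fraction of cells that are the
    sole member of their clone; the rest fall into clones of size >= 2 drawn
    from a truncated power law with exponent ``clone_size_exponent`` and
    maximum ``clone_size_max``.  ``mutation_rate`` is the expected per-base
    V-segment SHM rate of *mutated* cells; ``fraction_unmutated`` the
    proportion of clonal units carrying <=2 mutations.
    """

    subset_name: str
    n_cells: int = 3195
    singleton_fraction: float = 0.5
    clone_size_exponent: float = 2.5
    clone_size_max: int = 20
    mutation_rate: float = 0.043
    fraction_unmutated: float = 0.6
    junction_shm_rate: float = 0.8  # mean junction substitutions per mutated member
    cdr_weight: float = 1.0  # positional CDR enrichment multiplier
    cdr_replacement_bias: float = 1.0  # replacement bias for CDR substitutions

    def __post_init__(self) -> None:
        if not 0 <= self.singleton_fraction <= 1:
            raise ValueError("singleton_fraction must be in [0, 1]")
        if not 0 <= self.mutation_rate <= 0.2:
            raise ValueError("mutation_rate must be in [0, 0.2]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


DEFAULT_PROFILES: dict[str, SubsetProfile] = {
    "CD27neg_CD21lo": SubsetProfile(
        "CD27neg_CD21lo",
        singleton_fraction=0.50,
        clone_size_exponent=2.5,
        clone_size_max=20,
        mutation_rate=0.043,
        fraction_unmutated=0.60,
        cdr_replacement_bias=1.2,
    ),
    "CD27pos_CD21lo": SubsetProfile(
        "CD27pos_CD21lo",
        singleton_fraction=0.15,
        clone_size_exponent=2.0,
        clone_size_max=60,
        mutation_rate=0.059,
        fraction_unmutated=0.15,
        cdr_replacement_bias=2.5,
    ),
    "PB": SubsetProfile(
        "PB",
        singleton_fraction=0.05,
        clone_size_exponent=1.6,
        clone_size_max=120,
        mutation_rate=0.073,
        fraction_unmutated=0.09,
        cdr_replacement_bias=2.5,
    ),
    "total_B": SubsetProfile(
        "total_B",
        singleton_fraction=0.70,
        clone_size_exponent=2.5,
        clone_size_max=20,
        mutation_rate=0.050,
        fraction_unmutated=0.70,
        cdr_replacement_bias=1.5,
    ),
}


@dataclass
class SharingPlan:
    """Within-individual clone sharing between the three sorted subsets.

    Pairwise counts include the triple-shared clones; defaults follow the
    healthy-control medians of the targeted study design (44 / 4 / 8 shared
    clones, with a handful present in all three subsets).
    """

    neg_pos: int = 44
    neg_pb: int = 4
    pos_pb: int = 8
    n_triple_shared: int = 3
    # Triple-shared clones are given at least this many members per subset so
    # that some exceed the >20-member lineage-tree eligibility rule.
    triple_min_size: int = 8

    def __post_init__(self) -> None:
        if min(self.neg_pos, self.neg_pb, self.pos_pb, self.n_triple_shared) < 0:
            raise ValueError("sharing counts must be >= 0")
        if self.n_triple_shared > min(self.neg_pos, self.neg_pb, self.pos_pb):
            raise ValueError("triple-shared count exceeds a pairwise count")

    def exact_pair_counts(self) -> dict[tuple[str, str], int]:
        t = self.n_triple_shared
        return {
            ("CD27neg_CD21lo", "CD27pos_CD21lo"): self.neg_pos - t,
            ("CD27neg_CD21lo", "PB"): self.neg_pb - t,
            ("CD27pos_CD21lo", "PB"): self.pos_pb - t,
        }


@dataclass
class ReadEmissionConfig:
    """Read-level emission model for UMI-tagged single-end amplicons."""

    umi_length: int = 9
    mid_length: int = 8
    primer: str = "ACGGTCTGAGTTCCACGACA"
    reads_per_molecule_mean: float = 5.0  # Poisson mean, floored at 1
    reads_per_molecule_fixed: int | None = None
    error_rate: float = 0.0
    phred_mean: float = 36.0
    phred_sd: float = 3.0
    # Miscalled bases receive low confidence, as real base-callers do; the
    # consensus tie-break is quality-aware and relies on this anticorrelation.
    error_phred_mean: float = 12.0
    error_phred_sd: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must be in [0, 0.1]")


@dataclass
class Rearrangement:
    """One naive (pre-SHM) productive VDJ rearrangement."""

    sequence: str
    v_call: str
    d_call: str
    j_call: str
    junction_start: int
    junction_end: int  # half-open
    np1_length: int
    np2_length: int

    @property
    def junction(self) -> str:
        return self.sequence[self.junction_start : self.junction_end]


@dataclass
class Mutation:
    position: int  # 0-based in the rearranged sequence
    from_base: str
    to_base: str
    region: str  # fr1/cdr1/fr2/cdr2/fr3
    is_replacement: bool


# ---------------------------------------------------------------------------
# rearrangement and SHM primitives
# ---------------------------------------------------------------------------


def simulate_rearrangement(
    reference: GermlineReference,
    rng_seed: int | np.random.Generator,
    force_np_lengths: tuple[int, int] | None = None,
) -> Rearrangement:
    """Draw one productive V(D)J rearrangement from the reference.

    The junction runs from the conserved V cysteine codon through the
    conserved J codon inclusive and is always a multiple of 3; the full
    sequence is stop-free in the V reading frame.  Resamples internally and
    raises after a bounded number of attempts.
    """
    rng = _as_rng(rng_seed)
    vs, ds, js = reference.v_genes, reference.d_genes, reference.j_genes
    for _ in range(MAX_REARRANGEMENT_ATTEMPTS):
        v = vs[rng.integers(len(vs))]
        d = ds[rng.integers(len(ds))]
        j = js[rng.integers(len(js))]
        if force_np_lengths is not None:
            n1, n2 = force_np_lengths
        else:
            n1 = int(rng.poisson(4))
            n2 = int(rng.poisson(4))
        # Pad n2 so the junction length is a multiple of 3.
        v_tail = len(v.sequence) - v.anchor_start
        jl = v_tail + n1 + len(d.sequence) + n2 + j.anchor_start + 3
        if force_np_lengths is None:
            n2 += (-jl) % 3
        elif jl % 3:
            continue  # resample a frame-compatible V/D/J combination
        np1 = "".join(rng.choice(list(NUCLEOTIDES), n1)) if n1 else ""
        np2 = "".join(rng.choice(list(NUCLEOTIDES), n2)) if n2 else ""
        seq = v.sequence + np1 + d.sequence + np2 + j.sequence
        junction_start = v.anchor_start
        junction_end = (
            len(v.sequence) + n1 + len(d.sequence) + n2 + j.anchor_start + 3
        )
        if (junction_end - junction_start) % 3:
            continue
        if has_stop(seq):
            continue
        return Rearrangement(
            sequence=seq,
            v_call=v.name,
            d_call=d.name,
            j_call=j.name,
            junction_start=junction_start,
            junction_end=junction_end,
            np1_length=n1,
            np2_length=n2,
        )
    raise RuntimeError("failed to draw a productive rearrangement")


def masked_germline(rearr: Rearrangement, reference: GermlineReference) -> str:
    """Germline with the D segment and N/P additions masked with Ns.

    The V and J segments are retained over their full spans (so the
    conserved-codon anchors stay unmasked); everything between them is N.
    """
    v = reference[rearr.v_call]
    j = reference[rearr.j_call]
    n_fill = len(rearr.sequence) - len(v.sequence) - len(j.sequence)
    return v.sequence + "N" * n_fill + j.sequence


def _region_at(v_gene: GermlineGene, position: int) -> str:
    for rname, (start, end) in v_gene.regions.items():
        if start <= position < end:
            return rname
    return "cdr3" if position >= v_gene.anchor_start else "unknown"


def _classify_substitution(naive: str, pos: int, new_base: str) -> bool:
    """True when the substitution changes the amino acid (replacement)."""
    codon_start = pos - pos % 3
    codon = naive[codon_start : codon_start + 3]
    mutated = codon[: pos - codon_start] + new_base + codon[pos - codon_start + 1 :]
    return CODON_TABLE.get(codon) != CODON_TABLE.get(mutated)


def implant_shm(
    naive: str,
    n_mutations: int,
    v_gene: GermlineGene,
    rng_seed: int | np.random.Generator,
    forbidden: set[int] | None = None,
    cdr_weight: float = 1.0,
    cdr_replacement_bias: float = 1.0,
    avoid_stop: bool = True,
) -> tuple[str, list[Mutation]]:
    """Implant exactly ``n_mutations`` substitutions in the V segment.

    Positions are drawn without replacement from ``[0, cysteine codon)``
    (uniformly, or CDR-weighted when ``cdr_weight > 1``), excluding
    ``forbidden`` positions.  Each mutation is recorded with its region and
    replacement/silent status relative to the naive codon; when
    ``avoid_stop`` is set, substitutions creating an in-frame stop codon are
    resampled so productive molecules stay productive.
    """
    rng = _as_rng(rng_seed)
    mutable = np.array(
        sorted(set(range(v_gene.anchor_start)) - (forbidden or set()))
    )
    if n_mutations > len(mutable):
        raise ValueError(
            f"n_mutations={n_mutations} exceeds {len(mutable)} mutable positions"
        )
    if n_mutations == 0:
        return naive, []
    weights = np.ones(len(mutable))
    if cdr_weight != 1.0:
        for rname in ("cdr1", "cdr2"):
            start, end = v_gene.regions[rname]
            weights[(mutable >= start) & (mutable < end)] = cdr_weight
    weights /= weights.sum()
    positions = rng.choice(mutable, size=n_mutations, replace=False, p=weights)
    seq = list(naive)
    mutations = []
    for pos in sorted(int(p) for p in positions):
        region = _region_at(v_gene, pos)
        in_cdr = region in ("cdr1", "cdr2")
        alternatives = [b for b in NUCLEOTIDES if b != naive[pos]]
        w = np.ones(3)
        if in_cdr and cdr_replacement_bias != 1.0:
            for i, b in enumerate(alternatives):
                if _classify_substitution(naive, pos, b):
                    w[i] = cdr_replacement_bias
        order = list(rng.permutation(3))
        order.sort(key=lambda i: -w[i] * rng.random())
        chosen = None
        for i in order:
            new = alternatives[i]
            seq[pos] = new
            codon_start = pos - pos % 3
            codon = "".join(seq[codon_start : codon_start + 3])
            if avoid_stop and codon in STOP_CODONS:
                seq[pos] = naive[pos]
                continue
            chosen = new
            break
        if chosen is None:  # every alternative creates a stop; leave unmutated
            continue
        mutations.append(
            Mutation(
                position=pos,
                from_base=naive[pos],
                to_base=chosen,
                region=region,
                is_replacement=_classify_substitution(naive, pos, chosen),
            )
        )
    return "".join(seq), mutations


def _mutate_junction(
    seq: str,
    rearr: Rearrangement,
    n_mut: int,
    rng: np.random.Generator,
) -> str:
    """Substitute ``n_mut`` junction-interior bases, avoiding the conserved
    codons and in-frame stops (junction length is preserved)."""
    lo = rearr.junction_start + 3
    hi = rearr.junction_end - 3
    if hi <= lo or n_mut == 0:
        return seq
    positions = rng.choice(np.arange(lo, hi), size=min(n_mut, hi - lo), replace=False)
    s = list(seq)
    for pos in positions:
        pos = int(pos)
        for _ in range(6):
            new = NUCLEOTIDES[rng.integers(4)]
            if new == s[pos]:
                continue
            old = s[pos]
            s[pos] = new
            codon_start = pos - pos % 3
            if "".join(s[codon_start : codon_start + 3]) in STOP_CODONS:
                s[pos] = old
            else:
                break
    return "".join(s)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_clone_sizes(
    n_cells_clonal: int, exponent: float, max_size: int, rng: np.random.Generator
) -> list[int]:
    """Clone sizes >= 2 from a truncated power law until the budget is met."""
    if n_cells_clonal < 2:
        return []
    support = np.arange(2, max(max_size, 2) + 1)
    p = support.astype(float) ** -exponent
    p /= p.sum()
    sizes: list[int] = []
    total = 0
    while total < n_cells_clonal:
        s = int(rng.choice(support, p=p))
        s = min(s, n_cells_clonal - total) if n_cells_clonal - total < 2 else s
        if n_cells_clonal - total == 1:
            break
        s = min(s, n_cells_clonal - total)
        if s < 2:
            break
        sizes.append(s)
        total += s
    return sizes


def _mutated_counts(
    profile: SubsetProfile, v_len: int, n_members: int, rng: np.random.Generator,
    extra: int = 0,
) -> tuple[int, list[int]]:
    """Trunk (shared) and per-member total mutation counts for a mutated unit."""
    mean_total = profile.mutation_rate * v_len + extra
    trunk = max(3, int(rng.poisson(0.75 * mean_total)))
    members = [trunk + int(rng.poisson(max(0.25 * mean_total, 0.5))) for _ in range(n_members)]
    return trunk, members


def _unmutated_counts(n_members: int, rng: np.random.Generator) -> list[int]:
    return [int(rng.choice([0, 1, 2], p=[0.6, 0.25, 0.15])) for _ in range(n_members)]


class _JunctionRegistry:
    """Keeps naive junctions of distinct clones separated within V/J/length
    groups so that single-linkage inference is identifiable by construction."""

    def __init__(self, min_dist: float = 0.2):
        self.min_dist = min_dist
        self._groups: dict[tuple[str, str, int], list[str]] = {}

    def admit(self, v_call: str, j_call: str, junction: str) -> bool:
        key = (v_call.split("*")[0], j_call.split("*")[0], len(junction))
        for other in self._groups.get(key, []):
            mism = sum(a != b for a, b in zip(junction, other))
            if mism / len(junction) < self.min_dist:
                return False
        self._groups.setdefault(key, []).append(junction)
        return True


def _new_clone_rearrangement(
    reference: GermlineReference,
    registry: _JunctionRegistry,
    rng: np.random.Generator,
) -> Rearrangement:
    for _ in range(80):
        rearr = simulate_rearrangement(reference, rng)
        if registry.admit(rearr.v_call, rearr.j_call, rearr.junction):
            return rearr
    return rearr  # extremely unlikely; accept the collision


def simulate_cohort(
    reference: GermlineReference,
    profiles: dict[str, SubsetProfile] | None = None,
    sharing: SharingPlan | None = None,
    n_individuals: int = 1,
    rng_seed: int | np.random.Generator = 0,
    subsets: tuple[str, ...] = SUBSETS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and return ``(records, ledger)`` DataFrames.

    ``records`` is an annotated AIRR-style rearrangement table (one row per
    unique sequence/cell) ready for the clonal/diversity/SHM stages;
    ``ledger`` holds the ground truth per cell.  Sharing applies to the three
    sorted subsets only; ``total_B`` is an independent reference subset.
    """
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    missing = [s for s in subsets if s not in profiles]
    if missing:
        raise ValueError(f"profiles missing for subsets: {missing}")
    sharing = SharingPlan() if sharing is None else sharing
    rng = _as_rng(rng_seed)

    record_rows: list[dict] = []
    ledger_rows: list[dict] = []

    for ind_idx in range(n_individuals):
        individual = f"P{ind_idx + 1:02d}"
        registry = _JunctionRegistry()
        clone_counter = 0
        cell_counter = 0

        budgets = {s: profiles[s].n_cells for s in subsets}

        # --- shared clone plan (sorted subsets only) -----------------------
        shared_specs: list[tuple[list[str], dict[str, int]]] = []
        sortable = [s for s in subsets if s != "total_B"]
        if len(sortable) == 3:
            pair_counts = sharing.exact_pair_counts()
            for _ in range(sharing.n_triple_shared):
                sizes = {
                    s: int(sharing.triple_min_size + rng.poisson(4)) for s in sortable
                }
                shared_specs.append((list(sortable), sizes))
            for (sa, sb), count in pair_counts.items():
                for _ in range(count):
                    sizes = {
                        sa: int(1 + rng.geometric(0.5)),
                        sb: int(1 + rng.geometric(0.5)),
                    }
                    shared_specs.append(([sa, sb], sizes))
            n_shared_cells = {
                s: sum(sizes.get(s, 0) for _, sizes in shared_specs) for s in sortable
            }
            for s in sortable:
                if n_shared_cells[s] >= budgets[s]:
                    raise ValueError(
                        f"sharing plan infeasible: {n_shared_cells[s]} shared cells "
                        f"exceed the {budgets[s]}-cell budget of {s}"
                    )
                budgets[s] -= n_shared_cells[s]

        def emit_unit(
            subsets_and_counts: dict[str, list[int]],
            profile_for_shm: SubsetProfile,
            mutated: bool,
            clone_id: str,
            shared: bool,
        ) -> None:
            """Simulate one clonal unit and append its member cells."""
            nonlocal cell_counter
            rearr = _new_clone_rearrangement(reference, registry, rng)
            v_gene = reference[rearr.v_call]
            germ = masked_germline(rearr, reference)
            trunk_muts: list[Mutation] = []
            trunk_seq = rearr.sequence
            if mutated:
                trunk_n = min(
                    min(n for counts in subsets_and_counts.values() for n in counts),
                    v_gene.anchor_start,
                )
                trunk_seq, trunk_muts = implant_shm(
                    rearr.sequence,
                    trunk_n,
                    v_gene,
                    rng,
                    cdr_weight=profile_for_shm.cdr_weight,
                    cdr_replacement_bias=profile_for_shm.cdr_replacement_bias,
                )
            trunk_positions = {m.position for m in trunk_muts}
            for subset, counts in subsets_and_counts.items():
                prof = profiles[subset]
                for total_count in counts:
                    private_n = max(0, total_count - len(trunk_muts))
                    private_n = min(
                        private_n, v_gene.anchor_start - len(trunk_positions)
                    )
                    seq, priv_muts = implant_shm(
                        trunk_seq,
                        private_n,
                        v_gene,
                        rng,
                        forbidden=trunk_positions,
                        cdr_weight=prof.cdr_weight,
                        cdr_replacement_bias=prof.cdr_replacement_bias,
                    )
                    if mutated and prof.junction_shm_rate > 0:
                        seq = _mutate_junction(
                            seq, rearr, int(rng.poisson(prof.junction_shm_rate)), rng
                        )
                    # Ledger R/S flags are always relative to the naive codon
                    # with only the one substitution applied (private
                    # mutations were implanted on top of the trunk).
                    priv_muts = [
                        Mutation(
                            m.position,
                            m.from_base,
                            m.to_base,
                            m.region,
                            _classify_substitution(
                                rearr.sequence, m.position, m.to_base
                            ),
                        )
                        for m in priv_muts
                    ]
                    all_muts = trunk_muts + priv_muts
                    cell_counter += 1
                    seq_id = f"{individual}_{cell_counter:06d}"
                    junction = seq[rearr.junction_start : rearr.junction_end]
                    junction_aa = translate(junction)
                    record_rows.append(
                        {
                            "sequence_id": seq_id,
                            "individual_id": individual,
                            "subset": subset,
                            "sequence": seq,
                            "sequence_alignment": seq,
                            "germline_alignment": germ,
                            "v_call": rearr.v_call,
                            "d_call": "",
                            "j_call": rearr.j_call,
                            "junction": junction,
                            "junction_aa": junction_aa,
                            "junction_length": len(junction),
                            "junction_start": rearr.junction_start,
                            "v_sequence_start": 0,
                            "v_germline_start": 0,
                            "j_sequence_start": len(seq) - len(reference[rearr.j_call].sequence),
                            "j_germline_start": 0,
                            "productive": True,
                        }
                    )
                    ledger_rows.append(
                        {
                            "sequence_id": seq_id,
                            "individual_id": individual,
                            "subset": subset,
                            "true_clone_id": clone_id,
                            "shared": shared,
                            "mutated_unit": mutated,
                            "naive_sequence": rearr.sequence,
                            "v_call": rearr.v_call,
                            "d_call": rearr.d_call,
                            "j_call": rearr.j_call,
                            "junction": rearr.junction,
                            "n_v_mutations": len(all_muts),
                            "mutations": "|".join(
                                f"{m.position}:{m.from_base}>{m.to_base}:{m.region}:"
                                f"{'R' if m.is_replacement else 'S'}"
                                for m in all_muts
                            ),
                        }
                    )

        # --- emit shared clones --------------------------------------------
        for members, sizes in shared_specs:
            clone_counter += 1
            clone_id = f"{individual}_C{clone_counter:05d}"
            base_prof = profiles[members[0]]
            v_len = 288  # nominal; per-clone value applied inside emit_unit
            counts_by_subset: dict[str, list[int]] = {}
            base_mean = min(profiles[s].mutation_rate for s in members) * v_len
            trunk = max(3, int(rng.poisson(0.6 * base_mean)))
            for s in members:
                extra = 3 * _SUBSET_RANK[s]
                counts_by_subset[s] = [
                    trunk + int(rng.poisson(1 + extra)) for _ in range(sizes[s])
                ]
            emit_unit(counts_by_subset, base_prof, True, clone_id, shared=True)

        # --- per-subset private clones and singletons ----------------------
        for subset in subsets:
            prof = profiles[subset]
            budget = budgets[subset]
            n_clonal = round(budget * (1 - prof.singleton_fraction))
            sizes = _draw_clone_sizes(
                n_clonal, prof.clone_size_exponent, prof.clone_size_max, rng
            )
            n_singletons = budget - sum(sizes)
            for size in sizes:
                clone_counter += 1
                clone_id = f"{individual}_C{clone_counter:05d}"
                mutated = rng.random() >= prof.fraction_unmutated
                if mutated:
                    _, counts = _mutated_counts(prof, 288, size, rng)
                else:
                    counts = _unmutated_counts(size, rng)
                emit_unit({subset: counts}, prof, mutated, clone_id, shared=False)
            for _ in range(n_singletons):
                clone_counter += 1
                clone_id = f"{individual}_C{clone_counter:05d}"
                mutated = rng.random() >= prof.fraction_unmutated
                if mutated:
                    _, counts = _mutated_counts(prof, 288, 1, rng)
                else:
                    counts = _unmutated_counts(1, rng)
                emit_unit({subset: counts}, prof, mutated, clone_id, shared=False)

    records = pd.DataFrame(record_rows)
    ledger = pd.DataFrame(ledger_rows)
    return records, ledger


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------


def _mid_for(individual_id: str, length: int) -> str:
    digest = hashlib.sha256(individual_id.encode()).digest()
    return "".join(NUCLEOTIDES[b % 4] for b in digest[:length])


def mid_table(records: pd.DataFrame, config: ReadEmissionConfig | None = None) -> dict[str, str]:
    """Per-individual 8-nt MID assignments used by :func:`emit_reads`."""
    config = config or ReadEmissionConfig()
    return {
        ind: _mid_for(ind, config.mid_length)
        for ind in sorted(records["individual_id"].unique())
    }


def emit_reads(
    records: pd.DataFrame,
    config: ReadEmissionConfig,
    rng_seed: int | np.random.Generator,
) -> list[tuple[str, str, list[int]]]:
    """Emit UMI-tagged reads: ``MID + UMI + primer + payload`` per read.

    Each molecule (record) receives a unique UMI (collision-checked); the
    read count per molecule is Poisson (floored at 1) or fixed; substitution
    errors at ``error_rate`` are applied to the payload only.  Returns
    ``(read_id, sequence, phred_quality)`` tuples suitable for
    :func:`bcrflow.io.write_fastq`.
    """
    rng = _as_rng(rng_seed)
    mids = mid_table(records, config)
    used_umis: set[str] = set()
    reads = []
    for row in records.itertuples():
        while True:
            umi = "".join(NUCLEOTIDES[i] for i in rng.integers(4, size=config.umi_length))
            if umi not in used_umis:
                used_umis.add(umi)
                break
        if config.reads_per_molecule_fixed is not None:
            n_reads = config.reads_per_molecule_fixed
        else:
            n_reads = max(1, int(rng.poisson(config.reads_per_molecule_mean)))
        mid = mids[row.individual_id]
        for r in range(n_reads):
            payload = list(row.sequence)
            err_pos: list[int] = []
            if config.error_rate > 0:
                n_err = rng.binomial(len(payload), config.error_rate)
                if n_err:
                    err_pos = [
                        int(p)
                        for p in rng.choice(len(payload), size=n_err, replace=False)
                    ]
                    for pos in err_pos:
                        payload[pos] = NUCLEOTIDES[
                            (NUCLEOTIDES.index(payload[pos]) + 1 + rng.integers(3)) % 4
                        ]
            seq = mid + umi + config.primer + "".join(payload)
            qual = np.clip(
                rng.normal(config.phred_mean, config.phred_sd, size=len(seq)),
                2,
                40,
            ).astype(int)
            offset = len(mid) + len(umi) + len(config.primer)
            for pos in err_pos:
                qual[offset + pos] = int(
                    np.clip(
                        rng.normal(config.error_phred_mean, config.error_phred_sd),
                        2,
                        40,
                    )
                )
            reads.append((f"{row.sequence_id}_r{r + 1}", seq, qual.tolist()))
    return reads
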