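"""Simulator: rearrangement frame/productivity contracts, SHM bookkeeping,
cohort structure, sharing realization, and read emission."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import binom

from bcrflow.sequtils import has_stop, translate
from bcrflow.simulate import (
    DEFAULT_PROFILES,
    ReadEmissionConfig,
    SharingPlan,
    emit_reads,
    implant_shm,
    simulate_cohort,
    simulate_rearrangement,
)
from tests.conftest import scaled_profiles


class TestRearrangement:
    def test_deterministic_under_seed(self, reference):
        a = simulate_rearrangement(reference, 42)
        b = simulate_rearrangement(reference, 42)
        assert a == b

    def test_zero_np_junction_spans_conserved_codons(self, reference):
        r = simulate_rearrangement(reference, 3, force_np_lengths=(0, 0))
        v = reference[r.v_call]
        j = reference[r.j_call]
        expected = (
            v.sequence[v.anchor_start :]
            + reference[r.d_call].sequence
            + j.sequence[: j.anchor_start + 3]
        )
        assert r.junction == expected
        assert len(r.junction) % 3 == 0

    def test_bulk_rearrangements_in_frame_and_stop_free(self, reference):
        rng = np.random.default_rng(7)
        for _ in range(300):
            r = simulate_rearrangement(reference, rng)
            assert (r.junction_end - r.junction_start) % 3 == 0
            assert not has_stop(r.sequence)
            aa = translate(r.junction)
            assert aa[0] == "C" and aa[-1] in "WF"


class TestImplantShm:
    def test_zero_mutations_is_identity(self, reference):
        r = simulate_rearrangement(reference, 5)
        seq, muts = implant_shm(r.sequence, 0, reference[r.v_call], 1)
        assert seq == r.sequence and muts == []

    def test_exact_count_and_positions_in_v(self, reference):
        r = simulate_rearrangement(reference, 5)
        v = reference[r.v_call]
        seq, muts = implant_shm(r.sequence, 7, v, 2)
        assert len(muts) == 7
        diffs = [i for i, (a, b) in enumerate(zip(r.sequence, seq)) if a != b]
        assert diffs == sorted(m.position for m in muts)
        assert all(p < v.anchor_start for p in diffs)

    def test_too_many_mutations_rejected(self, reference):
        r = simulate_rearrangement(reference, 5)
        v = reference[r.v_call]
        with pytest.raises(ValueError, match="exceeds"):
            implant_shm(r.sequence, v.anchor_start + 1, v, 0)

    def test_replacement_silent_flags_match_codon_table(self, reference):
        # Independent oracle: Biopython translation of the affected codon.
        rng = np.random.default_rng(9)
        for _ in range(30):
            r = simulate_rearrangement(reference, rng)
            _, muts = implant_shm(r.sequence, 10, reference[r.v_call], rng)
            for m in muts:
                start = m.position - m.position % 3
                naive_codon = r.sequence[start : start + 3]
                mutated = (
                    naive_codon[: m.position - start]
                    + m.to_base
                    + naive_codon[m.position - start + 1 :]
                )
                expected = str(Seq(naive_codon).translate()) != str(
                    Seq(mutated).translate()
                )
                assert m.is_replacement == expected


class TestCohort:
    def test_singleton_only_degenerate_config(self, reference):
        profiles = {
            name: prof
            for name, prof in scaled_profiles(60).items()
        }
        import dataclasses

        profiles = {
            n: dataclasses.replace(p, singleton_fraction=1.0) for n, p in profiles.items()
        }
        records, ledger = simulate_cohort(
            reference,
            profiles=profiles,
            sharing=SharingPlan(0, 0, 0, 0),
            n_individuals=1,
            rng_seed=1,
        )
        assert ledger["true_clone_id"].nunique() == len(ledger)

    def test_sharing_plan_realized_exactly(self, reference):
        records, ledger = simulate_cohort(
            reference,
            profiles=scaled_profiles(300),
            sharing=SharingPlan(neg_pos=5, neg_pb=0, pos_pb=0, n_triple_shared=0),
            n_individuals=1,
            rng_seed=4,
        )
        by_clone = ledger.groupby("true_clone_id")["subset"].agg(set)
        both = by_clone.map(
            lambda s: {"CD27neg_CD21lo", "CD27pos_CD21lo"} <= s
        ).sum()
        assert both == 5

    def test_infeasible_sharing_plan_rejected(self, reference):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_cohort(
                reference,
                profiles=scaled_profiles(30),
                sharing=SharingPlan(neg_pos=40, neg_pb=4, pos_pb=8, n_triple_shared=3),
                n_individuals=1,
                rng_seed=0,
            )

    def test_ledger_complete_and_deterministic(self, small_cohort, reference):
        records, ledger = small_cohort
        assert set(records["sequence_id"]) == set(ledger["sequence_id"])
        assert len(records) == len(ledger)
        again, _ = simulate_cohort(
            reference,
            profiles=scaled_profiles(500),
            sharing=SharingPlan(neg_pos=8, neg_pb=2, pos_pb=3, n_triple_shared=1),
            n_individuals=1,
            rng_seed=11,
        )
        assert again.equals(records)

    def test_clone_members_share_v_j_and_junction_length(self, small_cohort):
        records, ledger = small_cohort
        merged = records.merge(ledger[["sequence_id", "true_clone_id"]], on="sequence_id")
        grp = merged.groupby("true_clone_id")
        assert (grp["v_call"].nunique() == 1).all()
        assert (grp["j_call"].nunique() == 1).all()
        assert (grp["junction_length"].nunique() == 1).all()

    def test_default_profiles_reach_target_clonal_fractions(self, study_cohort):
        records, ledger = study_cohort
        targets = {"CD27neg_CD21lo": 0.50, "CD27pos_CD21lo": 0.85, "PB": 0.95}
        for ind, sub in ledger.groupby("individual_id"):
            for subset, target in targets.items():
                g = sub[sub["subset"] == subset]
                sizes = g.groupby("true_clone_id").size()
                frac = g["true_clone_id"].map(sizes).ge(2).mean()
                assert abs(frac - target) < 0.05, (ind, subset, frac)

    def test_ledger_mutation_flags_self_consistent(self, small_cohort):
        # Recompute R/S for every ledger mutation from the codon table.
        records, ledger = small_cohort
        checked = 0
        for row in ledger.itertuples():
            if not row.mutations:
                continue
            for token in str(row.mutations).split("|"):
                if not token:
                    continue
                pos_s, change, _, flag = token.split(":")
                pos = int(pos_s)
                frm, to = change.split(">")
                assert row.naive_sequence[pos] == frm
                start = pos - pos % 3
                codon = row.naive_sequence[start : start + 3]
                mutated = codon[: pos - start] + to + codon[pos - start + 1 :]
                expected = "R" if str(Seq(codon).translate()) != str(
                    Seq(mutated).translate()
                ) else "S"
                assert flag == expected
                checked += 1
        assert checked > 500


class TestEmitReads:
    def test_error_free_reads_identical_payload(self, reference):
        records, _ = simulate_cohort(
            reference, profiles=scaled_profiles(5), n_individuals=1, rng_seed=2,
            sharing=SharingPlan(0, 0, 0, 0),
        )
        cfg = ReadEmissionConfig(error_rate=0.0, reads_per_molecule_fixed=5)
        reads = emit_reads(records, cfg, 3)
        assert len(reads) == 5 * len(records)
        off = cfg.mid_length + cfg.umi_length + len(cfg.primer)
        by_mol = {}
        for rid, seq, qual in reads:
            assert len(seq) == len(qual)
            by_mol.setdefault(rid.rsplit("_r", 1)[0], set()).add(seq[off:])
        assert all(len(payloads) == 1 for payloads in by_mol.values())

    def test_umis_unique_per_molecule(self, reference):
        records, _ = simulate_cohort(
            reference, profiles=scaled_profiles(30), n_individuals=1, rng_seed=2,
            sharing=SharingPlan(0, 0, 0, 0),
        )
        cfg = ReadEmissionConfig(reads_per_molecule_fixed=1)
        reads = emit_reads(records, cfg, 5)
        umis = [seq[cfg.mid_length : cfg.mid_length + cfg.umi_length] for _, seq, _ in reads]
        assert len(set(umis)) == len(records)

    def test_error_rate_within_binomial_bounds(self, reference):
        records, _ = simulate_cohort(
            reference, profiles=scaled_profiles(10), n_individuals=1, rng_seed=6,
            sharing=SharingPlan(0, 0, 0, 0),
        )
        cfg = ReadEmissionConfig(error_rate=0.01, reads_per_molecule_fixed=3)
        reads = emit_reads(records, cfg, 8)
        truth = {r.sequence_id: r.sequence for r in records.itertuples()}
        off = cfg.mid_length + cfg.umi_length + len(cfg.primer)
        mismatches = bases = 0
        for rid, seq, _ in reads:
            t = truth[rid.rsplit("_r", 1)[0]]
            payload = seq[off:]
            assert len(payload) == len(t)
            mismatches += sum(a != b for a, b in zip(payload, t))
            bases += len(t)
        lo, hi = binom.ppf([0.005, 0.995], bases, 0.01)
        assert lo <= mismatches <= hi
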