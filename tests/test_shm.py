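"""SHM profiling: mutation counting against ledger truth, unmutated/mutated
classification, clone-weighted summaries, R/S classification, and the
shared-vs-nonshared comparison."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from bcrflow.clonal import infer_clones
from bcrflow.sequtils import CODON_TABLE
from bcrflow.shm import (
    add_mutation_columns,
    classify_mutated,
    clone_unit_table,
    count_v_mutations,
    is_replacement,
    rs_counts,
    rs_ratio,
    shared_vs_nonshared_mutation,
    subset_mutation_summary,
)


class TestCountVMutations:
    def test_identical_to_germline(self):
        count, compared = count_v_mutations("ACGTACGT", "ACGTACGT", 8)
        assert count == 0 and compared == 8

    def test_junction_differences_not_counted(self):
        seq = "ACGTACGT" + "TTTT"
        germ = "ACGTACGT" + "NNNN"
        count, _ = count_v_mutations(seq, germ, 8)
        assert count == 0

    def test_masked_and_gap_positions_skipped(self):
        count, compared = count_v_mutations("ACG-ACGT", "ACGTNCGT", 8)
        assert compared == 6
        assert count == 0

    def test_no_comparable_positions_raises(self):
        with pytest.raises(ValueError):
            count_v_mutations("ACGT", "NNNN", 4)

    def test_matches_ledger_on_simulated_records(self, small_cohort, reference):
        records, ledger = small_cohort
        sample = records.head(400)
        with_mu = add_mutation_columns(sample, reference)
        truth = ledger.set_index("sequence_id")["n_v_mutations"]
        assert (with_mu.set_index("sequence_id")["mu_count"] == truth.loc[
            with_mu["sequence_id"]
        ].to_numpy()).all()


class TestClassification:
    @pytest.mark.parametrize(
        "count,label", [(0, "unmutated"), (2, "unmutated"), (3, "mutated")]
    )
    def test_absolute_count_threshold(self, count, label):
        assert classify_mutated(count) == label

    def test_clone_mean_thresholded(self):
        assert classify_mutated(np.mean([1, 2, 6])) == "mutated"


class TestSummaries:
    def _df(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "sequence_id",
                "individual_id",
                "subset",
                "clone_id",
                "mu_count",
                "mu_freq",
                "r_cdr",
                "s_cdr",
            ],
        )

    def test_unit_mean_example(self):
        rows = [
            ("s1", "P01", "A", "c1", 12, 0.04, 1, 1),
            ("s2", "P01", "A", "c2", 20, 0.08, 1, 1),
            ("s3", "P01", "A", "c3", 0, 0.00, 0, 0),
        ]
        out = subset_mutation_summary(self._df(rows))
        assert out.iloc[0]["mean_freq_all_units"] == pytest.approx(0.04)

    def test_all_units_unmutated_percent_zero(self):
        rows = [("s1", "P01", "A", "c1", 1, 0.003, 0, 0)]
        out = subset_mutation_summary(self._df(rows))
        assert out.iloc[0]["percent_mutated"] == 0.0

    def test_clone_weighting_robust_to_member_duplication(self):
        rows = [
            ("s1", "P01", "A", "c1", 12, 0.05, 1, 1),
            ("s2", "P01", "A", "c2", 4, 0.01, 1, 1),
        ]
        base = subset_mutation_summary(self._df(rows))
        dup = self._df(
            rows + [("s3", "P01", "A", "c1", 12, 0.05, 1, 1)] * 1
        )
        duped = subset_mutation_summary(dup)
        assert duped.iloc[0]["mean_freq_all_units"] == pytest.approx(
            base.iloc[0]["mean_freq_all_units"]
        )
        # whereas a naive per-sequence mean shifts
        naive_base = self._df(rows)["mu_freq"].mean()
        naive_dup = dup["mu_freq"].mean()
        assert naive_base != pytest.approx(naive_dup)


class TestReplacementSilent:
    def test_hand_picked_codon_examples(self):
        # GAT -> GAA: D -> E replacement; GAT -> GAC: D -> D silent
        assert is_replacement("GAT", 2, "A") is True
        assert is_replacement("GAT", 2, "C") is False

    def test_rs_counts_on_constructed_alignment(self, reference):
        gene = reference.v_genes[0]
        germ = gene.sequence
        lo, hi = gene.regions["cdr1"]
        pos_r = lo - lo % 3  # first base of a codon inside/near CDR1
        while pos_r < lo:
            pos_r += 3
        seq = list(germ)
        codon = germ[pos_r : pos_r + 3]
        for alt in "ACGT":
            if alt != codon[0] and CODON_TABLE[alt + codon[1:]] != CODON_TABLE[codon]:
                seq[pos_r] = alt
                break
        r, s = rs_counts("".join(seq), germ, gene.name, reference)
        assert (r, s) == (1, 0)

    def test_brute_force_codon_table_agreement(self):
        # independent oracle: Biopython translation on random substitutions
        rng = np.random.default_rng(12)
        bases = "ACGT"
        for _ in range(2000):
            codon = "".join(rng.choice(list(bases), 3))
            offset = int(rng.integers(3))
            new = rng.choice([b for b in bases if b != codon[offset]])
            expected = str(Seq(codon).translate()) != str(
                Seq(codon[:offset] + new + codon[offset + 1 :]).translate()
            )
            assert is_replacement(codon, offset, new) == expected

    def test_ratio_example_and_exclusions(self):
        df = pd.DataFrame(
            {
                "sequence_id": ["s1", "s2", "s3"],
                "individual_id": ["P01"] * 3,
                "subset": ["A"] * 3,
                "clone_id": ["c1", "c2", "c3"],
                "mu_count": [5, 6, 7],
                "mu_freq": [0.02, 0.02, 0.03],
                "r_cdr": [1, 0, 2],
                "s_cdr": [1, 2, 0],
            }
        )
        out = rs_ratio(df)
        # unit c3 has S=0 and is excluded; mean of (1/1, 0/2) = 0.5
        assert out.n_excluded_zero_silent == 1
        assert out.per_individual.iloc[0]["rs_ratio"] == pytest.approx(0.5)

    def test_cdr_replacement_bias_raises_ratio(self, reference):
        # simulator contrast: replacement-biased CDR mutations vs unbiased
        import dataclasses

        from bcrflow.simulate import DEFAULT_PROFILES, SharingPlan, simulate_cohort

        def run(bias, seed):
            profiles = {
                n: dataclasses.replace(
                    p, n_cells=150, cdr_replacement_bias=bias, fraction_unmutated=0.0
                )
                for n, p in DEFAULT_PROFILES.items()
            }
            records, _ = simulate_cohort(
                reference,
                profiles=profiles,
                sharing=SharingPlan(0, 0, 0, 0),
                n_individuals=1,
                rng_seed=seed,
                subsets=("CD27neg_CD21lo",),
            )
            with_clones, _, _ = infer_clones(records, threshold=0.1)
            with_mu = add_mutation_columns(with_clones, reference)
            out = rs_ratio(with_mu)
            return out.per_individual["rs_ratio"].iloc[0]

        biased = [run(3.0, s) for s in range(3)]
        flat = [run(1.0, s + 100) for s in range(3)]
        assert np.mean(biased) > np.mean(flat)


class TestSharedVsNonshared:
    def test_no_sharing_is_skipped_with_reason(self, reference):
        from bcrflow.simulate import SharingPlan, simulate_cohort
        from tests.conftest import scaled_profiles

        records, _ = simulate_cohort(
            reference,
            profiles=scaled_profiles(120),
            sharing=SharingPlan(0, 0, 0, 0),
            n_individuals=1,
            rng_seed=3,
        )
        with_clones, clone_set, _ = infer_clones(records)
        with_mu = add_mutation_columns(with_clones, reference)
        comp = shared_vs_nonshared_mutation(
            with_mu, {"P01": clone_set}, "CD27neg_CD21lo", "PB"
        )
        assert comp.per_individual.empty
        assert comp.skipped and "no shared clones" in comp.skipped[0]

    def test_shared_clones_more_mutated_by_construction(self, small_cohort, reference):
        records, ledger = small_cohort
        with_clones, clone_set, _ = infer_clones(records)
        with_mu = add_mutation_columns(with_clones, reference)
        comp = shared_vs_nonshared_mutation(
            with_mu, {"P01": clone_set}, "CD27neg_CD21lo", "CD27pos_CD21lo"
        )
        row = comp.per_individual.iloc[0]
        assert row["mean_freq_shared"] > row["mean_freq_nonshared"]
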