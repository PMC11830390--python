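"""Clonal inference: distance-to-nearest semantics, threshold detection,
single-linkage equivalence to a brute-force oracle, subsampling, sharing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bcrflow.clonal import (
    CLONE_SIZE_CATEGORIES,
    DistanceDistribution,
    categorize_clone_sizes,
    cluster_clones,
    distance_to_nearest,
    find_threshold,
    infer_clones,
    shared_clones,
    subsample_uniform,
)


def _records(junctions, v="IGHV1-S1*01", j="IGHJ4-S1*01", subsets=None):
    n = len(junctions)
    return pd.DataFrame(
        {
            "sequence_id": [f"s{i:03d}" for i in range(n)],
            "individual_id": ["P01"] * n,
            "subset": subsets or ["CD27neg_CD21lo"] * n,
            "v_call": [v] * n if isinstance(v, str) else v,
            "j_call": [j] * n if isinstance(j, str) else j,
            "junction": junctions,
            "junction_length": [len(s) for s in junctions],
        }
    )


def _brute_force_partition(df, threshold):
    """Transitive closure over the pairwise <=threshold graph, with the
    V/J/length grouping rule applied pairwise."""
    n = len(df)
    adj = {i: set() for i in range(n)}
    rows = list(df.itertuples())
    for i, j in itertools.combinations(range(n), 2):
        a, b = rows[i], rows[j]
        if (
            a.v_call.split("*")[0] != b.v_call.split("*")[0]
            or a.j_call.split("*")[0] != b.j_call.split("*")[0]
            or a.junction_length != b.junction_length
        ):
            continue
        d = sum(x != y for x, y in zip(a.junction, b.junction)) / a.junction_length
        if d <= threshold:
            adj[i].add(j)
            adj[j].add(i)
    seen, parts = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        parts.append(frozenset(rows[k].sequence_id for k in comp))
    return set(parts)


def _partition_of(clone_set):
    return {frozenset(c.members) for c in clone_set.clones}


class TestDistanceToNearest:
    def test_single_mismatch_distance(self):
        df = _records(["TGTGCGAGA", "TGTGCGAGG"])
        dist = distance_to_nearest(df)
        assert np.allclose(dist.distances.to_numpy(), 1 / 9)

    def test_identical_junctions_distance_zero(self):
        df = _records(["TGTGCGAGA", "TGTGCGAGA"])
        assert (distance_to_nearest(df).distances == 0).all()

    def test_different_lengths_contribute_nothing(self):
        df = _records(["TGTGCGAGA", "TGTGCGAGGCGT"])
        assert distance_to_nearest(df).distances.empty

    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            distance_to_nearest(_records(["TGTGCGAGA"]))


class TestFindThreshold:
    def test_bimodal_mixture_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        values = np.clip(
            np.concatenate(
                [rng.normal(0.03, 0.01, 200), rng.normal(0.30, 0.05, 200)]
            ),
            0,
            1,
        )
        dist = DistanceDistribution(distances=pd.Series(values))
        out = find_threshold(dist)
        assert out.bimodal and not out.fallback
        assert 0.08 < out.threshold < 0.22

    def test_unimodal_distribution_falls_back(self):
        dist = DistanceDistribution(distances=pd.Series([0.5] * 100))
        out = find_threshold(dist)
        assert out.fallback and out.threshold == 0.1

    def test_sparse_distribution_falls_back(self):
        dist = DistanceDistribution(distances=pd.Series([0.1, 0.5] * 10))
        out = find_threshold(dist)
        assert out.fallback


class TestClusterClones:
    def test_single_linkage_chaining(self):
        # A-B 1/20, B-C 1/20, A-C 2/20: chaining joins all three at t=0.06
        a = "TGTGCGAGAGCGAGAGCTGG"
        b = a[:19] + "C"
        c = a[:18] + "CC"[:1] + a[19:]
        c = a[:18] + "C" + a[19:]
        df = _records([a, b, c])
        joined = cluster_clones(df, 0.06)
        assert len(_partition_of(joined)) == 1
        split = cluster_clones(df, 0.04)
        assert len(_partition_of(split)) == 3

    def test_matches_brute_force_on_random_instances(self, reference):
        rng = np.random.default_rng(42)
        vs = [g.name for g in reference.v_genes]
        js = [g.name for g in reference.j_genes]
        for _ in range(25):
            n = int(rng.integers(2, 50))
            lengths = [9, 12]
            junctions, vc, jc = [], [], []
            for _ in range(n):
                L = int(rng.choice(lengths))
                junctions.append("".join(rng.choice(list("ACGT"), L)))
                vc.append(vs[rng.integers(len(vs))])
                jc.append(js[rng.integers(len(js))])
            df = _records(junctions, v=vc, j=jc)
            t = float(rng.uniform(0.05, 0.5))
            assert _partition_of(cluster_clones(df, t)) == _brute_force_partition(df, t)

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=2, max_size=25
        ),
        st.floats(min_value=0.0, max_value=0.9),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_property_oracle_equivalence(self, junctions, threshold):
        df = _records(junctions)
        assert _partition_of(cluster_clones(df, threshold)) == _brute_force_partition(
            df, threshold
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        junctions = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(30)]
        df = _records(junctions)
        base = _partition_of(cluster_clones(df, 0.3))
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert _partition_of(cluster_clones(shuffled, 0.3)) == base

    def test_raising_threshold_never_increases_clone_count(self):
        rng = np.random.default_rng(4)
        junctions = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(40)]
        df = _records(junctions)
        counts = [
            len(cluster_clones(df, t).clones) for t in (0.0, 0.1, 0.3, 0.5, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCloneSizeCategories:
    @pytest.mark.parametrize(
        "size,category", [(2, "low"), (5, "low"), (6, "moderate"), (20, "moderate"), (21, "high")]
    )
    def test_boundaries(self, size, category):
        df = _records(["TGTGCGAGA"] * size + ["AAACCCGGG"])
        clone_set = cluster_clones(df, 0.0)
        counts = categorize_clone_sizes(clone_set)
        assert counts[category] == 1
        assert sum(counts.values()) == 1  # the singleton is excluded


class TestSubsample:
    def test_exact_sample_size(self):
        df = _records(["TGTGCGAGA"] * 50)
        out, shortfall = subsample_uniform(df, 20, rng_seed=0)
        assert len(out) == 20 and not shortfall

    def test_shortfall_reported(self):
        df = _records(["TGTGCGAGA"] * 5)
        out, shortfall = subsample_uniform(df, 20, rng_seed=0)
        assert len(out) == 5 and shortfall

    def test_deterministic_under_seed(self):
        df = _records(["TGTGCGAGA"] * 50)
        a, _ = subsample_uniform(df, 10, rng_seed=7)
        b, _ = subsample_uniform(df, 10, rng_seed=7)
        assert a.equals(b)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            subsample_uniform(_records(["TGTGCGAGA"]), 0)


class TestSharedClones:
    def test_small_constructed_instance(self):
        df = _records(
            ["TGTGCGAGA", "TGTGCGAGC", "TGTGCGAGA", "AAATTTCCC"],
            subsets=["CD27neg_CD21lo", "CD27neg_CD21lo", "CD27pos_CD21lo", "PB"],
        )
        clone_set = cluster_clones(df, 0.0)
        summary = shared_clones(clone_set)
        assert summary.pair_counts[("CD27neg_CD21lo", "CD27pos_CD21lo")] == 1
        assert summary.pair_counts[("CD27neg_CD21lo", "PB")] == 0
        assert summary.triple_count == 0

    def test_disjoint_junctions_share_nothing(self):
        df = _records(
            ["TGTGCGAGA", "AAATTTCCC"],
            subsets=["CD27neg_CD21lo", "CD27pos_CD21lo"],
        )
        summary = shared_clones(cluster_clones(df, 0.1))
        assert all(v == 0 for v in summary.pair_counts.values())

    def test_sharing_plan_recovered_from_simulation(self, reference):
        from bcrflow.simulate import SharingPlan, simulate_cohort
        from tests.conftest import scaled_profiles

        records, ledger = simulate_cohort(
            reference,
            profiles=scaled_profiles(400),
            sharing=SharingPlan(neg_pos=5, neg_pb=1, pos_pb=2, n_triple_shared=1),
            n_individuals=1,
            rng_seed=13,
        )
        with_clones, clone_set, dist = infer_clones(records)
        summary = shared_clones(clone_set)
        assert abs(summary.pair_counts[("CD27neg_CD21lo", "CD27pos_CD21lo")] - 5) <= 1


class TestThresholdRecoveryOnSimulation:
    def test_threshold_separates_true_populations(self, small_cohort):
        records, ledger = small_cohort
        with_clones, clone_set, dist = infer_clones(records)
        assert dist.bimodal
        # within-clone junction divergence stays below the threshold,
        # between-clone distances above it
        merged = records.merge(
            ledger[["sequence_id", "true_clone_id"]], on="sequence_id"
        )
        t = clone_set.threshold
        assert 0.0 < t < 0.35
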