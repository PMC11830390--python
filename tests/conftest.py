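"""Shared fixtures: the bundled reference and simulated cohorts.

Heavier cohorts are session-scoped so that clonal-recovery, pattern, and
lineage checks reuse one simulation.
"""

from __future__ import annotations

import dataclasses

import pytest

from bcrflow.germline import load_reference
from bcrflow.simulate import (
    DEFAULT_PROFILES,
    SharingPlan,
    simulate_cohort,
)


def scaled_profiles(n_cells: int) -> dict:
    """Default subset profiles at a reduced per-subset cell count."""
    return {
        name: dataclasses.replace(prof, n_cells=n_cells)
        for name, prof in DEFAULT_PROFILES.items()
    }


SMALL_SHARING = SharingPlan(neg_pos=8, neg_pb=2, pos_pb=3, n_triple_shared=1)


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def small_cohort(reference):
    """One individual, 500 cells/subset: fast enough for most module tests."""
    records, ledger = simulate_cohort(
        reference,
        profiles=scaled_profiles(500),
        sharing=SMALL_SHARING,
        n_individuals=1,
        rng_seed=11,
    )
    return records, ledger


@pytest.fixture(scope="session")
def study_cohort(reference):
    """Three individuals at the full default study conditions (3195 cells per
    subset, default sharing plan); reused by recovery and pattern tests."""
    records, ledger = simulate_cohort(
        reference,
        n_individuals=3,
        rng_seed=2024,
    )
    return records, ledger
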