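"""Clonal inference: distance-to-nearest distributions, per-individual
threshold detection at the bimodal minimum, single-linkage clustering within
V/J/junction-length groups, clone-size categories, uniform subsampling, and
cross-subset clone sharing.

Sequences are grouped by gene-level V and J calls and identical junction
length; within a group, two sequences are clonally related when their
junction-normalized Hamming distance falls below the per-individual
threshold, and clones are the single-linkage (transitive) closure of that
relation.  The threshold is the density minimum between the two modes of
the distance-to-nearest histogram; a fixed fallback applies when the
distribution is unimodal or too sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .germline import gene_of

FALLBACK_THRESHOLD = 0.1
MIN_DISTANCES_FOR_KDE = 50
MIN_MODE_SEPARATION = 0.05

CLONE_SIZE_CATEGORIES = {"low": (2, 5), "moderate": (6, 20), "high": (21, None)}

SORTED_SUBSETS = ("CD27neg_CD21lo", "CD27pos_CD21lo", "PB")


def _group_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["v_call"].map(gene_of)
        + "|"
        + df["j_call"].map(gene_of)
        + "|"
        + df["junction_length"].astype(str)
    )


def _encode(junctions: list[str]) -> np.ndarray:
    return np.frombuffer("".join(junctions).encode(), dtype=np.uint8).reshape(
        len(junctions), -1
    )


def _pairwise_normalized_hamming(junctions: list[str]) -> np.ndarray:
    mat = _encode(junctions)
    d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2) / mat.shape[1]
    return d


@dataclass
class DistanceDistribution:
    """Per-record nearest-neighbor junction distances for one individual."""

    distances: pd.Series  # indexed by sequence_id; only records with >=1 partner
    threshold: float = float("nan")
    bimodal: bool = False
    fallback: bool = False
    density_grid: np.ndarray | None = None
    density: np.ndarray | None = None


def distance_to_nearest(records: pd.DataFrame) -> DistanceDistribution:
    """Minimum normalized junction Hamming distance to any same-group record.

    Records in singleton V/J/length groups contribute no distance.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    out_idx: list[str] = []
    out_val: list[float] = []
    for _, grp in records.groupby(_group_key(records), sort=True):
        if len(grp) < 2:
            continue
        d = _pairwise_normalized_hamming(grp["junction"].tolist())
        np.fill_diagonal(d, np.inf)
        nearest = d.min(axis=1)
        out_idx.extend(grp["sequence_id"].tolist())
        out_val.extend(nearest.tolist())
    return DistanceDistribution(distances=pd.Series(out_val, index=out_idx, dtype=float))


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict local maxima, including the grid boundaries."""
    idx = []
    for i in range(len(y)):
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < len(y) - 1 else -np.inf
        if y[i] > left and y[i] >= right:
            idx.append(i)
    return idx


def find_threshold(
    dist: DistanceDistribution, grid_size: int = 512
) -> DistanceDistribution:
    """Detect the clonal threshold at the density minimum between the two
    modes of the distance-to-nearest distribution.

    Gaussian KDE with Silverman bandwidth on a 512-point grid over [0, 1];
    "two modes" are the two highest local maxima separated by at least 0.05
    in distance.  A unimodal or sparse (<50 distances) distribution falls
    back to a fixed threshold of 0.1 with ``fallback=True``.
    """
    values = dist.distances.to_numpy()
    grid = np.linspace(0.0, 1.0, grid_size)
    if len(values) < MIN_DISTANCES_FOR_KDE or np.ptp(values) < 1e-12:
        return DistanceDistribution(
            distances=dist.distances,
            threshold=FALLBACK_THRESHOLD,
            bimodal=False,
            fallback=True,
        )
    kde = gaussian_kde(values, bw_method="silverman")
    density = kde(grid)
    maxima = _local_maxima(density)
    maxima.sort(key=lambda i: -density[i])
    chosen: tuple[int, int] | None = None
    for i in range(1, len(maxima)):
        a, b = maxima[0], maxima[i]
        if abs(grid[a] - grid[b]) >= MIN_MODE_SEPARATION:
            chosen = (min(a, b), max(a, b))
            break
    if chosen is None:
        return DistanceDistribution(
            distances=dist.distances,
            threshold=FALLBACK_THRESHOLD,
            bimodal=False,
            fallback=True,
            density_grid=grid,
            density=density,
        )
    lo, hi = chosen
    valley = lo + int(np.argmin(density[lo : hi + 1]))
    return DistanceDistribution(
        distances=dist.distances,
        threshold=float(grid[valley]),
        bimodal=True,
        fallback=False,
        density_grid=grid,
        density=density,
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


@dataclass
class CloneInfo:
    clone_id: str
    members: list[str]
    subsets: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_singleton(self) -> bool:
        return self.size == 1


@dataclass
class CloneSet:
    """Partition of one individual's records into clones and singletons."""

    individual_id: str
    threshold: float
    assignments: pd.Series  # sequence_id -> clone_id
    clones: list[CloneInfo]

    def clones_of_size(self, minimum: int = 2) -> list[CloneInfo]:
        return [c for c in self.clones if c.size >= minimum]

    @property
    def singletons(self) -> list[CloneInfo]:
        return [c for c in self.clones if c.is_singleton]


def cluster_clones(records: pd.DataFrame, threshold: float) -> CloneSet:
    """Single-linkage clones under the normalized Hamming ``threshold``.

    Two records are co-clonal iff they are connected by a chain of
    same-group pairs with junction distance <= threshold.  Identical
    junctions (distance 0) are always co-clonal, so the rule also captures
    100%-identical sequences in different subsets.  Clone ids are stable
    under input permutation (records are canonically sorted internally).
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    records = records.sort_values("sequence_id").reset_index(drop=True)
    individual = (
        str(records["individual_id"].iloc[0]) if "individual_id" in records else "NA"
    )
    labels = pd.Series(index=records["sequence_id"], dtype=object)
    clones: list[CloneInfo] = []
    counter = 0
    for _, grp in records.groupby(_group_key(records), sort=True):
        idx = grp.index.to_list()
        if len(idx) == 1:
            comps = [[0]]
        else:
            d = _pairwise_normalized_hamming(grp["junction"].tolist())
            uf = _UnionFind(len(idx))
            ii, jj = np.nonzero(d <= threshold)
            for a, b in zip(ii, jj):
                if a < b:
                    uf.union(int(a), int(b))
            roots: dict[int, list[int]] = {}
            for k in range(len(idx)):
                roots.setdefault(uf.find(k), []).append(k)
            comps = [roots[r] for r in sorted(roots)]
        for comp in comps:
            counter += 1
            clone_id = f"{individual}_c{counter:06d}"
            member_ids = [grp["sequence_id"].iloc[k] for k in comp]
            subsets = (
                set(grp["subset"].iloc[comp]) if "subset" in grp.columns else set()
            )
            clones.append(CloneInfo(clone_id, member_ids, subsets))
            labels.loc[member_ids] = clone_id
    return CloneSet(
        individual_id=individual,
        threshold=threshold,
        assignments=labels,
        clones=clones,
    )


def infer_clones(
    records: pd.DataFrame, threshold: float | None = None
) -> tuple[pd.DataFrame, CloneSet, DistanceDistribution | None]:
    """Distance-to-nearest -> threshold -> single-linkage clones for one
    individual; returns the records with a ``clone_id`` column added."""
    dist = None
    if threshold is None:
        dist = find_threshold(distance_to_nearest(records))
        threshold = dist.threshold
    clone_set = cluster_clones(records, threshold)
    out = records.copy()
    out["clone_id"] = out["sequence_id"].map(clone_set.assignments)
    return out, clone_set, dist


def categorize_clone_sizes(clone_set: CloneSet) -> dict[str, int]:
    """Count clones (size >= 2) in the low (2-5), moderate (6-20), and high
    (>20 members) clonality categories; singletons are excluded."""
    counts = {name: 0 for name in CLONE_SIZE_CATEGORIES}
    for clone in clone_set.clones_of_size(2):
        for name, (lo, hi) in CLONE_SIZE_CATEGORIES.items():
            if clone.size >= lo and (hi is None or clone.size <= hi):
                counts[name] += 1
                break
    return counts


def subsample_uniform(
    records: pd.DataFrame,
    n_target: int = 3195,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, bool]:
    """Simple random sample of exactly ``n_target`` records without
    replacement; when fewer are available all are retained and the shortfall
    is flagged (``(sample, shortfall)``)."""
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if len(records) <= n_target:
        return records.reset_index(drop=True), len(records) < n_target
    take = rng.choice(len(records), size=n_target, replace=False)
    return records.iloc[np.sort(take)].reset_index(drop=True), False


@dataclass
class SharedCloneSummary:
    """Clone-sharing counts between sorted subsets of one individual."""

    pair_counts: dict[tuple[str, str], int]
    triple_count: int
    pair_clone_ids: dict[tuple[str, str], list[str]]
    triple_clone_ids: list[str]


def shared_clones(
    clone_set: CloneSet, subsets: tuple[str, ...] = SORTED_SUBSETS
) -> SharedCloneSummary:
    """A clone is shared between two subsets iff it has at least one member
    record from each; the triple count requires members from all three."""
    pairs = [
        (subsets[0], subsets[1]),
        (subsets[0], subsets[2]),
        (subsets[1], subsets[2]),
    ]
    pair_ids: dict[tuple[str, str], list[str]] = {p: [] for p in pairs}
    triple_ids: list[str] = []
    for clone in clone_set.clones:
        present = clone.subsets
        for a, b in pairs:
            if a in present and b in present:
                pair_ids[(a, b)].append(clone.clone_id)
        if all(s in present for s in subsets):
            triple_ids.append(clone.clone_id)
    return SharedCloneSummary(
        pair_counts={p: len(ids) for p, ids in pair_ids.items()},
        triple_count=len(triple_ids),
        pair_clone_ids=pair_ids,
        triple_clone_ids=triple_ids,
    )
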