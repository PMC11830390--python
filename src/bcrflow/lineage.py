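"""Germline-rooted clonal lineage trees by greedy parsimony.

Clone members are deduplicated to unique haplotypes and attached
iteratively to the growing tree, each step adding the haplotype with the
smallest substitution distance to any current node (Prim's construction,
which minimizes the total substitution count over all trees whose nodes
are the observed haplotypes plus the germline root; no unobserved Steiner
sequences are inferred).  Distances ignore positions where either sequence
is masked (N) or gapped.  Trees serialize to Newick with NHX subset
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clonal import CloneSet, SORTED_SUBSETS

ROOT_NAME = "germline"

_VALID = frozenset("ACGT")


def masked_distance(a: str, b: str) -> int:
    """Substitution count over positions where both sequences are ACGT."""
    if len(a) != len(b):
        raise ValueError("sequences of unequal aligned length")
    return sum(1 for x, y in zip(a, b) if x in _VALID and y in _VALID and x != y)


@dataclass
class TreeNode:
    name: str
    sequence: str
    parent: str | None
    edge_weight: int
    subsets: list[str] = field(default_factory=list)
    member_ids: list[str] = field(default_factory=list)


@dataclass
class LineageTree:
    """Clonal lineage tree rooted at the masked germline."""

    clone_id: str
    nodes: dict[str, TreeNode]

    @property
    def root(self) -> TreeNode:
        return self.nodes[ROOT_NAME]

    def children(self, name: str) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.parent == name]

    def depth(self, name: str) -> int:
        """Summed edge weight from the root to ``name``."""
        node = self.nodes[name]
        total = 0
        while node.parent is not None:
            total += node.edge_weight
            node = self.nodes[node.parent]
        return total

    @property
    def parsimony_score(self) -> int:
        return sum(n.edge_weight for n in self.nodes.values() if n.parent is not None)

    def to_newick(self) -> str:
        def annot(node: TreeNode) -> str:
            subsets = ",".join(sorted(set(node.subsets))) or "germline"
            return f"[&&NHX:subsets={subsets}]"

        def render(name: str) -> str:
            node = self.nodes[name]
            kids = sorted(self.children(name), key=lambda n: n.name)
            label = f"{node.name}:{node.edge_weight}{annot(node)}"
            if not kids:
                return label
            inner = ",".join(render(k.name) for k in kids)
            return f"({inner}){label}"

        root = self.root
        kids = sorted(self.children(ROOT_NAME), key=lambda n: n.name)
        inner = ",".join(render(k.name) for k in kids)
        return f"({inner}){root.name}:0{annot(root)};"


def select_tree_clones(
    clone_set: CloneSet, subsets: tuple[str, ...] = SORTED_SUBSETS, min_size: int = 21
) -> list[str]:
    """Clones eligible for lineage reconstruction: more than 20 members and
    at least one member from each of the three sorted subsets."""
    return [
        c.clone_id
        for c in clone_set.clones
        if c.size >= min_size and all(s in c.subsets for s in subsets)
    ]


def build_tree(members: pd.DataFrame, germline: str, clone_id: str = "") -> LineageTree:
    """Greedy-parsimony lineage tree of one clone.

    ``members`` needs ``sequence_id``, ``subset`` and ``sequence_alignment``
    columns, all alignments the same length as ``germline``.  Haplotypes are
    deduplicated (a node lists every member and subset it represents) and
    canonically sorted, making the construction deterministic.
    """
    for aln in members["sequence_alignment"]:
        if len(aln) != len(germline):
            raise ValueError("member alignment length differs from germline")
    haplotypes: dict[str, dict] = {}
    for row in members.sort_values("sequence_id").itertuples():
        h = haplotypes.setdefault(
            row.sequence_alignment, {"subsets": [], "member_ids": []}
        )
        h["subsets"].append(row.subset)
        h["member_ids"].append(row.sequence_id)
    ordered = sorted(haplotypes)  # canonical order for determinism
    nodes = {
        ROOT_NAME: TreeNode(ROOT_NAME, germline, parent=None, edge_weight=0)
    }
    pending = {seq: f"h{idx + 1}" for idx, seq in enumerate(ordered)}
    in_tree: list[tuple[str, str]] = [(ROOT_NAME, germline)]
    while pending:
        best = None  # (distance, haplotype name, haplotype seq, attach name)
        for seq, hname in sorted(pending.items(), key=lambda kv: kv[1]):
            for tname, tseq in in_tree:
                d = masked_distance(seq, tseq)
                cand = (d, hname, seq, tname)
                if best is None or cand < best:
                    best = cand
        d, hname, seq, attach = best
        nodes[hname] = TreeNode(
            hname,
            seq,
            parent=attach,
            edge_weight=d,
            subsets=haplotypes[seq]["subsets"],
            member_ids=haplotypes[seq]["member_ids"],
        )
        in_tree.append((hname, seq))
        del pending[seq]
    return LineageTree(clone_id=clone_id, nodes=nodes)


def subset_depth_report(trees: list[LineageTree]) -> pd.DataFrame:
    """Mean root distance per subset, per tree and pooled.

    Each observed member contributes its node's root-path substitution
    distance under its subset label.
    """
    rows = []
    for tree in trees:
        for node in tree.nodes.values():
            if node.parent is None:
                continue
            depth = tree.depth(node.name)
            for subset in node.subsets:
                rows.append(
                    {"clone_id": tree.clone_id, "subset": subset, "depth": depth}
                )
    long = pd.DataFrame(rows)
    if long.empty:
        return pd.DataFrame(columns=["clone_id", "subset", "mean_depth", "n_members"])
    per_tree = (
        long.groupby(["clone_id", "subset"], sort=True)["depth"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_depth", "size": "n_members"})
    )
    pooled = (
        long.groupby("subset", sort=True)["depth"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_depth", "size": "n_members"})
    )
    pooled.insert(0, "clone_id", "(pooled)")
    return pd.concat([per_tree, pooled], ignore_index=True)
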