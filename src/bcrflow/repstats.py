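"""V/J usage percentages, CDR3 amino-acid length statistics, and the
nonparametric test battery.

Usage is computed over all unique sequences (clone members and singletons)
as a percentage per individual, subset, and optional mutation stratum (the
CD27-CD21lo subset is conventionally split into unmutated/mutated).  Group
comparisons follow the standard decision rule: Mann-Whitney U for two
independent groups, Wilcoxon signed-rank for two paired groups,
Kruskal-Wallis respectively Friedman with Dunn's multiple-comparison
post-hoc for three or more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .germline import family_of, gene_of
from .shm import MUTATED_THRESHOLD


# ---------------------------------------------------------------------------
# usage and CDR3 length
# ---------------------------------------------------------------------------


def vj_usage(
    records: pd.DataFrame,
    segment: str = "V",
    level: str = "family",
    stratify_mutation: bool = False,
) -> pd.DataFrame:
    """Usage table: percent of unique sequences per gene or family.

    Requires ``mu_count`` when ``stratify_mutation`` is set (strata:
    unmutated <=2, mutated >2 mutations, per record).  Percentages sum to
    100 within each (individual, subset, stratum).
    """
    if records.empty:
        import warnings

        warnings.warn("empty record table: empty usage table returned")
        return pd.DataFrame(
            columns=["individual_id", "subset", "stratum", "level", "name", "percent"]
        )
    call_col = "v_call" if segment == "V" else "j_call"
    mapper = family_of if level == "family" else gene_of
    df = records.copy()
    df["name"] = df[call_col].map(mapper)
    if stratify_mutation:
        df["stratum"] = np.where(
            df["mu_count"] > MUTATED_THRESHOLD, "mutated", "unmutated"
        )
    else:
        df["stratum"] = "all"
    group_cols = ["individual_id", "subset", "stratum"]
    counts = (
        df.groupby(group_cols + ["name"], sort=True).size().rename("n").reset_index()
    )
    totals = counts.groupby(group_cols)["n"].transform("sum")
    counts["percent"] = 100.0 * counts["n"] / totals
    counts["level"] = level
    return counts[group_cols + ["level", "name", "n", "percent"]]


def cdr3_length_stats(records: pd.DataFrame, stratify_mutation: bool = False) -> pd.DataFrame:
    """Per-individual mean/median CDR3 amino-acid length per subset (and
    mutation stratum).  CDR3 is the junction minus the two conserved-residue
    codons; only productive records are valid here."""
    if "productive" in records.columns and not records["productive"].all():
        raise ValueError("non-productive records reached CDR3 length analysis")
    df = records.copy()
    df["cdr3_aa_length"] = (df["junction_length"] - 6) // 3
    if stratify_mutation:
        df["stratum"] = np.where(
            df["mu_count"] > MUTATED_THRESHOLD, "mutated", "unmutated"
        )
    else:
        df["stratum"] = "all"
    out = (
        df.groupby(["individual_id", "subset", "stratum"], sort=True)["cdr3_aa_length"]
        .agg(["mean", "median", "size"])
        .reset_index()
        .rename(columns={"size": "n"})
    )
    return out


# ---------------------------------------------------------------------------
# test battery
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    test: str
    groups: list[str]
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    note: str = ""


def _dunn_kruskal(values: list[np.ndarray], names: list[str]) -> list[TestResult]:
    """Dunn's all-pairs post-hoc after Kruskal-Wallis (tie-corrected rank
    z-statistics, two-sided, Bonferroni-adjusted over all contrasts)."""
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start : start + len(v)].mean())
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    results = []
    pairs = [(i, j) for i in range(len(values)) for j in range(i + 1, len(values))]
    m = len(pairs)
    for i, j in pairs:
        se = math.sqrt(
            (n_total * (n_total + 1) / 12 - tie_term)
            * (1 / len(values[i]) + 1 / len(values[j]))
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se else 0.0
        p = 2 * sps.norm.sf(abs(z))
        results.append(
            TestResult(
                test="dunn",
                groups=[names[i], names[j]],
                statistic=float(z),
                p_value=float(p),
                adjusted_p=float(min(1.0, p * m)),
            )
        )
    return results


def _dunn_friedman(block_matrix: np.ndarray, names: list[str]) -> list[TestResult]:
    """Dunn's all-pairs post-hoc after Friedman (within-block rank sums)."""
    n, k = block_matrix.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, block_matrix)
    rank_sums = ranks.sum(axis=0)
    se = math.sqrt(n * k * (k + 1) / 6)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    results = []
    for i, j in pairs:
        z = (rank_sums[i] - rank_sums[j]) / se
        p = 2 * sps.norm.sf(abs(z))
        results.append(
            TestResult(
                test="dunn",
                groups=[names[i], names[j]],
                statistic=float(z),
                p_value=float(p),
                adjusted_p=float(min(1.0, p * m)),
            )
        )
    return results


def run_group_tests(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    design: str,
    block_col: str | None = None,
) -> list[TestResult]:
    """Apply the matching nonparametric test for the declared design.

    ``design='independent'``: Mann-Whitney U (2 groups) or Kruskal-Wallis +
    Dunn (>2).  ``design='paired'``: Wilcoxon signed-rank (2) or Friedman +
    Dunn (>2); paired designs require ``block_col`` and incomplete blocks
    are dropped (noted in the result).  All tests are two-sided.
    """
    if design not in ("independent", "paired"):
        raise ValueError("design must be 'independent' or 'paired'")
    names = sorted(table[group_col].unique())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    results: list[TestResult] = []
    if design == "independent":
        values = [
            table.loc[table[group_col] == g, value_col].to_numpy() for g in names
        ]
        if len(names) == 2:
            stat, p = sps.mannwhitneyu(values[0], values[1], alternative="two-sided")
            results.append(TestResult("mann_whitney_u", names, float(stat), float(p)))
        else:
            stat, p = sps.kruskal(*values)
            results.append(TestResult("kruskal_wallis", names, float(stat), float(p)))
            results.extend(_dunn_kruskal(values, names))
        return results
    if block_col is None:
        raise ValueError("paired design requires block_col")
    wide = table.pivot_table(
        index=block_col, columns=group_col, values=value_col, aggfunc="mean"
    )[names]
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    note = f"{n_dropped} incomplete blocks dropped" if n_dropped else ""
    mat = complete.to_numpy()
    if len(names) == 2:
        diffs = mat[:, 0] - mat[:, 1]
        if np.all(diffs == 0):
            results.append(
                TestResult("wilcoxon_signed_rank", names, 0.0, 1.0, note=note)
            )
        else:
            stat, p = sps.wilcoxon(mat[:, 0], mat[:, 1])
            results.append(
                TestResult("wilcoxon_signed_rank", names, float(stat), float(p), note=note)
            )
    else:
        if np.all(mat == mat[:, [0]]):
            # no rank variation within any block: chi-square is identically 0
            results.append(TestResult("friedman", names, 0.0, 1.0, note=note))
        else:
            stat, p = sps.friedmanchisquare(*[mat[:, i] for i in range(mat.shape[1])])
            results.append(
                TestResult("friedman", names, float(stat), float(p), note=note)
            )
        results.extend(_dunn_friedman(mat, names))
    return results


# ---------------------------------------------------------------------------
# optional plotting
# ---------------------------------------------------------------------------


def usage_boxplot(usage: pd.DataFrame, path: str, title: str = "") -> None:
    """Boxplots (median, 25th/75th hinges) of usage percent per name across
    individuals, one panel per subset; written as PNG/SVG by extension."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subsets = sorted(usage["subset"].unique())
    fig, axes = plt.subplots(
        1, len(subsets), figsize=(4 * len(subsets), 4), squeeze=False
    )
    for ax, subset in zip(axes[0], subsets):
        sub = usage[usage["subset"] == subset]
        names = sorted(sub["name"].unique())
        data = [sub.loc[sub["name"] == n, "percent"].to_numpy() for n in names]
        ax.boxplot(data, tick_labels=names, whis=(25, 75))
        ax.set_title(subset)
        ax.set_ylabel("% of unique sequences")
        ax.tick_params(axis="x", rotation=90)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
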