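"""End-to-end orchestration: simulate -> (reads -> preprocess -> annotate)
-> clonal -> diversity -> shm -> stats -> lineage, under a single config
with deterministic per-stage seeds and a run manifest.

Every stochastic stage derives its seed from the master seed and the stage
name, so a rerun with the same config produces byte-identical outputs.
Raw reads are emitted and preprocessed per individual x subset library,
mirroring demultiplexed sequencing of sorted populations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import clonal, diversity, lineage, preprocess, repstats, shm, simulate
from .germline import load_reference
from .io import read_airr, write_airr, write_fastq

STAGES = (
    "simulate",
    "preprocess",
    "annotate",
    "clonal",
    "diversity",
    "shm",
    "stats",
    "lineage",
)


@dataclass
class PipelineConfig:
    """Single configuration object for a full run."""

    output_dir: str = "bcrflow_run"
    master_seed: int = 1
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    input_airr: str | None = None  # skip simulate/preprocess/annotate
    n_individuals: int = 3
    n_cells: int | None = None  # override per-subset cell count
    use_reads: bool = False  # emit+preprocess reads instead of direct records
    subsample_depth: int = 3195
    bootstrap_iterations: int = 1000
    mutation_threshold: int = 2
    clone_size_bounds: tuple[int, int, int, int, int] = (2, 5, 6, 20, 21)
    threshold_override: float | None = None
    error_rate: float = 0.002
    reads_per_molecule: float = 5.0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.clone_size_bounds, list):
            cfg.clone_size_bounds = tuple(cfg.clone_size_bounds)
        return cfg

    def seed_for(self, stage: str) -> int:
        return simulate.derive_seed(self.master_seed, stage)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    The manifest records per-stage seeds, output file hashes, and warnings
    (subsample shortfalls, threshold fallbacks, skipped comparisons).
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    reference = load_reference()

    def register(stage: str, paths: list[str], **info) -> None:
        manifest["stages"][stage] = {
            "seed": config.seed_for(stage),
            "complete": True,
            **info,
        }
        for p in paths:
            manifest["outputs"][os.path.relpath(p, out)] = _sha256(p)

    records: pd.DataFrame | None = None
    ledger = None

    if config.input_airr:
        records = read_airr(config.input_airr)
        manifest["stages"]["simulate"] = {"complete": True, "source": config.input_airr}
    elif config.stages.get("simulate", True):
        profiles = None
        sharing = None
        if config.n_cells is not None:
            profiles = {
                name: dataclasses.replace(prof, n_cells=config.n_cells)
                for name, prof in simulate.DEFAULT_PROFILES.items()
            }
            # scale the default sharing plan with the reduced depth
            f = config.n_cells / 3195
            neg_pos, neg_pb, pos_pb = (
                round(44 * f),
                round(4 * f),
                round(8 * f),
            )
            triple = min(round(3 * f), neg_pos, neg_pb, pos_pb)
            sharing = simulate.SharingPlan(neg_pos, neg_pb, pos_pb, triple)
        records, ledger = simulate.simulate_cohort(
            reference,
            profiles=profiles,
            sharing=sharing,
            n_individuals=config.n_individuals,
            rng_seed=config.seed_for("simulate"),
        )
        rec_path = os.path.join(out, "simulated_records.tsv")
        led_path = os.path.join(out, "truth_ledger.tsv")
        write_airr(records, rec_path)
        ledger.to_csv(led_path, sep="\t", index=False)
        register("simulate", [rec_path, led_path], n_records=len(records))
    else:
        raise ValueError("no input: enable the simulate stage or set input_airr")

    if config.use_reads and config.stages.get("preprocess", True) and ledger is not None:
        read_cfg = simulate.ReadEmissionConfig(
            error_rate=config.error_rate,
            reads_per_molecule_mean=config.reads_per_molecule,
        )
        unique_tables = []
        fastq_paths = []
        for (individual, subset), grp in records.groupby(["individual_id", "subset"]):
            reads = simulate.emit_reads(
                grp, read_cfg, config.seed_for(f"preprocess:{individual}:{subset}")
            )
            fq = os.path.join(out, f"reads_{individual}_{subset}.fastq")
            write_fastq(reads, fq)
            fastq_paths.append(fq)
            parsed = preprocess.load_fastq(
                fq, preprocess.ReadLayout(primer_length=len(read_cfg.primer))
            )
            unique = preprocess.preprocess_reads(parsed)
            unique["individual_id"] = individual
            unique["subset"] = subset
            unique_tables.append(unique)
        unique_df = pd.concat(unique_tables, ignore_index=True)
        uniq_path = os.path.join(out, "unique_sequences.tsv")
        unique_df.to_csv(uniq_path, sep="\t", index=False)
        register("preprocess", fastq_paths + [uniq_path], n_unique=len(unique_df))

        if config.stages.get("annotate", True):
            from .annotate import annotate_table

            records = annotate_table(unique_df, reference)
            ann_path = os.path.join(out, "annotated_records.tsv")
            write_airr(records, ann_path)
            register(
                "annotate",
                [ann_path],
                n_unassignable=records.attrs.get("n_unassignable", 0),
                n_nonproductive=records.attrs.get("n_nonproductive", 0),
            )
    else:
        for stage in ("preprocess", "annotate"):
            manifest["stages"][stage] = {
                "complete": True,
                "skipped": "records used directly",
            }

    # --- clonal inference (full data, per individual) ----------------------
    if not config.stages.get("clonal", True):
        raise ValueError("the clonal stage is required by all downstream stages")
    clone_sets: dict[str, clonal.CloneSet] = {}
    full_records = []
    threshold_rows = []
    for individual, grp in records.groupby("individual_id", sort=True):
        with_clones, clone_set, dist = clonal.infer_clones(
            grp, threshold=config.threshold_override
        )
        if dist is not None and dist.fallback:
            manifest["warnings"].append(
                f"{individual}: unimodal/sparse distance distribution, "
                f"fallback threshold {clone_set.threshold}"
            )
        clone_sets[individual] = clone_set
        full_records.append(with_clones)
        threshold_rows.append(
            {
                "individual_id": individual,
                "threshold": clone_set.threshold,
                "bimodal": dist.bimodal if dist else False,
                "n_distances": len(dist.distances) if dist else 0,
            }
        )
    records = pd.concat(full_records, ignore_index=True)
    clone_path = os.path.join(out, "records_with_clones.tsv")
    write_airr(records, clone_path)
    thr_path = os.path.join(out, "thresholds.tsv")
    pd.DataFrame(threshold_rows).to_csv(thr_path, sep="\t", index=False)
    register("clonal", [clone_path, thr_path], n_clones=sum(
        len(cs.clones_of_size(2)) for cs in clone_sets.values()
    ))

    # --- subsampled clustering for sharing + diversity ---------------------
    subsampled = []
    for (individual, subset), grp in records.groupby(
        ["individual_id", "subset"], sort=True
    ):
        sample, shortfall = clonal.subsample_uniform(
            grp,
            config.subsample_depth,
            simulate.derive_seed(
                config.master_seed, f"subsample:{individual}:{subset}"
            ),
        )
        if shortfall:
            manifest["warnings"].append(
                f"{individual}/{subset}: only {len(sample)} records at "
                f"subsample depth {config.subsample_depth}"
            )
        subsampled.append(sample)
    sub_records = pd.concat(subsampled, ignore_index=True)
    sub_with_clones = []
    shared_rows = []
    for individual, grp in sub_records.groupby("individual_id", sort=True):
        with_clones, clone_set, _ = clonal.infer_clones(
            grp, threshold=clone_sets[individual].threshold
        )
        sub_with_clones.append(with_clones)
        summary = clonal.shared_clones(clone_set)
        row = {"individual_id": individual, "triple": summary.triple_count}
        for (a, b), n in summary.pair_counts.items():
            row[f"{a}|{b}"] = n
        shared_rows.append(row)
    sub_records = pd.concat(sub_with_clones, ignore_index=True)
    shared_path = os.path.join(out, "shared_clones.tsv")
    pd.DataFrame(shared_rows).to_csv(shared_path, sep="\t", index=False)

    if config.stages.get("diversity", True):
        report = diversity.diversity_report(
            sub_records,
            n_iterations=config.bootstrap_iterations,
            rng_seed=config.seed_for("diversity"),
            subsample_depth=config.subsample_depth,
        )
        div_path = os.path.join(out, "diversity.tsv")
        report.to_csv(div_path, sep="\t", index=False)
        register("diversity", [div_path, shared_path])

    if config.stages.get("shm", True):
        records = shm.add_mutation_columns(records, reference)
        summary = shm.subset_mutation_summary(records)
        rs = shm.rs_ratio(records)
        mut_path = os.path.join(out, "mutation_summary.tsv")
        rs_path = os.path.join(out, "rs_ratio.tsv")
        summary.to_csv(mut_path, sep="\t", index=False)
        rs.per_individual.to_csv(rs_path, sep="\t", index=False)
        comparisons = []
        for x, y in [
            ("CD27neg_CD21lo", "CD27pos_CD21lo"),
            ("CD27neg_CD21lo", "PB"),
            ("CD27pos_CD21lo", "PB"),
        ]:
            comp = shm.shared_vs_nonshared_mutation(records, clone_sets, x, y)
            manifest["warnings"].extend(comp.skipped)
            if not comp.per_individual.empty:
                comparisons.append(comp.per_individual)
        cmp_path = os.path.join(out, "shared_vs_nonshared.tsv")
        if comparisons:
            pd.concat(comparisons, ignore_index=True).to_csv(
                cmp_path, sep="\t", index=False
            )
        else:
            pd.DataFrame().to_csv(cmp_path, sep="\t", index=False)
        register("shm", [mut_path, rs_path, cmp_path],
                 n_rs_excluded=rs.n_excluded_zero_silent)

    if config.stages.get("stats", True):
        if "mu_count" not in records.columns:
            records = shm.add_mutation_columns(records, reference)
        usage_v = repstats.vj_usage(records, "V", "family", stratify_mutation=False)
        usage_j = repstats.vj_usage(records, "J", "family", stratify_mutation=False)
        cdr3 = repstats.cdr3_length_stats(records)
        paths = []
        for name, df in [
            ("usage_v_family.tsv", usage_v),
            ("usage_j_family.tsv", usage_j),
            ("cdr3_length.tsv", cdr3),
        ]:
            p = os.path.join(out, name)
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        register("stats", paths)

    if config.stages.get("lineage", True):
        trees = []
        newick_paths = []
        for individual, clone_set in clone_sets.items():
            eligible = lineage.select_tree_clones(clone_set)
            grp = records[records["individual_id"] == individual]
            for clone_id in eligible:
                members = grp[grp["clone_id"] == clone_id]
                germline = members["germline_alignment"].iloc[0]
                tree = lineage.build_tree(members, germline, clone_id)
                trees.append(tree)
        depth = lineage.subset_depth_report(trees)
        depth_path = os.path.join(out, "lineage_depth.tsv")
        depth.to_csv(depth_path, sep="\t", index=False)
        nwk_path = os.path.join(out, "lineage_trees.nwk")
        with open(nwk_path, "w") as fh:
            for tree in trees:
                fh.write(tree.to_newick() + "\n")
        register("lineage", [depth_path, nwk_path], n_trees=len(trees))

    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
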