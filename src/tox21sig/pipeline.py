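"""End-to-end orchestration: simulate/ingest -> clean -> aggregate ->
signatures -> benchmark -> promiscuity -> cluster -> reports.

Every stage writes tab-delimited artifacts under the output directory and
the final manifest records the configuration, seed, package version, and
a SHA-256 checksum of every output file, so a run is reproducible and
auditable. Identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import benchmark_all
from .cleaning import (
    aggregate_by_cid,
    annotate_concentration,
    clean_records,
    compute_pac50_cutoff,
    dense_set_table,
    partition_dense_sets,
)
from .cluster import cluster_compounds, cluster_report
from .datamodel import CATEGORIES, ConfigError
from .features import featurize_table, modeling_features
from .io import (
    read_assay_annotations,
    read_screen_table,
    read_substance_meta,
    write_assay_annotations,
    write_screen_table,
    write_signature_matrix,
    write_substance_meta,
)
from .promiscuity import cluster_promiscuity, profile_table
from .signatures import build_signatures, summarize_categories
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration: exactly one of synthetic generation or file inputs."""

    outdir: str | Path = "results/run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    #: file inputs: paths for records / substance meta / assay annotations
    records_path: str | Path | None = None
    meta_path: str | Path | None = None
    annotations_path: str | Path | None = None
    strict: bool = True
    randomized_reps: int = 10
    cluster_target_size: int = 20
    fingerprint_kind: str = "ECFP6"
    cluster_fingerprint_kind: str = "FCFP6"
    n_bins: int = 10

    def validate(self) -> None:
        have_files = any(
            p is not None for p in (self.records_path, self.meta_path, self.annotations_path)
        )
        if self.synthetic is not None and have_files:
            raise ConfigError("configure either synthetic generation or input paths, not both")
        if self.synthetic is None:
            paths = {
                "records_path": self.records_path,
                "meta_path": self.meta_path,
                "annotations_path": self.annotations_path,
            }
            missing = [k for k, v in paths.items() if v is None]
            if missing:
                raise ConfigError(f"missing input paths: {missing}")
            absent = [str(v) for v in paths.values() if not Path(v).exists()]
            if absent:
                raise ConfigError(f"input files not found: {absent}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    Stage order and per-stage row counts are logged; any failure halts
    with the stage name in the exception message.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # -- stage: inputs ------------------------------------------------------
    if config.synthetic is not None:
        data = generate_dataset(config.synthetic, seed=config.seed)
        meta, records, annotations = data["meta"], data["records"], data["annotations"]
        raw = outdir / "raw"
        raw.mkdir(exist_ok=True)
        write_screen_table(records, raw / "records.tsv")
        write_substance_meta(meta, raw / "substances.tsv")
        write_assay_annotations(annotations, raw / "assays.tsv")
        _write_tsv(data["compounds"], raw / "compounds.tsv")
        _write_tsv(data["truth"].assay_tokens, raw / "truth_assays.tsv")
        outputs += [raw / n for n in (
            "records.tsv", "substances.tsv", "assays.tsv", "compounds.tsv", "truth_assays.tsv"
        )]
        structures = data["compounds"][["cid", "smiles"]]
    else:
        records = read_screen_table(config.records_path, strict=config.strict)
        meta = read_substance_meta(config.meta_path)
        annotations = read_assay_annotations(config.annotations_path)
        structures = (
            meta.dropna(subset=["cid", "smiles"])
            .drop_duplicates("cid")[["cid", "smiles"]]
            .reset_index(drop=True)
        )
    log.info("stage inputs: %d records, %d substances, %d assays",
             len(records), len(meta), len(annotations))

    # -- stage: clean + aggregate -------------------------------------------
    clean, report = clean_records(records, meta)
    cutoff = compute_pac50_cutoff(clean)
    activities = aggregate_by_cid(clean, meta)
    activities = annotate_concentration(activities, cutoff)
    dense_sets = partition_dense_sets(activities)
    log.info("stage clean: kept %d of %d SIDs; %d aggregate activities; %d dense sets",
             report.n_kept, report.n_input_sids, len(activities), len(dense_sets))
    (outdir / "clean").mkdir(exist_ok=True)
    _write_tsv(activities, outdir / "clean" / "activities.tsv")
    _write_tsv(report.per_assay, outdir / "clean" / "per_assay_counts.tsv")
    (outdir / "clean" / "filter_report.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n")
    (outdir / "clean" / "cutoff.json").write_text(json.dumps(cutoff.to_dict(), indent=2) + "\n")
    sets_df = dense_set_table(dense_sets)
    _write_tsv(sets_df, outdir / "clean" / "dense_sets.tsv")
    (outdir / "clean" / "dense_set_members.json").write_text(json.dumps(
        {s.set_label: {"cids": s.cids, "assays": s.assays} for s in dense_sets}, indent=0
    ) + "\n")
    outputs += [outdir / "clean" / n for n in (
        "activities.tsv", "per_assay_counts.tsv", "filter_report.json",
        "cutoff.json", "dense_sets.tsv", "dense_set_members.json",
    )]

    # -- stage: signatures ----------------------------------------------------
    matrices = build_signatures(activities, annotations, dense_sets)
    sig_dir = outdir / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for set_label, cats in matrices.items():
        for category, mat in cats.items():
            p = sig_dir / f"{set_label}_{category}.tsv"
            write_signature_matrix(mat, p)
            outputs.append(p)
    per_col, global_counts = summarize_categories(matrices)
    _write_tsv(per_col, sig_dir / "summary_columns.tsv")
    _write_tsv(global_counts, sig_dir / "summary_global.tsv")
    outputs += [sig_dir / "summary_columns.tsv", sig_dir / "summary_global.tsv"]

    # -- stage: benchmark ----------------------------------------------------
    feats = modeling_features(structures, kind=config.fingerprint_kind, n_bins=config.n_bins,
                              on_error="drop")
    bench = benchmark_all(matrices, feats, randomized_reps=config.randomized_reps,
                          seed=config.seed)
    _write_tsv(bench, outdir / "benchmark.tsv")
    outputs.append(outdir / "benchmark.tsv")
    log.info("stage benchmark: %d columns, mean ROC %.3f",
             len(bench), bench["roc"].mean())

    # -- stage: promiscuity --------------------------------------------------
    profiles = profile_table(activities, annotations)
    _write_tsv(profiles, outdir / "promiscuity.tsv", index=True)
    outputs.append(outdir / "promiscuity.tsv")

    # -- stage: clustering ---------------------------------------------------
    cluster_fps, _ = featurize_table(structures, kind=config.cluster_fingerprint_kind,
                                     on_error="drop")
    cluster_fps = {c: fp for c, fp in cluster_fps.items()
                   if c in set(activities["cid"])}
    assignment = cluster_compounds(cluster_fps, target_avg_size=config.cluster_target_size)
    smiles_of = structures.set_index("cid")["smiles"]
    creport = cluster_report(assignment, cluster_fps, smiles_of)
    cprom = cluster_promiscuity(assignment.labels, profiles)
    cdir = outdir / "clusters"
    cdir.mkdir(exist_ok=True)
    members = assignment.labels.reset_index()
    members["is_medoid"] = members["cid"].isin(assignment.medoids)
    _write_tsv(members, cdir / "assignment.tsv")
    _write_tsv(creport, cdir / "summary.tsv")
    _write_tsv(cprom, cdir / "promiscuity.tsv", index=True)
    outputs += [cdir / "assignment.tsv", cdir / "summary.tsv", cdir / "promiscuity.tsv"]
    log.info("stage cluster: %d clusters over %d compounds",
             assignment.n_clusters, len(assignment.labels))

    # -- report + manifest ---------------------------------------------------
    report_text = report_summary(
        filter_report=report, sets_table=sets_df, benchmark=bench, profiles=profiles,
    )
    (outdir / "report.txt").write_text(report_text)
    outputs.append(outdir / "report.txt")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = {
        "outdir": str(config.outdir),
        "seed": config.seed,
        "strict": config.strict,
        "randomized_reps": config.randomized_reps,
        "cluster_target_size": config.cluster_target_size,
        "fingerprint_kind": config.fingerprint_kind,
        "cluster_fingerprint_kind": config.cluster_fingerprint_kind,
        "n_bins": config.n_bins,
    }
    if config.synthetic is not None:
        d["synthetic"] = config.synthetic.to_dict()
    else:
        d["records_path"] = str(config.records_path)
        d["meta_path"] = str(config.meta_path)
        d["annotations_path"] = str(config.annotations_path)
    return d


def report_summary(
    filter_report,
    sets_table: pd.DataFrame,
    benchmark: pd.DataFrame,
    profiles: pd.DataFrame,
) -> str:
    """Human-readable run report: attrition, dense-set accounting, ROC
    summary per category, and promiscuity label counts."""
    lines = ["# Run summary", "", "## Filter attrition"]
    fr = filter_report.to_dict()
    lines += [f"- input SIDs: {fr['n_input_sids']}",
              f"- removed (purity): {fr['n_removed_purity']}",
              f"- removed (no CID): {fr['n_removed_unmapped']}",
              f"- kept: {fr['n_kept']}", ""]
    lines.append("## Dense matrix statistics")
    lines.append(sets_table.to_string(index=False))
    lines.append("")
    lines.append("## Benchmark (leave-one-out ROC)")
    scored = benchmark[benchmark["roc"].notna()]
    if len(scored):
        by_cat = scored.groupby("category")["roc"].agg(["count", "mean", "std"])
        lines.append(by_cat.round(3).to_string())
    skipped = benchmark[benchmark["skip_reason"] != ""]
    if len(skipped):
        lines.append(f"skipped columns: {len(skipped)} "
                     f"({skipped['skip_reason'].iloc[0]})")
    lines.append("")
    lines.append("## Promiscuity classes (compounds)")
    label_counts: dict[str, int] = {}
    for entry in profiles["labels"]:
        if entry:
            for lab in entry.split(";"):
                label_counts[lab] = label_counts.get(lab, 0) + 1
    for lab, cnt in sorted(label_counts.items()):
        lines.append(f"- {lab}: {cnt}")
    lines.append("")
    lines.append("## Quadrants (compounds)")
    for quad, cnt in profiles["quadrant"].value_counts().items():
        lines.append(f"- {quad}: {cnt}")
    return "\n".join(lines) + "\n"
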