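"""Stage orchestration: Fetch -> Aggregate -> Score -> Database -> Annotate -> denovo.

Every stage reads and writes the documented table formats, so running the
individual CLI subcommands with the same configuration produces outputs
identical to the one-shot ``complete`` run, which simply calls the same stage
functions in order. All randomness flows from the run seed.
"""

from __future__ import annotations

import json
import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from ._io import meta_lines, read_tsv, write_tsv
from .annotation import (
    FilterConfig,
    GeneModel,
    PanelFrequencies,
    filter_calls,
    load_gene_modes,
    write_candidates,
    write_rejections,
)
from .clustering import (
    BamDepthSource,
    cluster_split_reads,
    compute_cluster_features,
    read_clusters,
    write_clusters,
)
from .config import RunConfig
from .inheritance import InheritanceStatus, Parent, classify_inheritance, parental_support
from .junctiondb import (
    build_junction_consensus,
    classify_sv,
    dedup_calls,
    merge_cohort,
    read_calls,
    realign_junction,
    write_calls,
    write_calls_vcf,
    write_cohort_db,
)
from .scoring import ModelArtifact, load_model, save_model, score_clusters, train_model
from .splitread import (
    ExtractionStats,
    extract_split_reads,
    read_splitreads,
    relaxed_parent_filters,
    write_splitreads,
)

log = logging.getLogger(__name__)


@dataclass
class SampleSpec:
    sample_id: str
    alignment: str
    mother: str | None = None
    father: str | None = None


def read_manifest(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    specs = []
    for r in df.itertuples(index=False):
        specs.append(
            SampleSpec(
                sample_id=r.sample_id,
                alignment=r.alignment,
                mother=None if r.mother in ("-", "") else r.mother,
                father=None if r.father in ("-", "") else r.father,
            )
        )
    return specs


def load_fasta(path) -> dict:
    fa = pysam.FastaFile(str(path))
    seqs = {name: fa.fetch(name).upper() for name in fa.references}
    fa.close()
    return seqs


# ---------------------------------------------------------------------------
# stages


def fetch_stage(alignment, sample_id, out_path, cfg: RunConfig) -> int:
    stats = ExtractionStats()
    srs = extract_split_reads(
        alignment,
        params=cfg.read_filters,
        sample_id=sample_id,
        reference_fasta=cfg.reference,
        stats=stats,
    )
    write_splitreads(out_path, srs, cfg.read_filters)
    log.info("%s fetch: %d records -> %d split reads", sample_id, stats.records_seen, len(srs))
    return len(srs)


def aggregate_stage(splitreads_path, alignment, sample_id, out_path, cfg: RunConfig) -> int:
    srs = read_splitreads(splitreads_path, sample_id)
    clusters = cluster_split_reads(srs, cfg.cluster_tolerance, cfg.min_support)
    depth = BamDepthSource(alignment, cfg.reference)
    for c in clusters:
        compute_cluster_features(c, depth)
    depth.close()
    write_clusters(out_path, clusters, {"cluster_tolerance": cfg.cluster_tolerance})
    return len(clusters)


def score_stage(clusters_path, sample_id, model: ModelArtifact, out_path, cfg: RunConfig):
    clusters = read_clusters(clusters_path, sample_id)
    retained, dropped = score_clusters(
        clusters, model, threshold=cfg.score_threshold, min_support=cfg.min_support
    )
    write_clusters(out_path, retained, {"threshold": cfg.score_threshold or model.threshold_default})
    return len(clusters), len(retained)


def database_stage(entries, outdir, cfg: RunConfig):
    """entries: (sample_id, scored_clusters_path) per cohort sample.

    Merges retained clusters across samples, builds each merged cluster's
    junction consensus, realigns it, classifies the SV, and writes the cohort
    frequency database plus per-sample calls (TSV and symbolic-ALT VCF).
    """
    outdir = Path(outdir)
    reference = load_fasta(cfg.reference)
    panel = load_fasta(cfg.repeat_panel) if cfg.repeat_panel else None
    per_sample = [(sid, read_clusters(path, sid)) for sid, path in entries]
    records = merge_cohort(per_sample, cfg.cluster_tolerance)
    write_cohort_db(outdir / "cohort.db.tsv.gz", records, {"cohort_size": len(per_sample)})

    calls_by_sample: dict = {sid: [] for sid, _ in entries}
    for rec in records:
        junction = build_junction_consensus(rec.clusters)
        hits = realign_junction(
            junction,
            reference,
            panel,
            min_identity=cfg.min_identity,
            min_hit_len=cfg.min_hit_len,
        )
        for cluster in rec.clusters:
            call = classify_sv(
                cluster,
                hits,
                junction,
                max_event_span=cfg.max_event_span,
                min_ins_len=cfg.min_ins_len,
            )
            call.cohort_key = rec.cluster_key
            call.call_frequency = rec.call_frequency
            call.carrier_count = rec.carrier_count
            calls_by_sample[cluster.sample_id].append(call)

    contigs = {name: len(seq) for name, seq in reference.items()}
    n_calls = 0
    for sid, _ in entries:
        calls = dedup_calls(calls_by_sample[sid], cfg.cluster_tolerance)
        calls_by_sample[sid] = calls
        n_calls += len(calls)
        write_calls(outdir / f"{sid}.calls.tsv", calls, {"cohort_size": len(per_sample)})
        write_calls_vcf(outdir / f"{sid}.calls.vcf", calls, contigs)
    log.info("database: %d cohort records, %d calls", len(records), n_calls)
    return records, calls_by_sample


def annotate_stage(call_paths, outdir, cfg: RunConfig):
    """call_paths: (sample_id, calls_tsv) for the analysis samples (probands)."""
    outdir = Path(outdir)
    gene_model = _load_gene_model(cfg)
    panel_freqs = PanelFrequencies.from_tsv(cfg.panel_freqs, cfg.cluster_tolerance) if cfg.panel_freqs else None
    all_calls = []
    for sid, path in call_paths:
        all_calls.extend(read_calls(path))
    retained, rejections = filter_calls(all_calls, None, panel_freqs, cfg.filter, gene_model)
    write_candidates(outdir / "candidates.tsv", retained, gene_model, cfg.filter)
    write_rejections(outdir / "rejections.tsv", rejections, cfg.filter)
    log.info("annotate: %d calls -> %d candidates, %d rejected", len(all_calls), len(retained), len(rejections))
    return retained, rejections


def _load_gene_model(cfg: RunConfig) -> GeneModel:
    if cfg.gene_model is None:
        raise ValueError("gene_model path is required for the Annotate stage")
    path = str(cfg.gene_model)
    if path.endswith((".gff", ".gff3", ".gff3.gz")):
        model = GeneModel.from_gff3(path)
    else:
        model = GeneModel.from_bed12(path)
    if cfg.gene_modes:
        model.set_inheritance_modes(load_gene_modes(cfg.gene_modes))
    return model


INHERITANCE_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "svtype",
    "svlen",
    "support",
    "mother_clips",
    "mother_depth",
    "mother_verdict",
    "father_clips",
    "father_depth",
    "father_verdict",
    "inheritance",
]


def denovo_stage(specs, calls_dir, candidates_path, outdir, cfg: RunConfig):
    """Classify inheritance for every trio-proband call; write the de novo table.

    The inheritance table covers ALL calls of each trio proband (so inherited
    variants keep their classification even when the rarity filter removes
    them from the candidate list); the de novo candidate table is the
    intersection of filtered candidates and DE_NOVO calls.
    """
    outdir = Path(outdir)
    by_id = {s.sample_id: s for s in specs}
    relaxed = relaxed_parent_filters()
    rows = []
    denovo_keys = set()
    for spec in specs:
        if spec.mother is None and spec.father is None:
            continue
        calls = read_calls(Path(calls_dir) / f"{spec.sample_id}.calls.tsv")
        parents = {}
        depth_sources = {}
        for role, pid in (("mother", spec.mother), ("father", spec.father)):
            if pid is None or pid not in by_id:
                parents[role] = None
            else:
                parents[role] = by_id[pid].alignment
                depth_sources[role] = BamDepthSource(by_id[pid].alignment, cfg.reference)
        for call in calls:
            sups = {}
            for role, parent_enum in (("mother", Parent.MOTHER), ("father", Parent.FATHER)):
                if parents.get(role) is None:
                    sups[role] = None
                else:
                    sups[role] = parental_support(
                        call,
                        parents[role],
                        parent_enum,
                        tolerance=cfg.cluster_tolerance,
                        relaxed_params=relaxed,
                        min_parent_clips=cfg.min_parent_clips,
                        min_parent_depth=cfg.min_parent_depth,
                        reference_fasta=cfg.reference,
                        depth_source=depth_sources.get(role),
                    )
            status = classify_inheritance(sups["mother"], sups["father"])
            call.inheritance = status.value
            if status is InheritanceStatus.DE_NOVO:
                denovo_keys.add((call.sample_id, call.chrom, call.bp1, call.svtype.value))
            m, f = sups["mother"], sups["father"]
            rows.append(
                (
                    call.sample_id,
                    call.chrom,
                    call.bp1 + 1,
                    call.svtype.value,
                    "" if call.svlen is None else call.svlen,
                    call.support,
                    "" if m is None else m.supporting_clips,
                    "" if m is None else m.depth_at_site,
                    "" if m is None else m.verdict.value,
                    "" if f is None else f.supporting_clips,
                    "" if f is None else f.depth_at_site,
                    "" if f is None else f.verdict.value,
                    status.value,
                )
            )
        for src in depth_sources.values():
            src.close()
    inheritance_df = pd.DataFrame(rows, columns=INHERITANCE_COLUMNS)
    params = {"min_parent_clips": cfg.min_parent_clips, "min_parent_depth": cfg.min_parent_depth}
    write_tsv(inheritance_df, outdir / "inheritance.tsv", meta_lines("denovo", params))

    cand = read_tsv(candidates_path, dtype={"chrom": str, "sample_id": str})
    if len(cand):
        keys = [
            (r.sample_id, r.chrom, int(r.pos) - 1, r.svtype) in denovo_keys
            for r in cand.itertuples(index=False)
        ]
        denovo_df = cand[pd.Series(keys, index=cand.index)].copy()
        denovo_df["inheritance"] = InheritanceStatus.DE_NOVO.value
    else:
        denovo_df = cand
    write_tsv(denovo_df, outdir / "denovo.tsv", meta_lines("denovo", params))
    log.info("denovo: %d trio-proband calls classified, %d de novo candidates", len(rows), len(denovo_df))
    return inheritance_df, denovo_df


# ---------------------------------------------------------------------------
# model provisioning and training


def train_default_model(seed: int, workdir=None) -> ModelArtifact:
    """Train the default scorer from the documented simulator recipe."""
    from .simulate import labeled_training_set

    if workdir is None:
        with tempfile.TemporaryDirectory(prefix="crypticsv-train-") as tmp:
            examples = labeled_training_set(seed, tmp)
    else:
        examples = labeled_training_set(seed, workdir)
    return train_model(examples, seed=seed)


def run_train(labeled_tsv, seed: int, out_path) -> ModelArtifact:
    """Train from a labeled feature TSV (feature columns + ``label``)."""
    from .clustering import FEATURE_NAMES, FeatureVector
    from .scoring import LabeledExample

    df = read_tsv(labeled_tsv)
    missing = [c for c in FEATURE_NAMES + ["label"] if c not in df.columns]
    if missing:
        raise ValueError(f"labeled table is missing columns: {missing}")
    examples = [
        LabeledExample(
            FeatureVector(*[float(getattr(r, n)) for n in FEATURE_NAMES]),
            str(r.label),
            source_id=str(i),
        )
        for i, r in enumerate(df.itertuples(index=False))
    ]
    artifact = train_model(examples, seed=seed)
    save_model(artifact, out_path)
    return artifact


# ---------------------------------------------------------------------------
# complete


def run_complete(cfg: RunConfig, manifest_path, outdir) -> dict:
    """Run every stage over a cohort manifest; returns the run summary.

    The manifest is a TSV with columns (sample_id, alignment, mother, father);
    '-' marks an absent parent. Samples that appear as someone's parent are
    cohort members (they contribute to call frequencies and get calls) but are
    not analysis probands for the Annotate stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / ".incomplete"
    marker.write_text("run in progress\n")
    summary: dict = {"samples": {}, "stages": {}}
    try:
        specs = read_manifest(manifest_path)
        if len({s.sample_id for s in specs}) != len(specs):
            raise ValueError("duplicate sample_id in manifest")
        cfg.write_yaml(outdir / "run_config.yaml")

        if cfg.model_path:
            model = load_model(cfg.model_path)
        else:
            model = train_default_model(cfg.seed)
            save_model(model, outdir / "model.pkl")
        summary["stages"]["train"] = dict(model.metrics)

        scored_entries = []
        for spec in specs:
            sid = spec.sample_id
            sr_path = outdir / f"{sid}.splitreads.tsv.gz"
            cl_path = outdir / f"{sid}.clusters.tsv.gz"
            sc_path = outdir / f"{sid}.clusters.scored.tsv.gz"
            n_sr = fetch_stage(spec.alignment, sid, sr_path, cfg)
            n_cl = aggregate_stage(sr_path, spec.alignment, sid, cl_path, cfg)
            n_in, n_ret = score_stage(cl_path, sid, model, sc_path, cfg)
            summary["samples"][sid] = {
                "split_reads": n_sr,
                "clusters": n_cl,
                "retained_clusters": n_ret,
            }
            scored_entries.append((sid, sc_path))

        records, calls_by_sample = database_stage(scored_entries, outdir, cfg)
        summary["stages"]["database"] = {
            "cohort_records": len(records),
            "calls": sum(len(v) for v in calls_by_sample.values()),
        }

        parent_ids = {s.mother for s in specs} | {s.father for s in specs}
        probands = [s for s in specs if s.sample_id not in parent_ids]
        call_paths = [(s.sample_id, outdir / f"{s.sample_id}.calls.tsv") for s in probands]
        retained, rejections = annotate_stage(call_paths, outdir, cfg)
        summary["stages"]["annotate"] = {
            "proband_calls": sum(len(read_calls(p)) for _, p in call_paths),
            "candidates": len(retained),
            "rejected": len(rejections),
        }

        inheritance_df, denovo_df = denovo_stage(specs, outdir, outdir / "candidates.tsv", outdir, cfg)
        summary["stages"]["denovo"] = {
            "classified_calls": int(len(inheritance_df)),
            "de_novo_candidates": int(len(denovo_df)),
        }
    except Exception as exc:
        log.error("run aborted: %s", exc)
        raise
    else:
        marker.unlink()
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
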