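"""End-to-end orchestration: QC -> circularity -> 16S taxonomy -> classification.

`run_pipeline` consumes the on-disk inputs (contig FASTA, depth TSV,
annotation TSV, 16S reference FASTA, optional amplicon profile and external
score tables), runs every stage with the configured thresholds, and writes one
TSV per stage plus a JSON summary. Identical config and inputs produce
byte-identical outputs. `make_demo` generates a small synthetic dataset, runs
the pipeline on it, and records output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .circular import detect_terminal_overlap
from .classify import (
    T4SS_COMPONENTS,
    ClassifierParams,
    build_features,
    classify_replicon,
    score_t4ss,
    assign_contig_taxonomy,
)
from .io import (
    read_annotations,
    read_contigs,
    read_depths,
    read_external_scores,
    read_profile,
    read_reference_db,
    write_annotations,
    write_depths,
    write_fasta,
    write_gff3,
    write_profile,
    write_reference_db,
)
from .qc import compute_stats, detect_low_complexity, filter_high_quality
from .ssu import (
    RankTiers,
    SSUGene,
    assign_taxonomy,
    compare_profiles,
    curate_reference_db,
    profile_community,
    tier_counts,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, record: str | None, cause: Exception):
        self.stage = stage
        self.record = record
        self.cause = cause
        where = f" (record {record!r})" if record else ""
        super().__init__(f"stage {stage!r} failed{where}: {cause}")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run; YAML-loadable."""

    contigs_fasta: str
    depth_tsv: str
    annotation_tsv: str
    reference_db_fasta: str
    outdir: str
    amplicon_profile_tsv: str | None = None
    external_scores_tsv: str | None = None
    min_depth: float = 5.0  # strict > for the high-quality filter
    ssu_min_depth: float = 5.0  # inclusive >= for 16S eligibility
    low_complexity_min_run: int = 1000
    low_complexity_max_frac: float = 0.5
    min_overlap: int = 1000
    max_overlap: int = 50_000
    max_mismatch_frac: float = 0.02
    min_len_16s: int = 1400
    cluster_identity: float = 97.0
    min_coverage: float = 95.0
    tiers: RankTiers = field(default_factory=RankTiers)
    min_fraction: float = 0.25
    taxonomy_min_identity: float = 80.0
    taxonomy_min_coverage: float = 80.0
    phage_score_cutoff: float = 0.8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "tiers" in raw and isinstance(raw["tiers"], dict):
            raw["tiers"] = RankTiers(**raw["tiers"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def extract_ssu_genes(
    contigs: dict[str, str],
    annotations: pd.DataFrame,
    depths: pd.Series,
    min_len: int = 1400,
    min_depth: float = 5.0,
) -> list[SSUGene]:
    """Pull 16S gene sequences out of contigs via their SSU_RRNA annotation rows.

    Keeps full-length genes (>= ``min_len`` bp) on contigs with mean depth
    >= ``min_depth``. Coordinates are 1-based inclusive; minus-strand rows are
    reverse-complemented.
    """
    from Bio.Seq import Seq

    genes: list[SSUGene] = []
    rows = annotations[annotations["label"] == "SSU_RRNA"]
    for _, row in rows.iterrows():
        cid = row["contig_id"]
        if cid not in contigs or cid not in depths.index:
            continue
        if float(depths[cid]) < min_depth:
            continue
        start, end = int(row["start"]), int(row["end"])
        if end - start + 1 < min_len:
            continue
        seq = contigs[cid][start - 1 : end]
        if row["strand"] == "-":
            seq = str(Seq(seq).reverse_complement())
        genes.append(
            SSUGene(
                gene_id=str(row["gene_id"]),
                contig_id=str(cid),
                sequence=seq,
                contig_depth=float(depths[cid]),
            )
        )
    return genes


def _stats_row(label: str, stats) -> dict:
    return {
        "set": label,
        "n_contigs": stats.n_contigs,
        "total_bp": stats.total_bp,
        "bp_ge_50kbp": stats.bp_ge_50kbp,
        "largest_bp": stats.largest_bp,
        "n50": stats.n50,
        "n_ge_1mbp": stats.n_ge_1mbp,
        "n_circular": stats.n_circular,
        "n_cds": stats.n_cds,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the per-stage TSVs; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": dataclasses.asdict(config)}
    logger.info("phyllotig %s starting; outputs -> %s", __version__, outdir)

    # ---- stage 1: assembly QC -------------------------------------------
    stage = "assembly_qc"
    try:
        depths = read_depths(config.depth_tsv)
        contigs = read_contigs(config.contigs_fasta)
        annotations = read_annotations(config.annotation_tsv)
        n_cds = int((annotations["label"] != "SSU_RRNA").sum()) if len(annotations) else 0
        stats_all = compute_stats(contigs, n_cds=n_cds)
        artifacts = [
            c.contig_id
            for c in contigs
            if detect_low_complexity(c, config.low_complexity_max_frac, config.low_complexity_min_run)
        ]
        clean = [c for c in contigs if c.contig_id not in set(artifacts)]
        hq = filter_high_quality(clean, depths, min_depth=config.min_depth)
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineStageError(stage, None, exc) from exc
    logger.info(
        "%s: %d contigs in, %d artifacts removed, %d high-quality (depth > %g)",
        stage, len(contigs), len(artifacts), len(hq), config.min_depth,
    )

    # ---- stage 2: circularity -------------------------------------------
    stage = "circularity"
    circ_rows = []
    trimmed: dict[str, str] = {}
    contig = None
    try:
        for contig in hq:
            if contig.length <= 2 * config.min_overlap:
                contig.circular = False
                continue
            res = detect_terminal_overlap(
                contig.sequence,
                min_overlap=config.min_overlap,
                max_overlap=config.max_overlap,
                max_mismatch_frac=config.max_mismatch_frac,
            )
            contig.circular = res.is_circular
            if res.is_circular:
                circ_rows.append(
                    {
                        "contig_id": contig.contig_id,
                        "raw_length": contig.length,
                        "overlap_len": res.overlap_len,
                        "mismatch_frac": round(res.mismatch_frac, 6),
                        "trimmed_length": res.trimmed_length,
                    }
                )
                trimmed[contig.contig_id] = contig.sequence[: res.trimmed_length]
    except Exception as exc:
        raise PipelineStageError(stage, contig.contig_id if contig else None, exc) from exc
    stats_hq = compute_stats(hq) if hq else None
    circ_df = pd.DataFrame(circ_rows, columns=["contig_id", "raw_length", "overlap_len", "mismatch_frac", "trimmed_length"])
    circ_df.to_csv(outdir / "circular_contigs.tsv", sep="\t", index=False)
    write_fasta(outdir / "circular_trimmed.fasta", trimmed)
    stats_df = pd.DataFrame(
        [_stats_row("all_contigs", stats_all)] + ([_stats_row("high_quality", stats_hq)] if stats_hq else [])
    )
    stats_df.to_csv(outdir / "assembly_stats.tsv", sep="\t", index=False)
    logger.info("%s: %d of %d high-quality contigs circular", stage, len(circ_rows), len(hq))

    # ---- stage 3: 16S taxonomy and community profile ---------------------
    stage = "ssu_taxonomy"
    try:
        raw_db = read_reference_db(config.reference_db_fasta)
        db = curate_reference_db(raw_db, min_len=config.min_len_16s, cluster_identity=config.cluster_identity)
        hq_seqs = {c.contig_id: c.sequence for c in hq}
        genes = extract_ssu_genes(
            hq_seqs, annotations, depths, min_len=config.min_len_16s, min_depth=config.ssu_min_depth
        )
        assignments = assign_taxonomy(genes, db, tiers=config.tiers, min_coverage=config.min_coverage)
        tiers_df = tier_counts(assignments, genes)
        profile = profile_community(assignments, genes, weighting="per_contig")
    except Exception as exc:
        raise PipelineStageError(stage, None, exc) from exc
    if not genes:
        logger.warning("%s: no 16S genes passed the length/depth filters; profile is empty", stage)
    tiers_df.to_csv(outdir / "rank_tiers.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "ref_id": a.ref_id,
                "identity": round(a.identity, 3),
                "query_coverage": round(a.query_coverage, 3),
                "resolved_rank": a.resolved_rank,
                "novelty_flag": a.novelty_flag,
                "lineage": ";".join(a.lineage),
            }
            for a in assignments
        ],
        columns=["gene_id", "ref_id", "identity", "query_coverage", "resolved_rank", "novelty_flag", "lineage"],
    ).to_csv(outdir / "ssu_assignments.tsv", sep="\t", index=False)
    write_profile(outdir / "community_profile.tsv", profile)
    logger.info(
        "%s: %d curated references, %d 16S genes, %d assigned, %d taxa profiled",
        stage, len(db), len(genes), len(assignments), len(profile.taxa),
    )

    comparison = None
    if config.amplicon_profile_tsv:
        amplicon = read_profile(config.amplicon_profile_tsv)
        comparison = compare_profiles(profile, amplicon, threshold=1.0)
        report["profile_comparison"] = {
            "n_above_1pct_amplicon": len(comparison.above_threshold_in_b),
            "n_shared": comparison.n_present_in_a,
            "combined_abundance_metagenome": round(comparison.combined_abundance_a, 3),
            "combined_abundance_amplicon": round(comparison.combined_abundance_b, 3),
        }
        logger.info(
            "%s: %d amplicon taxa >1%%, %d shared with the metagenome profile",
            stage, len(comparison.above_threshold_in_b), comparison.n_present_in_a,
        )

    # ---- stage 4: replicon classification and T4SS -----------------------
    stage = "replicon_classification"
    params = ClassifierParams(phage_score_cutoff=config.phage_score_cutoff)
    ext = read_external_scores(config.external_scores_tsv) if config.external_scores_tsv else None
    call_rows = []
    t4ss_rows = []
    contig = None
    try:
        by_contig = dict(tuple(annotations.groupby("contig_id")))
        for contig in hq:
            ann = by_contig.get(contig.contig_id, annotations.iloc[0:0])
            scores = ext.loc[contig.contig_id].to_dict() if ext is not None and contig.contig_id in ext.index else None
            fv = build_features(ann, contig, external_scores=scores)
            call = classify_replicon(fv, params)
            taxon = None
            if len(ann):
                taxon = assign_contig_taxonomy(
                    ann,
                    min_fraction=config.min_fraction,
                    min_identity=config.taxonomy_min_identity,
                    min_coverage=config.taxonomy_min_coverage,
                )
            call_rows.append(
                {
                    "contig_id": contig.contig_id,
                    "length": contig.length,
                    "circular": contig.circular,
                    "class": call.klass,
                    "evidence": ";".join(call.evidence),
                    "taxon_rank": taxon.rank if taxon else None,
                    "taxon_name": taxon.name if taxon else None,
                }
            )
            if fv.n_virB_components or fv.has_virD4:
                t4 = score_t4ss(ann, contig_id=contig.contig_id)
                t4ss_rows.append(
                    {
                        "contig_id": contig.contig_id,
                        "status": t4.status,
                        "n_components": len(t4.present),
                        "missing": ";".join(t4.missing),
                        "duplicated": ";".join(f"{c}x{n}" for c, n in sorted(t4.duplicated.items())),
                        "reference_order_conserved": t4.order_diff.reference_order_conserved if t4.order_diff else None,
                        **{c: (c in t4.present) for c in T4SS_COMPONENTS},
                    }
                )
    except Exception as exc:
        raise PipelineStageError(stage, contig.contig_id if contig else None, exc) from exc
    calls_df = pd.DataFrame(
        call_rows,
        columns=["contig_id", "length", "circular", "class", "evidence", "taxon_rank", "taxon_name"],
    )
    calls_df.to_csv(outdir / "replicon_calls.tsv", sep="\t", index=False)
    pd.DataFrame(t4ss_rows).to_csv(outdir / "t4ss_report.tsv", sep="\t", index=False)
    class_counts = calls_df["class"].value_counts().to_dict() if len(calls_df) else {}
    logger.info("%s: %s", stage, class_counts or "no high-quality contigs")

    report.update(
        {
            "n_contigs": stats_all.n_contigs,
            "n_artifacts_removed": len(artifacts),
            "n_high_quality": len(hq),
            "n_circular": len(circ_rows),
            "n_curated_references": len(db),
            "n_ssu_genes": len(genes),
            "n_ssu_assigned": len(assignments),
            "n_profiled_taxa": len(profile.taxa),
            "class_counts": class_counts,
            "n_t4ss_contigs": len(t4ss_rows),
        }
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_demo(seed: int, outdir: str | Path) -> dict[str, str]:
    """Write a small ground-truthed demo dataset, run the pipeline on it, and
    record SHA-256 checksums of every output (the determinism contract)."""
    from .io import write_external_scores
    from .synthetic import CommunityConfig, generate_community, generate_reference_db, make_amplicon_profile

    outdir = Path(outdir)
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    db = generate_reference_db(n_taxa=6, seed=seed)
    config = CommunityConfig(seed=seed, n_taxa=6, n_contigs=12)
    community = generate_community(config, db)

    write_fasta(datadir / "contigs.fasta", community.contigs)
    write_depths(datadir / "depths.tsv", community.depths)
    write_annotations(datadir / "annotations.tsv", community.annotations)
    write_gff3(datadir / "annotations.gff3", community.annotations, {c: len(s) for c, s in community.contigs.items()})
    write_reference_db(datadir / "reference_16s.fasta", [t.as_ssu_record() for t in db])
    write_external_scores(datadir / "external_scores.tsv", community.external_scores.set_index("contig_id"))
    community.truth.to_csv(datadir / "truth.tsv", sep="\t", index=False)
    amplicon = make_amplicon_profile(community, seed=seed + 1)
    write_profile(datadir / "amplicon_profile.tsv", amplicon)

    pipeline_config = PipelineConfig(
        contigs_fasta=str(datadir / "contigs.fasta"),
        depth_tsv=str(datadir / "depths.tsv"),
        annotation_tsv=str(datadir / "annotations.tsv"),
        reference_db_fasta=str(datadir / "reference_16s.fasta"),
        external_scores_tsv=str(datadir / "external_scores.tsv"),
        amplicon_profile_tsv=str(datadir / "amplicon_profile.tsv"),
        outdir=str(outdir / "pipeline"),
        seed=seed,
    )
    pipeline_config.to_yaml(outdir / "config.yaml")
    run_pipeline(pipeline_config)

    checksums = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted((outdir / "pipeline").glob("*"))
        if p.is_file()
    }
    with open(outdir / "checksums.json", "w") as fh:
        json.dump(checksums, fh, indent=2, sort_keys=True)
    return checksums
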