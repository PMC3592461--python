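"""End-to-end orchestration: annotation build and expression analysis.

These functions are the library surface the command-line interface wraps;
they are importable and fully deterministic for a given input set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from .core import (
    Parameters,
    PositionalClass,
    Probe,
    ProbeStatus,
    TranscriptCluster,
    TranscriptModel,
)
from .expression import (
    GroupDesign,
    compute_gni,
    differential_expression,
    quantile_normalize,
    splice_index,
    summarize,
)
from .io import ExpressionMatrix
from .mapping import build_genome_index, map_probes

logger = logging.getLogger("lncexon")


@dataclass
class AnnotationResult:
    clusters: list[TranscriptCluster]
    probes: list[Probe]
    summary: dict[str, int]
    lncrnas_kept: list[TranscriptModel] = field(default_factory=list)


def build_annotation(
    genome: dict[str, str] | str | Path,
    probes: list[Probe],
    coding_sets: Sequence[Sequence[TranscriptModel]],
    lncrnas: Sequence[TranscriptModel],
    params: Parameters = Parameters(),
) -> AnnotationResult:
    """Run the full annotation build: map probes, exclude coding-exon
    overlaps, length-filter lncRNAs, cluster, segment, assign, prune.

    The summary mirrors the annotation-overview bookkeeping: total
    probes, probes on protein-coding exons, probes assigned to lncRNA
    probe sets, surviving probe sets / clusters / lncRNA transcripts.
    """
    index = build_genome_index(genome, params)
    probes = map_probes(probes, index)
    n_unique = sum(p.status == ProbeStatus.UNASSIGNED for p in probes)
    logger.info("mapped probes: %d/%d uniquely placed", n_unique, len(probes))

    mask = ann.build_coding_exon_mask(*coding_sets)
    placed = [p for p in probes if p.status == ProbeStatus.UNASSIGNED]
    ann.filter_probes_against_coding(placed, mask)
    n_coding = sum(p.status == ProbeStatus.CODING_OVERLAP for p in probes)
    logger.info("coding-exon filter: %d probes excluded", n_coding)

    kept = ann.filter_short_lncrnas(lncrnas, params)
    logger.info("length filter: %d/%d lncRNAs kept", len(kept), len(lncrnas))
    clusters = ann.cluster_lncrnas(kept)
    ann.segment_all(clusters)
    probes, clusters = ann.assign_probes(probes, clusters, params)
    logger.info("annotation: %d clusters, %d probe sets",
                len(clusters), sum(len(c.probesets) for c in clusters))

    summary = {
        "total_probes": len(probes),
        "protein_coding_probes": n_coding,
        "lncrna_probes": sum(p.status == ProbeStatus.ASSIGNED for p in probes),
        "probe_sets": sum(len(c.probesets) for c in clusters),
        "transcript_clusters": len(clusters),
        "lncrna_transcripts": sum(len(c.members) for c in clusters),
    }
    return AnnotationResult(clusters, probes, summary, lncrnas_kept=kept)


def classification_table(
    clusters: Sequence[TranscriptCluster],
    coding_genes: Sequence[TranscriptModel],
    params: Parameters = Parameters(),
) -> pd.DataFrame:
    """One row per cluster: positional category, nearest gene, distance."""
    rows = []
    for c in clusters:
        pc: PositionalClass = ann.classify_cluster(c, coding_genes, params)
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "category": pc.category.value,
                "nearest_gene": pc.nearest_gene_id or "",
                "distance": pc.distance,
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "category",
                                       "nearest_gene", "distance"])


# ---------------------------------------------------------------------------
# Expression analysis

@dataclass
class AnalysisResult:
    probeset_expr: ExpressionMatrix
    cluster_expr: ExpressionMatrix
    gni: pd.DataFrame
    splice: pd.DataFrame
    de: pd.DataFrame
    report: pd.DataFrame


def feature_maps_from_clusters(
    clusters: Sequence[TranscriptCluster],
) -> tuple[dict[str, list[str]], dict[str, list[str]], dict[str, str]]:
    """(probe-set map, cluster map, probe-set -> cluster) in the
    annotation's deterministic order.  The cluster map pools *all*
    retained probes of the cluster."""
    ps_map: dict[str, list[str]] = {}
    cl_map: dict[str, list[str]] = {}
    ps_to_cl: dict[str, str] = {}
    for c in clusters:
        cl_map[c.cluster_id] = []
        for ps in c.probesets:
            ps_map[ps.probeset_id] = list(ps.probe_ids)
            ps_to_cl[ps.probeset_id] = c.cluster_id
            cl_map[c.cluster_id].extend(ps.probe_ids)
    return ps_map, cl_map, ps_to_cl


def feature_maps_from_tables(
    assignment: pd.DataFrame, meta: pd.DataFrame
) -> tuple[dict[str, list[str]], dict[str, list[str]], dict[str, str]]:
    """Rebuild the feature maps from probe_assignment.tsv +
    meta_probeset.tsv (annotation order given by the meta table)."""
    by_ps: dict[str, list[str]] = {}
    for probe_id, ps in zip(assignment["probe_id"], assignment["probeset_id"]):
        by_ps.setdefault(str(ps), []).append(str(probe_id))
    ps_map: dict[str, list[str]] = {}
    cl_map: dict[str, list[str]] = {}
    ps_to_cl: dict[str, str] = {}
    for cluster_id, ps_ids in zip(meta["cluster_id"], meta["probeset_ids"]):
        ids = [s for s in str(ps_ids).split(",") if s]
        cl_map[str(cluster_id)] = []
        for ps in ids:
            ps_map[ps] = by_ps.get(ps, [])
            ps_to_cl[ps] = str(cluster_id)
            cl_map[str(cluster_id)].extend(ps_map[ps])
    return ps_map, cl_map, ps_to_cl


def analyze(
    matrix: ExpressionMatrix,
    ps_map: Mapping[str, list[str]],
    cl_map: Mapping[str, list[str]],
    ps_to_cl: Mapping[str, str],
    design: GroupDesign,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    si_threshold: float = 1.0,
) -> AnalysisResult:
    """quantile-normalize -> summarize (probe set + cluster) -> GNI ->
    Splice Index -> cluster-level differential expression.

    The report lists gene-level hits (|log2 fc| > fc_threshold, FDR <
    fdr_threshold) and exon-level hits (|SI| > si_threshold, FDR <
    fdr_threshold); thresholds only affect this convenience report.
    """
    design.check_samples(matrix.sample_ids)
    norm = quantile_normalize(matrix)
    probeset_expr = summarize(norm, ps_map)
    cluster_expr = summarize(norm, cl_map)
    gni = compute_gni(probeset_expr, cluster_expr, ps_to_cl)
    splice = pd.DataFrame(
        [r.__dict__ for r in splice_index(gni, design, ps_to_cl)],
        columns=["probeset_id", "cluster_id", "si", "p_value", "fdr"],
    )
    de = pd.DataFrame(
        [r.__dict__ for r in differential_expression(cluster_expr, design)],
        columns=["cluster_id", "log2_fold_change", "p_value", "fdr"],
    )
    rows = []
    for _, r in de.iterrows():
        if abs(r["log2_fold_change"]) > fc_threshold and r["fdr"] < fdr_threshold:
            rows.append(("gene", r["cluster_id"], r["cluster_id"],
                         r["log2_fold_change"], r["fdr"]))
    for _, r in splice.iterrows():
        if abs(r["si"]) > si_threshold and r["fdr"] < fdr_threshold:
            rows.append(("exon", r["probeset_id"], r["cluster_id"],
                         r["si"], r["fdr"]))
    report = pd.DataFrame(
        rows, columns=["level", "feature_id", "cluster_id", "log2_change", "fdr"]
    )
    return AnalysisResult(probeset_expr, cluster_expr, gni, splice, de, report)


def write_analysis(result: AnalysisResult, outdir: str | Path) -> dict[str, Path]:
    from .io import write_expression_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["probeset_expression.tsv"] = outdir / "probeset_expression.tsv"
    write_expression_matrix(result.probeset_expr, paths["probeset_expression.tsv"],
                            id_label="probeset_id")
    paths["cluster_expression.tsv"] = outdir / "cluster_expression.tsv"
    write_expression_matrix(result.cluster_expr, paths["cluster_expression.tsv"],
                            id_label="cluster_id")
    paths["gni.tsv"] = outdir / "gni.tsv"
    write_expression_matrix(
        ExpressionMatrix(result.gni, scale="log2"), paths["gni.tsv"],
        id_label="probeset_id",
    )
    for name, df in (("splice_results.tsv", result.splice),
                     ("de_results.tsv", result.de),
                     ("filtered_report.tsv", result.report)):
        paths[name] = outdir / name
        df.to_csv(paths[name], sep="\t", index=False, float_format="%.10g")
    return paths
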