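"""Building the custom two-level lncRNA annotation.

The pipeline stages implemented here:

1. drop lncRNAs with spliced length <= 200 nt (the size floor of the
   lncRNA definition);
2. build a per-strand mask of all protein-coding exons and discard every
   uniquely mapped probe overlapping it on the same strand;
3. combine same-strand lncRNAs whose exons overlap into *transcript
   clusters* (connected components of the exon-overlap graph);
4. segment each cluster's exonic footprint into *probe sets* — maximal
   sub-intervals not interrupted by any member's exon boundary;
5. assign probes to probe sets by full containment and prune empty probe
   sets, then empty clusters;
6. classify each cluster by its position relative to protein-coding
   genes into seven categories (sense, antisense, intronic,
   bidirectional, extension, close, intergenic).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    Biotype,
    GenomicInterval,
    Parameters,
    PositionalCategory,
    PositionalClass,
    Probe,
    ProbeSet,
    ProbeStatus,
    TranscriptCluster,
    TranscriptModel,
    ValidationError,
)


# ---------------------------------------------------------------------------
# lncRNA length filter

def filter_short_lncrnas(
    transcripts: Sequence[TranscriptModel], params: Parameters
) -> list[TranscriptModel]:
    """Keep lncRNAs with spliced length >= ``min_lncrna_spliced_length``
    (default 201 bp, i.e. strictly longer than 200 nt).  Spliced length is
    the sum of exon lengths, not the genomic span.  Order preserved."""
    return [
        t
        for t in transcripts
        if t.spliced_length >= params.min_lncrna_spliced_length
    ]


# ---------------------------------------------------------------------------
# Coding-exon mask

@dataclass
class CodingExonMask:
    """Per (chrom, strand) maximally merged union of coding exons."""

    intervals: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # (starts, ends), sorted, disjoint, non-adjacent

    def overlaps(self, iv: GenomicInterval) -> bool:
        """True if ``iv`` shares >= 1 bp with a masked exon on the same strand."""
        key = (iv.chrom, iv.strand)
        if key not in self.intervals:
            return False
        starts, ends = self.intervals[key]
        i = int(np.searchsorted(starts, iv.start, side="right")) - 1
        if i >= 0 and ends[i] > iv.start:
            return True
        return i + 1 < len(starts) and starts[i + 1] < iv.end


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    intervals.sort()
    starts: list[int] = []
    ends: list[int] = []
    for s, e in intervals:
        if starts and s <= ends[-1]:  # merge touching intervals too
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def build_coding_exon_mask(
    *coding_sets: Sequence[TranscriptModel],
) -> CodingExonMask:
    """Union of all exons from all coding annotation sources, merged per
    (chrom, strand)."""
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for source in coding_sets:
        for t in source:
            if t.biotype != Biotype.CODING:
                raise ValidationError(
                    f"{t.transcript_id}: coding mask input must have biotype "
                    f"'coding', got {t.biotype.value!r}"
                )
            for e in t.exons:
                raw.setdefault((e.chrom, e.strand), []).append((e.start, e.end))
    mask = CodingExonMask()
    for key, ivs in raw.items():
        mask.intervals[key] = _merge(ivs)
    return mask


def filter_probes_against_coding(
    probes: Sequence[Probe], mask: CodingExonMask
) -> list[Probe]:
    """Flag uniquely mapped probes overlapping a coding exon (same strand,
    >= 1 bp) as ``coding_overlap``; all other probes pass unchanged."""
    for p in probes:
        if p.status != ProbeStatus.UNASSIGNED or p.alignment is None:
            raise ValidationError(
                f"{p.probe_id}: coding filter applies only to uniquely "
                f"placed probes (status 'unassigned'), got {p.status.value!r}"
            )
        if mask.overlaps(p.alignment):
            p.status = ProbeStatus.CODING_OVERLAP
    return list(probes)


# ---------------------------------------------------------------------------
# Transcript clustering

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_lncrnas(transcripts: Sequence[TranscriptModel]) -> list[TranscriptCluster]:
    """Combine same-strand lncRNAs whose exons overlap (>= 1 bp) into
    transcript clusters — connected components of the exon-overlap graph.

    Overlap is exon-level, not span-level: transcripts nested inside
    another transcript's intron without shared exonic sequence stay
    separate.  Cluster ids are deterministic: clusters sorted by (chrom,
    strand, span start) and numbered TC000001, ...
    """
    for t in transcripts:
        if t.biotype != Biotype.LNCRNA:
            raise ValidationError(
                f"{t.transcript_id}: clustering expects biotype 'lncRNA'"
            )
    uf = _UnionFind(len(transcripts))
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(transcripts):
        by_key.setdefault((t.chrom, t.strand), []).append(i)
    for indices in by_key.values():
        # sweep over exons sorted by start: an exon starting before the
        # running max end overlaps some earlier exon of the run
        exon_records = sorted(
            ((e.start, e.end, i) for i in indices for e in transcripts[i].exons)
        )
        run_end = -1
        run_rep = -1
        for s, e, i in exon_records:
            if s < run_end:
                uf.union(run_rep, i)
                run_end = max(run_end, e)
            else:
                run_rep = i
                run_end = e
    components: dict[int, list[int]] = {}
    for i in range(len(transcripts)):
        components.setdefault(uf.find(i), []).append(i)
    clusters = []
    for member_idx in components.values():
        members = [transcripts[i] for i in member_idx]
        members.sort(key=lambda t: (t.span.start, t.span.end, t.transcript_id))
        clusters.append(
            TranscriptCluster("", members[0].chrom, members[0].strand, members)
        )
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.span.start, c.span.end))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"TC{i:06d}"
    return clusters


# ---------------------------------------------------------------------------
# Probe-set segmentation

def segment_probesets(cluster: TranscriptCluster) -> list[ProbeSet]:
    """Cut the cluster's exonic footprint at every member exon boundary.

    The footprint F is the union of all member exons; the boundary set B
    holds every exon start and end of every member.  Probe sets are the
    maximal sub-intervals of F whose interiors contain no point of B,
    sorted by start and numbered ``<cluster_id>_PS<ordinal>``.
    """
    boundaries: set[int] = set()
    footprint: list[tuple[int, int]] = []
    for t in cluster.members:
        for e in t.exons:
            boundaries.add(e.start)
            boundaries.add(e.end)
            footprint.append((e.start, e.end))
    starts, ends = _merge(footprint)
    cuts = sorted(boundaries)
    probesets: list[ProbeSet] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        inner = [c for c in cuts if s < c < e]
        edges = [s] + inner + [e]
        for a, b in zip(edges, edges[1:]):
            probesets.append(
                ProbeSet(
                    probeset_id="",
                    interval=GenomicInterval(cluster.chrom, a, b, cluster.strand),
                    cluster_id=cluster.cluster_id,
                )
            )
    probesets.sort(key=lambda ps: ps.interval.start)
    for i, ps in enumerate(probesets, start=1):
        ps.probeset_id = f"{cluster.cluster_id}_PS{i:03d}"
    return probesets


def segment_all(clusters: Sequence[TranscriptCluster]) -> None:
    for c in clusters:
        c.probesets = segment_probesets(c)


# ---------------------------------------------------------------------------
# Probe assignment

def assign_probes(
    probes: Sequence[Probe],
    clusters: Sequence[TranscriptCluster],
    params: Parameters,
) -> tuple[list[Probe], list[TranscriptCluster]]:
    """Assign retained probes to probe sets by full containment on the
    same strand, then delete probe sets without probes and clusters
    without probe sets.

    Probes straddling a probe-set boundary are left unassigned: a
    straddling 25-mer would measure two exonic segments at once.
    """
    # same-strand probe sets of different clusters are disjoint, so a
    # per-(chrom, strand) sorted list supports binary-search containment
    by_key: dict[tuple[str, str], list[ProbeSet]] = {}
    for c in clusters:
        if not c.probesets:
            raise ValidationError(f"{c.cluster_id}: segment before assigning probes")
        for ps in c.probesets:
            by_key.setdefault((ps.interval.chrom, ps.interval.strand), []).append(ps)
    sorted_sets: dict[tuple[str, str], tuple[list[int], list[ProbeSet]]] = {}
    for key, sets in by_key.items():
        sets.sort(key=lambda ps: ps.interval.start)
        for a, b in zip(sets, sets[1:]):
            if b.interval.start < a.interval.end:
                raise ValidationError(
                    f"internal consistency error: probe sets {a.probeset_id} "
                    f"and {b.probeset_id} overlap on the same strand"
                )
        sorted_sets[key] = ([ps.interval.start for ps in sets], sets)

    for p in probes:
        if p.status != ProbeStatus.UNASSIGNED:
            continue
        iv = p.alignment
        key = (iv.chrom, iv.strand)
        if key not in sorted_sets:
            continue
        starts, sets = sorted_sets[key]
        i = bisect_right(starts, iv.start) - 1
        if i >= 0 and sets[i].interval.end >= iv.end:
            ps = sets[i]
            p.status = ProbeStatus.ASSIGNED
            p.probeset_id = ps.probeset_id
            ps.probe_ids.append(p.probe_id)
            p.validate()

    pruned: list[TranscriptCluster] = []
    for c in clusters:
        c.probesets = [
            ps for ps in c.probesets if len(ps.probe_ids) >= params.min_probes_per_set
        ]
        if c.probesets:
            pruned.append(c)
    return list(probes), pruned


# ---------------------------------------------------------------------------
# Positional classification

def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two spans on the same chromosome (0 if they
    overlap or touch)."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _head_to_head(cluster_span: GenomicInterval, gene_span: GenomicInterval,
                  gene_strand: str) -> bool:
    """Divergent-promoter geometry: opposite strands, non-overlapping and
    each element's 5' end is the end nearest the other element."""
    if gene_strand == "+":
        # gene 5' at gene.start; cluster must sit upstream on '-' so its
        # 5' end (its right end) faces the gene
        return cluster_span.strand == "-" and cluster_span.end <= gene_span.start
    return cluster_span.strand == "+" and cluster_span.start >= gene_span.end


def classify_cluster(
    cluster: TranscriptCluster,
    coding_genes: Sequence[TranscriptModel],
    params: Parameters,
) -> PositionalClass:
    """Classify a cluster relative to protein-coding genes.

    Categories are evaluated in precedence order sense > antisense >
    intronic > bidirectional > extension > close > intergenic, so they
    partition the clusters.  Each coding transcript is treated as its
    own gene; ``distance`` is the minimal gap between the cluster span
    and the nearest gene span (0 when overlapping),
    ``nearest_gene_id`` the gene attaining it.
    """
    span = cluster.span
    exons = [e for t in cluster.members for e in t.exons]

    best: Optional[tuple[int, str]] = None  # (gap, gene_id)
    category_hits: dict[PositionalCategory, list[tuple[int, str]]] = {}

    for gene in coding_genes:
        if gene.chrom != span.chrom:
            continue
        gspan = gene.span
        gap = _gap(span, GenomicInterval(gspan.chrom, gspan.start, gspan.end, span.strand))
        if best is None or gap < best[0]:
            best = (gap, gene.transcript_id)

        exon_overlap = any(
            ge.start < ce.end and ce.start < ge.end
            for ge in gene.exons
            for ce in exons
        )
        same = gene.strand == span.strand
        if exon_overlap:
            cat = PositionalCategory.SENSE if same else PositionalCategory.ANTISENSE
            category_hits.setdefault(cat, []).append((0, gene.transcript_id))
            continue
        # entirely inside one intron of this gene?
        intronic = any(
            a.end <= span.start and span.end <= b.start
            for a, b in zip(gene.exons, gene.exons[1:])
        )
        if intronic:
            category_hits.setdefault(PositionalCategory.INTRONIC, []).append(
                (0, gene.transcript_id)
            )
            continue
        span_overlap = gspan.start < span.end and span.start < gspan.end
        if span_overlap or gap <= 0 or gap >= params.proximate_distance:
            continue
        if same:
            cat = PositionalCategory.EXTENSION
        elif _head_to_head(span, gspan, gene.strand):
            cat = PositionalCategory.BIDIRECTIONAL
        else:
            cat = PositionalCategory.CLOSE
        category_hits.setdefault(cat, []).append((gap, gene.transcript_id))

    order = (
        PositionalCategory.SENSE,
        PositionalCategory.ANTISENSE,
        PositionalCategory.INTRONIC,
        PositionalCategory.BIDIRECTIONAL,
        PositionalCategory.EXTENSION,
        PositionalCategory.CLOSE,
    )
    for cat in order:
        if cat in category_hits:
            # distance is the gap to the category-defining gene: 0 for the
            # overlap categories, the (positive, < proximate_distance) gap
            # for the proximate ones
            gap, gene_id = min(category_hits[cat])
            return PositionalClass(cat, gene_id, gap)
    if best is None:
        return PositionalClass(PositionalCategory.INTERGENIC, None, 0)
    return PositionalClass(PositionalCategory.INTERGENIC, best[1], best[0])


def classify_all(
    clusters: Sequence[TranscriptCluster],
    coding_genes: Sequence[TranscriptModel],
    params: Parameters,
) -> dict[str, PositionalClass]:
    return {
        c.cluster_id: classify_cluster(c, coding_genes, params) for c in clusters
    }
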