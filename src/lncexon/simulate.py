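"""Seeded synthetic fixtures with known ground truth.

Everything here is a pure function of its seed and parameters, so
fixtures regenerate byte-identically.  The default transcriptome is
built from deterministic "scenario blocks": successive coding genes each
carry one satellite lncRNA realizing one positional category (sense,
antisense, intronic, bidirectional, extension, close); the remaining
lncRNAs are intergenic, including a staggered overlapping pair (which
yields a cluster with several probe sets), one transcript of spliced
length < 200 nt (removed by the length filter) and one transcript left
without probes (whose cluster is deleted by the empty-probe-set rule).

Intensities follow a log-additive model: log2 I[probe i, sample s] =
mu + a_i + e[cluster(i), s] + delta[probeset(i), group(s)] + eps, with
probe affinities a_i ~ N(0, tau^2) and noise eps ~ N(0, sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Biotype,
    GenomicInterval,
    Parameters,
    Probe,
    ProbeSet,
    ProbeStatus,
    TranscriptCluster,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)
from .io import ExpressionMatrix
from .mapping import build_genome_index

_BASES = np.array(list("ACGT"))

# default model parameters of the intensity simulation
DEFAULT_MU = 7.0
DEFAULT_TAU = 0.5
DEFAULT_SIGMA = 0.25
DEFAULT_BASELINE_SD = 1.0


# ---------------------------------------------------------------------------
# Genome

def make_toy_genome(
    seed: int,
    n_chroms: int = 2,
    length: int = 60_000,
    dup_length: int = 0,
) -> dict[str, str]:
    """Uniform random ACGT chromosomes ``chr1..chrN`` of equal length.

    With ``dup_length`` > 0 a segment of that many bp from near the start
    of chr1 is copied near the end of the last chromosome, planting
    known multimapping 25-mers (transcript scenarios never use either
    region).
    """
    if length < 1000:
        raise ValidationError("chromosome length must be >= 1000")
    rng = np.random.default_rng(seed)
    genome = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=length))
        for i in range(n_chroms)
    }
    if dup_length:
        if dup_length > 500:
            raise ValidationError("dup_length must be <= 500")
        first, last = f"chr{1}", f"chr{n_chroms}"
        segment = genome[first][300 : 300 + dup_length]
        dst = length - dup_length - 500
        s = genome[last]
        genome[last] = s[:dst] + segment + s[dst + dup_length :]
    return genome


# ---------------------------------------------------------------------------
# Transcriptome

class _Allocator:
    """Sequential window allocator over the chromosomes, keeping clear of
    the first/last kilobases (where duplicated segments live)."""

    def __init__(self, genome: dict[str, str], head: int = 1000, tail: int = 1500,
                 gap: int = 1500):
        self.windows = [(name, len(seq) - tail) for name, seq in genome.items()]
        self.gap = gap
        self.idx = 0
        self.cursor = head
        self.head = head

    def alloc(self, size: int) -> tuple[str, int]:
        while self.idx < len(self.windows):
            name, limit = self.windows[self.idx]
            if self.cursor + size <= limit:
                start = self.cursor
                self.cursor += size + self.gap
                return name, start
            self.idx += 1
            self.cursor = self.head
        raise ValidationError("genome too small for the requested transcriptome")


def _exon_chain(start: int, exon_lens: Sequence[int], intron_lens: Sequence[int],
                chrom: str, strand: str) -> list[GenomicInterval]:
    exons = []
    pos = start
    for i, length in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + int(length), strand))
        if i < len(intron_lens):
            pos += int(length) + int(intron_lens[i])
    return exons


def _rand_lnc_structure(rng: np.random.Generator) -> tuple[list[int], list[int]]:
    n_exons = int(rng.integers(2, 5))  # 2-4 exons; >= 60% multi-exon overall
    exon_lens = [int(x) for x in rng.integers(100, 251, n_exons)]
    intron_lens = [int(x) for x in rng.integers(200, 601, n_exons - 1)]
    return exon_lens, intron_lens


_SATELLITE_KINDS = ("sense", "antisense", "intronic", "bidirectional",
                    "extension", "close")

#: margin left on both sides of every coding gene; satellites stay inside it
_MARGIN = 1500


def make_transcriptome(
    seed: int,
    genome: dict[str, str],
    n_coding: int = 6,
    n_lncrna: int = 14,
    overlap_fraction: float = 0.3,
    params: Parameters = Parameters(),
) -> list[TranscriptModel]:
    """Generate coding genes plus lncRNAs realizing every positional
    category, same-strand overlaps and the pruning special cases.

    Transcript ids encode their scenario (``LNC_sense_01`` etc.), which
    downstream fixtures use as planted truth.  Requires ``n_coding`` >=
    6 (one satellite per category) and ``n_lncrna`` >= 10.
    """
    if n_coding < len(_SATELLITE_KINDS):
        raise ValidationError(f"n_coding must be >= {len(_SATELLITE_KINDS)}")
    if n_lncrna < 10:
        raise ValidationError("n_lncrna must be >= 10")
    rng = np.random.default_rng(seed)
    alloc = _Allocator(genome)
    transcripts: list[TranscriptModel] = []

    # --- coding genes with one satellite lncRNA each -----------------------
    lnc_counter = 0
    for g in range(n_coding):
        strand = "+" if g % 2 == 0 else "-"
        n_exons = int(rng.integers(3, 6))
        exon_lens = [int(x) for x in rng.integers(150, 351, n_exons)]
        intron_lens = [int(x) for x in rng.integers(800, 1501, n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        chrom, wstart = alloc.alloc(span + 2 * _MARGIN)
        gstart = wstart + _MARGIN
        gexons = _exon_chain(gstart, exon_lens, intron_lens, chrom, strand)
        gene = TranscriptModel(f"GENE{g + 1:02d}", f"GENE{g + 1:02d}",
                               gexons, Biotype.CODING)
        transcripts.append(gene)
        if lnc_counter < min(len(_SATELLITE_KINDS), n_lncrna):
            kind = _SATELLITE_KINDS[lnc_counter]
            lnc_counter += 1
            transcripts.append(
                _satellite(rng, gene, kind, f"LNC_{kind}_{lnc_counter:02d}")
            )

    # --- intergenic lncRNAs ------------------------------------------------
    remaining = n_lncrna - lnc_counter
    n_special = 2  # one short, one probe-free
    n_pairs = int(round(overlap_fraction * n_lncrna / 2.0))
    n_pairs = max(0, min(n_pairs, (remaining - n_special) // 2))
    n_single = remaining - n_special - 2 * n_pairs

    for p in range(n_pairs):
        chrom, wstart = alloc.alloc(1200)
        strand = "+" if p % 2 == 0 else "-"
        if p == 0:
            # deterministic staggered pair -> >= 3 probe sets in one cluster
            a_exons = [GenomicInterval(chrom, wstart, wstart + 200, strand),
                       GenomicInterval(chrom, wstart + 400, wstart + 600, strand)]
            b_exons = [GenomicInterval(chrom, wstart + 100, wstart + 300, strand),
                       GenomicInterval(chrom, wstart + 450, wstart + 550, strand)]
        else:
            exon_lens, intron_lens = ([200, 180], [250])
            shift = int(rng.integers(50, 150))
            a_exons = _exon_chain(wstart, exon_lens, intron_lens, chrom, strand)
            b_exons = _exon_chain(wstart + shift, exon_lens, intron_lens,
                                  chrom, strand)
        transcripts.append(TranscriptModel(f"LNC_pair{p + 1:02d}_A",
                                           f"LNC_pair{p + 1:02d}_A",
                                           a_exons, Biotype.LNCRNA))
        transcripts.append(TranscriptModel(f"LNC_pair{p + 1:02d}_B",
                                           f"LNC_pair{p + 1:02d}_B",
                                           b_exons, Biotype.LNCRNA))

    for i in range(n_single):
        exon_lens, intron_lens = _rand_lnc_structure(rng)
        span = sum(exon_lens) + sum(intron_lens)
        chrom, wstart = alloc.alloc(span)
        strand = "+" if rng.integers(2) == 0 else "-"
        transcripts.append(
            TranscriptModel(
                f"LNC_intergenic_{i + 1:02d}", f"LNC_intergenic_{i + 1:02d}",
                _exon_chain(wstart, exon_lens, intron_lens, chrom, strand),
                Biotype.LNCRNA,
            )
        )

    # spliced length 180 <= 200 nt -> removed by the length filter
    chrom, wstart = alloc.alloc(200)
    transcripts.append(
        TranscriptModel(
            "LNC_short_01", "LNC_short_01",
            [GenomicInterval(chrom, wstart, wstart + 180, "+")], Biotype.LNCRNA,
        )
    )
    # valid lncRNA that the probe table skips -> empty probe sets -> pruned
    chrom, wstart = alloc.alloc(700)
    transcripts.append(
        TranscriptModel(
            "LNC_probefree_01", "LNC_probefree_01",
            _exon_chain(wstart, [150, 150], [300], chrom, "+"), Biotype.LNCRNA,
        )
    )
    return transcripts


def _satellite(rng: np.random.Generator, gene: TranscriptModel, kind: str,
               tid: str) -> TranscriptModel:
    """Place one lncRNA relative to ``gene`` so it classifies as ``kind``."""
    chrom = gene.chrom
    gspan = gene.span
    flip = {"+": "-", "-": "+"}
    gap = int(rng.integers(100, 801))
    if kind in ("sense", "antisense"):
        strand = gene.strand if kind == "sense" else flip[gene.strand]
        e0 = gene.exons[0]
        exons = [
            GenomicInterval(chrom, e0.start + 50, e0.start + 200, strand),
            GenomicInterval(chrom, e0.end + 100, e0.end + 250, strand),
        ]
    elif kind == "intronic":
        e0, e1 = gene.exons[0], gene.exons[1]
        exons = [
            GenomicInterval(chrom, e0.end + 100, e0.end + 200, strand := gene.strand),
            GenomicInterval(chrom, e0.end + 350, e0.end + 500, strand),
        ]
        assert exons[-1].end <= e1.start
    elif kind == "bidirectional":
        strand = flip[gene.strand]
        if gene.strand == "+":  # upstream of the gene 5' end, divergent
            end = gspan.start - gap
            exons = _exon_chain(end - 390, [120, 120], [150], chrom, strand)
        else:
            exons = _exon_chain(gspan.end + gap, [120, 120], [150], chrom, strand)
    elif kind in ("extension", "close"):
        strand = gene.strand if kind == "extension" else flip[gene.strand]
        if gene.strand == "+":  # downstream of the gene 3' end
            exons = _exon_chain(gspan.end + gap, [120, 120], [150], chrom, strand)
        else:
            exons = _exon_chain(gspan.start - gap - 390, [120, 120], [150],
                                chrom, strand)
    else:  # pragma: no cover
        raise ValidationError(f"unknown satellite kind {kind!r}")
    return TranscriptModel(tid, tid, exons, Biotype.LNCRNA)


# ---------------------------------------------------------------------------
# Probe table

def make_probe_table(
    seed: int,
    genome: dict[str, str],
    transcripts: Sequence[TranscriptModel],
    spacing: int = 35,
    n_unmapped: int = 8,
    n_multimapped: int = 6,
    probe_free_ids: Iterable[str] = (),
    params: Parameters = Parameters(),
) -> list[Probe]:
    """Tile 25-mers across exons (sense strand of each transcript) and
    add known-unmapped (random, verified absent) and known-multimapped
    (copied from a duplicated genome segment) probes.

    Probe ids encode the planted truth: ``P...`` tiles, ``RND...``
    unmapped, ``MM...`` multimapped.  Tiles landing on duplicated
    sequence would be multimapped too, but the default scenario layout
    keeps transcripts clear of those regions.
    """
    k = params.probe_length
    index = build_genome_index(genome, params)
    skip = set(probe_free_ids)
    positions: dict[tuple[str, int, str], None] = {}
    for t in transcripts:
        if t.transcript_id in skip:
            continue
        for e in t.exons:
            for s in range(e.start, e.end - k + 1, spacing):
                positions.setdefault((e.chrom, s, e.strand), None)

    probes: list[Probe] = []
    for i, (chrom, start, strand) in enumerate(sorted(positions), start=1):
        seq = genome[chrom][start : start + k].upper()
        if strand == "-":
            seq = reverse_complement(seq)
        probes.append(Probe(f"P{i:05d}", seq))

    if n_multimapped:
        found: list[str] = []
        used: set[str] = set()
        for seq, hits in index.lookup.items():
            if seq in used:
                continue
            if index.n_hits(seq) >= 2:
                found.append(seq)
                used.add(seq)
                used.add(reverse_complement(seq))
                if len(found) == n_multimapped:
                    break
        if len(found) < n_multimapped:
            raise ValidationError(
                f"genome contains only {len(found)} multimapping {k}-mers; "
                f"plant a duplicated segment (dup_length) to get more"
            )
        for i, seq in enumerate(found, start=1):
            probes.append(Probe(f"MM{i:03d}", seq))

    rng = np.random.default_rng(seed)
    for i in range(1, n_unmapped + 1):
        while True:
            seq = "".join(rng.choice(_BASES, size=k))
            if index.n_hits(seq) == 0:
                break
        probes.append(Probe(f"RND{i:03d}", seq))
    return probes


# ---------------------------------------------------------------------------
# Intensity simulation

@dataclass
class SimulationTruth:
    """Planted ground truth of one simulated experiment."""

    seed: int
    clusters: list[TranscriptCluster]
    probes: list[Probe]
    #: probeset_id -> (delta log2, group label receiving the shift)
    affected_probesets: dict[str, tuple[float, str]] = field(default_factory=dict)
    #: cluster_id -> (delta log2, group label receiving the shift)
    affected_clusters: dict[str, tuple[float, str]] = field(default_factory=dict)
    mu: float = DEFAULT_MU
    tau: float = DEFAULT_TAU
    sigma: float = DEFAULT_SIGMA
    baseline_sd: float = DEFAULT_BASELINE_SD
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def probeset_to_cluster(self) -> dict[str, str]:
        return {
            ps.probeset_id: c.cluster_id
            for c in self.clusters
            for ps in c.probesets
        }


def make_two_group_design(
    n_per_group: int = 5, labels: tuple[str, str] = ("g1", "g2")
) -> dict[str, str]:
    """Sample -> group mapping ``{label}_1..{label}_n`` for two groups."""
    design: dict[str, str] = {}
    for label in labels:
        for i in range(1, n_per_group + 1):
            design[f"{label}_{i}"] = label
    return design


def simulate_intensities(
    seed: int,
    truth: SimulationTruth,
    design: Mapping[str, str],
) -> ExpressionMatrix:
    """Draw a linear-scale probe x sample intensity matrix from the
    log-additive model.

    Assigned probes receive their cluster's expression plus any planted
    probe-set (splice) or cluster (differential expression) effect;
    unassigned probes get background (mu + affinity + noise) only.
    """
    samples = list(design)
    if not samples:
        raise ValidationError("empty design")
    groups = [design[s] for s in samples]
    rng = np.random.default_rng(seed)

    ps_to_cluster = truth.probeset_to_cluster()
    cluster_ids = [c.cluster_id for c in truth.clusters]
    probe_ids = [p.probe_id for p in truth.probes]

    affinities = rng.normal(0.0, truth.tau, len(truth.probes))
    baselines = dict(zip(cluster_ids, rng.normal(0.0, truth.baseline_sd,
                                                 len(cluster_ids))))
    noise = rng.normal(0.0, truth.sigma, (len(truth.probes), len(samples)))

    log2 = np.full((len(truth.probes), len(samples)), truth.mu, dtype=float)
    log2 += affinities[:, None]
    log2 += noise
    for i, probe in enumerate(truth.probes):
        if probe.status != ProbeStatus.ASSIGNED:
            continue
        cl = ps_to_cluster.get(probe.probeset_id)
        if cl is None:
            raise ValidationError(
                f"{probe.probe_id}: probeset {probe.probeset_id!r} not in truth"
            )
        log2[i] += baselines[cl]
        cdelta = truth.affected_clusters.get(cl)
        pdelta = truth.affected_probesets.get(probe.probeset_id)
        for s, group in enumerate(groups):
            if cdelta is not None and group == cdelta[1]:
                log2[i, s] += cdelta[0]
            if pdelta is not None and group == pdelta[1]:
                log2[i, s] += pdelta[0]
    df = pd.DataFrame(np.exp2(log2), index=probe_ids, columns=samples)
    return ExpressionMatrix(df, scale="linear")


# ---------------------------------------------------------------------------
# Complete workspace on disk

def make_workspace(
    seed: int,
    outdir,
    n_coding: int = 6,
    n_lncrna: int = 14,
    overlap_fraction: float = 0.3,
    n_per_group: int = 5,
    spacing: int = 35,
    splice_delta: float = 2.0,
    de_delta: float = 3.0,
    params: Parameters = Parameters(),
) -> SimulationTruth:
    """Write a complete synthetic input set: genome.fa, coding.bed,
    lncrna.bed, probes.tsv, intensities.tsv, design.tsv, truth.json.

    One probe set (the first one with >= 2 probes in a cluster of >= 3
    probe sets, so the cluster summary stays anchored by unaffected
    probes) carries a planted splice effect of ``splice_delta`` log2 in
    group 2, and one other cluster a gene-level effect of ``de_delta``.
    """
    import json
    from pathlib import Path

    from . import io as fio
    from .pipeline import build_annotation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = make_toy_genome(seed, n_chroms=2, length=60_000, dup_length=200)
    transcripts = make_transcriptome(seed + 1, genome, n_coding, n_lncrna,
                                     overlap_fraction, params)
    coding = [t for t in transcripts if t.biotype == Biotype.CODING]
    lncrnas = [t for t in transcripts if t.biotype == Biotype.LNCRNA]
    probe_free = {t.transcript_id for t in lncrnas if "probefree" in t.transcript_id}
    probes = make_probe_table(seed + 2, genome, transcripts, spacing=spacing,
                              probe_free_ids=probe_free, params=params)

    fio.write_fasta(genome, outdir / "genome.fa")
    fio.write_transcripts_bed12(coding, outdir / "coding.bed")
    fio.write_transcripts_bed12(lncrnas, outdir / "lncrna.bed")
    fio.write_probe_table(probes, outdir / "probes.tsv")

    result = build_annotation(genome, probes, [coding], lncrnas, params)

    affected_ps: dict[str, tuple[float, str]] = {}
    affected_cl: dict[str, tuple[float, str]] = {}
    design = make_two_group_design(n_per_group)
    g2 = sorted(set(design.values()))[1]
    splice_cluster = None
    for c in result.clusters:
        if len(c.probesets) >= 3:
            target = next((ps for ps in c.probesets if len(ps.probe_ids) >= 2), None)
            if target is not None:
                affected_ps[target.probeset_id] = (splice_delta, g2)
                splice_cluster = c.cluster_id
                break
    for c in reversed(result.clusters):
        if c.cluster_id != splice_cluster:
            affected_cl[c.cluster_id] = (de_delta, g2)
            break

    truth = SimulationTruth(
        seed=seed,
        clusters=result.clusters,
        probes=result.probes,
        affected_probesets=affected_ps,
        affected_clusters=affected_cl,
        transcripts=transcripts,
    )
    matrix = simulate_intensities(seed + 3, truth, design)
    fio.write_expression_matrix(matrix, outdir / "intensities.tsv",
                                id_label="probe_id")
    fio.write_design(design, outdir / "design.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "affected_probesets": {k: list(v) for k, v in affected_ps.items()},
                "affected_clusters": {k: list(v) for k, v in affected_cl.items()},
                "summary": result.summary,
                "model": {"mu": truth.mu, "tau": truth.tau, "sigma": truth.sigma,
                          "baseline_sd": truth.baseline_sd},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return truth


# ---------------------------------------------------------------------------
# Statistics-only fixture (no genome needed)

def make_expression_fixture(
    n_clusters: int = 10,
    probesets_per_cluster: int = 5,
    probes_per_set: int = 4,
) -> tuple[list[TranscriptCluster], list[Probe]]:
    """A synthetic fully-assigned annotation on a virtual chromosome,
    for exercising the statistics stack in isolation."""
    clusters: list[TranscriptCluster] = []
    probes: list[Probe] = []
    for c in range(n_clusters):
        cid = f"SC{c + 1:03d}"
        base = 10_000 + c * 100_000
        intervals = [
            GenomicInterval("simchr", base + j * 1000, base + j * 1000 + 500, "+")
            for j in range(probesets_per_cluster)
        ]
        member = TranscriptModel(f"{cid}_T1", f"{cid}_T1", intervals,
                                 Biotype.LNCRNA)
        cluster = TranscriptCluster(cid, "simchr", "+", [member])
        for j, iv in enumerate(intervals):
            ps = ProbeSet(f"{cid}_PS{j + 1:03d}", iv, cid)
            for i in range(probes_per_set):
                pid = f"{cid}_PS{j + 1:03d}_P{i + 1}"
                aln = GenomicInterval("simchr", iv.start + i * 30,
                                      iv.start + i * 30 + 25, "+")
                probes.append(Probe(pid, "A" * 25, alignment=aln,
                                    status=ProbeStatus.ASSIGNED,
                                    probeset_id=ps.probeset_id))
                ps.probe_ids.append(pid)
            cluster.probesets.append(ps)
        clusters.append(cluster)
    return clusters, probes
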