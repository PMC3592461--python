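"""Readers and writers for the on-disk formats.

All genomic files use 0-based half-open coordinates internally; BED is
read and written verbatim, GTF starts are shifted by -1 on ingestion.
Expression matrices travel as plain TSV (feature id column + one column
per sample).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

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
)


class ParseError(ValidationError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into {name: uppercase sequence}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA record {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED12 transcripts

def read_transcripts_bed12(path: str | Path, biotype: Biotype | str) -> list[TranscriptModel]:
    """Read transcript models from a BED12 file.

    Exons are reconstructed from blockSizes/blockStarts; the standard
    BED12 block consistency rules are enforced (first block at offset 0,
    last block ending at chromEnd).  File order is preserved.
    """
    biotype = Biotype(biotype)
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected >= 12 BED columns, "
                                 f"got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(
                    f"{path}:{lineno}: blockCount {n_blocks} does not match "
                    f"blockSizes/blockStarts"
                )
            if offsets[0] != 0 or start + offsets[-1] + sizes[-1] != end:
                raise ParseError(
                    f"{path}:{lineno}: blocks do not span [{start}, {end})"
                )
            try:
                exons = [
                    GenomicInterval(chrom, start + off, start + off + size, strand)
                    for off, size in zip(offsets, sizes)
                ]
                out.append(TranscriptModel(name, name, exons, biotype))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_transcripts_bed12(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            span = t.span
            sizes = ",".join(str(e.length) for e in t.exons)
            offsets = ",".join(str(e.start - span.start) for e in t.exons)
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(span.start),
                        str(span.end),
                        t.transcript_id,
                        "0",
                        t.strand,
                        str(span.start),
                        str(span.end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF transcripts (optional input dialect)

def read_transcripts_gtf(path: str | Path, biotype: Biotype | str) -> list[TranscriptModel]:
    """Read transcripts from a GTF file (exon features grouped by
    transcript_id; 1-based starts shifted to 0-based on ingestion)."""
    biotype = Biotype(biotype)
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "exon":
                continue
            chrom, start, end, strand, attrs = (
                fields[0],
                int(fields[3]) - 1,
                int(fields[4]),
                fields[6],
                fields[8],
            )
            tid = None
            for part in attrs.rstrip(";").split(";"):
                key, _, val = part.strip().partition(" ")
                if key == "transcript_id":
                    tid = val.strip().strip('"')
                    break
            if tid is None:
                raise ParseError(f"{path}:{lineno}: exon without transcript_id")
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            exons[tid].append(GenomicInterval(chrom, start, end, strand))
    out = []
    for tid in order:
        ivs = sorted(exons[tid], key=lambda iv: iv.start)
        out.append(TranscriptModel(tid, tid, ivs, biotype))
    return out


# ---------------------------------------------------------------------------
# Probe table (probe_id TAB 25-nt sequence)

def read_probe_table(path: str | Path, params: Parameters) -> list[Probe]:
    """Read the two-column probe table; probes come back ``unmapped``."""
    probes: list[Probe] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated "
                                 f"columns, got {len(fields)}")
            probe_id, seq = fields[0], fields[1].upper()
            if probe_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate probe_id {probe_id!r}")
            seen.add(probe_id)
            if len(seq) != params.probe_length:
                raise ValidationError(
                    f"probe {probe_id!r}: sequence length {len(seq)} != "
                    f"{params.probe_length}"
                )
            if set(seq) - set("ACGT"):
                raise ValidationError(
                    f"probe {probe_id!r}: sequence contains non-ACGT characters"
                )
            probes.append(Probe(probe_id, seq))
    return probes


def write_probe_table(probes: Sequence[Probe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.sequence}\n")


# ---------------------------------------------------------------------------
# Annotation output files

def write_annotation_files(
    clusters: Sequence[TranscriptCluster],
    probes: Sequence[Probe],
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit the custom annotation as four plain-text files.

    probesets.bed   BED6, one row per probe set, score = probe count
    clusters.bed    BED6, one row per cluster span, score = probe-set count
    meta_probeset.tsv  cluster_id, comma-joined probeset ids, total probes
    probe_assignment.tsv  probe_id, probeset_id, chrom, start, end, strand

    Rows are sorted by (chrom, start).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / name for name in (
        "probesets.bed", "clusters.bed", "meta_probeset.tsv", "probe_assignment.tsv")}

    all_ps = [(ps, c) for c in clusters for ps in c.probesets]
    all_ps.sort(key=lambda x: (x[0].interval.chrom, x[0].interval.start))
    with open(paths["probesets.bed"], "w") as fh:
        for ps, _ in all_ps:
            iv = ps.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ps.probeset_id}\t"
                     f"{len(ps.probe_ids)}\t{iv.strand}\n")

    ordered = sorted(clusters, key=lambda c: (c.chrom, c.span.start))
    with open(paths["clusters.bed"], "w") as fh:
        for c in ordered:
            iv = c.span
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cluster_id}\t"
                     f"{len(c.probesets)}\t{iv.strand}\n")

    with open(paths["meta_probeset.tsv"], "w") as fh:
        fh.write("cluster_id\tprobeset_ids\tprobe_count\n")
        for c in ordered:
            ps_ids = ",".join(ps.probeset_id for ps in c.probesets)
            n = sum(len(ps.probe_ids) for ps in c.probesets)
            fh.write(f"{c.cluster_id}\t{ps_ids}\t{n}\n")

    assigned = [p for p in probes if p.status == ProbeStatus.ASSIGNED]
    assigned.sort(key=lambda p: (p.alignment.chrom, p.alignment.start))
    with open(paths["probe_assignment.tsv"], "w") as fh:
        fh.write("probe_id\tprobeset_id\tchrom\tstart\tend\tstrand\n")
        for p in assigned:
            iv = p.alignment
            fh.write(f"{p.probe_id}\t{p.probeset_id}\t{iv.chrom}\t{iv.start}\t"
                     f"{iv.end}\t{iv.strand}\n")
    return paths


def read_bed6(path: str | Path) -> list[tuple[GenomicInterval, str, int]]:
    """Read a BED6 file into (interval, name, score) tuples."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            out.append((iv, fields[3], int(fields[4])))
    return out


def read_probe_assignment(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "probeset_id": str,
                                            "chrom": str, "strand": str})
    required = {"probe_id", "probeset_id", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return df


def read_meta_probeset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cluster_id", "probeset_ids"}.issubset(df.columns):
        raise ParseError(f"{path}: not a meta_probeset table")
    return df


# ---------------------------------------------------------------------------
# Expression matrix

@dataclass
class ExpressionMatrix:
    """A features x samples intensity matrix with an explicit scale flag."""

    data: pd.DataFrame  # index = feature ids, columns = sample ids
    scale: str = "linear"  # {"linear", "log2"}

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicated feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicated sample ids")
        if self.scale == "linear" and (self.data.values <= 0).any():
            raise ValidationError("linear-scale matrix must be strictly positive")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.data), scale="log2")


def read_expression_matrix(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read a TSV matrix (first column feature id, header of sample names)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        ncol = len(cols)
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != ncol:
                raise ParseError(f"{path}:{lineno}: expected {ncol} columns, "
                                 f"got {len(fields)}")
            ids.append(fields[0])
            vals = []
            for j, cell in enumerate(fields[1:], start=1):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in "
                        f"column {cols[j]!r}"
                    ) from None
            rows.append(vals)
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicated feature id(s) {dup[:5]}")
    df = pd.DataFrame(rows, index=ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(df, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            id_label: str = "feature_id") -> None:
    """Write a matrix as TSV with full float precision (round-trip exact)."""
    with open(path, "w") as fh:
        fh.write(id_label + "\t" + "\t".join(matrix.sample_ids) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Two-group design

def read_design(path: str | Path) -> dict[str, str]:
    """Read a sample_id TAB group TSV into a mapping."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        first = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if first and fields[0].lower() in ("sample", "sample_id"):
                first = False
                continue
            first = False
            if fields[0] in mapping:
                raise ParseError(f"{path}:{lineno}: duplicate sample {fields[0]!r}")
            mapping[fields[0]] = fields[1]
    return mapping


def write_design(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in mapping.items():
            fh.write(f"{sample}\t{group}\n")
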