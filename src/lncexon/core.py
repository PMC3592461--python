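"""Core coordinate and annotation types.

Every genomic position in this package is 0-based, half-open and
strand-aware.  The two-level custom annotation mirrors the exon-array
design: *transcript clusters* are the gene-level unit (all lncRNAs that
overlap each other on the same strand) and *probe sets* are the
exon-level unit (maximal sub-intervals of a cluster's exonic footprint
not interrupted by any member's exon boundary).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

STRANDS = ("+", "-")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (N maps to N)."""
    return seq.translate(COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic span [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        """True if the two spans share >= 1 bp (optionally requiring same strand)."""
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start <= other.start and other.end <= self.end


class Biotype(str, enum.Enum):
    CODING = "coding"
    LNCRNA = "lncRNA"


@dataclass
class TranscriptModel:
    """An exon-structured transcript (coding gene model or lncRNA).

    Exons share chrom/strand, are sorted by start and pairwise disjoint
    (zero-length introns, i.e. touching exons, are tolerated on input).
    """

    transcript_id: str
    accession: str
    exons: list[GenomicInterval]
    biotype: Biotype

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        first = self.exons[0]
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.chrom != first.chrom or cur.strand != first.strand:
                raise ValidationError(
                    f"{self.transcript_id}: exons on mixed chrom/strand"
                )
            if cur.start < prev.end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
        self.biotype = Biotype(self.biotype)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """5' end position (start on +, end on -)."""
        return self.span.start if self.strand == "+" else self.span.end


class ProbeStatus(str, enum.Enum):
    UNMAPPED = "unmapped"
    MULTIMAPPED = "multimapped"
    CODING_OVERLAP = "coding_overlap"
    UNASSIGNED = "unassigned"
    ASSIGNED = "assigned"


#: statuses for which a genomic alignment must be present
_PLACED = {ProbeStatus.CODING_OVERLAP, ProbeStatus.UNASSIGNED, ProbeStatus.ASSIGNED}


@dataclass
class Probe:
    """A 25-nt array probe with its mapping status and final assignment."""

    probe_id: str
    sequence: str
    alignment: Optional[GenomicInterval] = None
    status: ProbeStatus = ProbeStatus.UNMAPPED
    probeset_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.status = ProbeStatus(self.status)
        self.validate()

    def validate(self) -> None:
        placed = self.status in _PLACED
        if placed and self.alignment is None:
            raise ValidationError(f"{self.probe_id}: status {self.status.value} "
                                  "requires an alignment")
        if not placed and self.alignment is not None:
            raise ValidationError(f"{self.probe_id}: status {self.status.value} "
                                  "forbids an alignment")
        if self.alignment is not None and self.alignment.length != len(self.sequence):
            raise ValidationError(
                f"{self.probe_id}: alignment length {self.alignment.length} "
                f"!= sequence length {len(self.sequence)}"
            )
        if (self.probeset_id is not None) != (self.status == ProbeStatus.ASSIGNED):
            raise ValidationError(
                f"{self.probe_id}: probeset_id present iff status is 'assigned'"
            )


@dataclass(frozen=True)
class Parameters:
    """Tunable constants of the annotation build.

    probe_length
        probe size in nt; exon arrays use 25-mers.
    min_lncrna_spliced_length
        minimal spliced length (bp) for a lncRNA to be kept; 201 keeps
        transcripts strictly longer than 200 nt (the lncRNA definition).
    proximate_distance
        gap threshold (bp) below which a non-overlapping neighbour is
        "proximate" (extension / close / bidirectional categories).
    min_probes_per_set
        probe sets with fewer probes than this are deleted.
    """

    probe_length: int = 25
    min_lncrna_spliced_length: int = 201
    proximate_distance: int = 1000
    min_probes_per_set: int = 1

    def __post_init__(self) -> None:
        for name in (
            "probe_length",
            "min_lncrna_spliced_length",
            "proximate_distance",
            "min_probes_per_set",
        ):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")


@dataclass
class ProbeSet:
    """A maximal exonic segment of a cluster uninterrupted by member exon
    boundaries; the exon-level measurement unit."""

    probeset_id: str
    interval: GenomicInterval
    cluster_id: str
    probe_ids: list[str] = field(default_factory=list)


@dataclass
class TranscriptCluster:
    """All same-strand mutually overlapping lncRNAs; the gene-level unit."""

    cluster_id: str
    chrom: str
    strand: str
    members: list[TranscriptModel]
    probesets: list[ProbeSet] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.members)
        end = max(t.span.end for t in self.members)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end


class PositionalCategory(str, enum.Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"
    INTRONIC = "intronic"
    BIDIRECTIONAL = "bidirectional"
    EXTENSION = "extension"
    CLOSE = "close"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class PositionalClass:
    """Genomic position of a cluster relative to protein-coding genes."""

    category: PositionalCategory
    nearest_gene_id: Optional[str]
    distance: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValidationError("distance must be >= 0")


def sort_key_interval(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end, iv.strand)


def group_by_chrom_strand(
    items: Iterable, key
) -> dict[tuple[str, str], list]:
    out: dict[tuple[str, str], list] = {}
    for it in items:
        iv = key(it)
        out.setdefault((iv.chrom, iv.strand), []).append(it)
    return out
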