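"""Exact-match genomic placement of array probes.

A zero-mismatch short-read aligner degenerates to exact string matching,
so probes are placed with a hash index of every probe-length genome
window.  Probes hitting no location stay ``unmapped``; probes hitting
two or more locations (both strands counted, so an even-length
reverse-complement palindrome at one locus counts twice) become
``multimapped`` and are discarded from further processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .core import (
    GenomicInterval,
    Parameters,
    Probe,
    ProbeStatus,
    ValidationError,
    reverse_complement,
)
from .io import read_fasta


@dataclass
class GenomeIndex:
    """Hash index of all forward-strand k-mer windows of a genome.

    Lookup of a query and of its reverse complement yields placements on
    the + and - strand respectively, so a k-mer and its reverse
    complement resolve to the same hit list with strands mirrored.
    """

    k: int
    lookup: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def placements(self, seq: str) -> list[tuple[str, int, str]]:
        """All genomic placements of ``seq`` on either strand."""
        if len(seq) != self.k:
            raise ValidationError(f"query length {len(seq)} != index k {self.k}")
        hits = [(c, s, "+") for c, s in self.lookup.get(seq, ())]
        hits += [(c, s, "-") for c, s in self.lookup.get(reverse_complement(seq), ())]
        return hits

    def n_hits(self, seq: str) -> int:
        return len(self.placements(seq))


def build_genome_index(
    genome: dict[str, str] | str | Path, params: Parameters
) -> GenomeIndex:
    """Index every length-k window of the genome (both strands implicitly).

    Windows containing N are skipped: N never matches any base.
    """
    if not isinstance(genome, dict):
        genome = read_fasta(genome)
    if not genome:
        raise ValidationError("empty genome")
    k = params.probe_length
    index = GenomeIndex(k=k)
    for chrom, seq in genome.items():
        seq = seq.upper()
        index.genome_lengths[chrom] = len(seq)
        lookup = index.lookup
        for start in range(0, len(seq) - k + 1):
            window = seq[start : start + k]
            if "N" in window:
                continue
            lookup.setdefault(window, []).append((chrom, start))
    return index


def map_probes(probes: list[Probe], index: GenomeIndex) -> list[Probe]:
    """Place probes on the genome; unique hits only.

    Exactly one placement -> aligned, status ``unassigned``; zero ->
    ``unmapped``; two or more -> ``multimapped``.  Input order is
    preserved and each probe is handled independently.
    """
    for probe in probes:
        if probe.status != ProbeStatus.UNMAPPED:
            raise ValidationError(f"{probe.probe_id}: expected status 'unmapped', "
                                  f"got {probe.status.value!r}")
        if len(probe.sequence) != index.k:
            raise ValidationError(
                f"{probe.probe_id}: probe length {len(probe.sequence)} != "
                f"index k {index.k}"
            )
        hits = index.placements(probe.sequence)
        if len(hits) == 1:
            chrom, start, strand = hits[0]
            probe.alignment = GenomicInterval(chrom, start, start + index.k, strand)
            probe.status = ProbeStatus.UNASSIGNED
        elif len(hits) == 0:
            probe.alignment = None
            probe.status = ProbeStatus.UNMAPPED
        else:
            probe.alignment = None
            probe.status = ProbeStatus.MULTIMAPPED
        probe.validate()
    return probes
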