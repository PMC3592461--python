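"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (full scans, base-by-base
labelling, O(n^2) graph walks, plain-Python arithmetic) and shares no
code with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np

from lncexon.core import Biotype, GenomicInterval, TranscriptModel, reverse_complement


# ---------------------------------------------------------------------------
# Mapper oracle: full two-strand string scan

def scan_placements(genome: dict[str, str], seq: str) -> list[tuple[str, int, str]]:
    hits = []
    for chrom, s in genome.items():
        for strand, query in (("+", seq), ("-", reverse_complement(seq))):
            start = s.find(query)
            while start != -1:
                hits.append((chrom, start, strand))
                start = s.find(query, start + 1)
    return sorted(hits)


# ---------------------------------------------------------------------------
# Segmentation oracle: base-by-base covering-set labelling

def label_segments(members: list[TranscriptModel]) -> list[tuple[int, int]]:
    """Maximal runs of constant, non-empty covering-transcript set."""
    lo = min(e.start for t in members for e in t.exons)
    hi = max(e.end for t in members for e in t.exons)
    labels = []
    for pos in range(lo, hi):
        cover = frozenset(
            t.transcript_id
            for t in members
            if any(e.start <= pos < e.end for e in t.exons)
        )
        labels.append(cover)
    segments = []
    start = None
    for i, lab in enumerate(labels + [frozenset()]):
        prev = labels[i - 1] if i > 0 else frozenset()
        if lab != prev:
            if start is not None and prev:
                segments.append((lo + start, lo + i))
            start = i if lab else None
    return segments


def label_segments_fast(members: list[TranscriptModel]) -> list[tuple[int, int]]:
    """Same base-by-base labelling as :func:`label_segments`, but with the
    per-position covering sets held in a boolean transcript x position
    matrix so large batches stay fast."""
    lo = min(e.start for t in members for e in t.exons)
    hi = max(e.end for t in members for e in t.exons)
    cov = np.zeros((len(members), hi - lo), dtype=bool)
    for i, t in enumerate(members):
        for e in t.exons:
            cov[i, e.start - lo : e.end - lo] = True
    nonempty = cov.any(axis=0)
    change = np.ones(hi - lo, dtype=bool)
    change[1:] = (cov[:, 1:] != cov[:, :-1]).any(axis=0)
    breakpoints = np.flatnonzero(change).tolist() + [hi - lo]
    return [
        (lo + a, lo + b)
        for a, b in zip(breakpoints, breakpoints[1:])
        if nonempty[a]
    ]


# ---------------------------------------------------------------------------
# Clustering oracle: O(n^2) pairwise overlap + BFS components

def _exon_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    return any(
        ea.start < eb.end and eb.start < ea.end
        for ea in a.exons
        for eb in b.exons
    )


def brute_force_components(
    transcripts: list[TranscriptModel],
) -> set[frozenset[str]]:
    n = len(transcripts)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if _exon_overlap(transcripts[i], transcripts[j]):
                adj[i].append(j)
                adj[j].append(i)
    seen: set[int] = set()
    comps: set[frozenset[str]] = set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.add(transcripts[k].transcript_id)
            stack.extend(adj[k])
        comps.add(frozenset(comp))
    return comps


# ---------------------------------------------------------------------------
# Median-polish oracle: plain-Python row/column sweeps, lower median

def _lomed(values) -> float:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def median_polish_oracle(X, max_iter: int = 10, tol: float = 1e-6):
    R = [[float(v) for v in row] for row in X]
    nr, nc = len(R), len(R[0])
    overall, row, col = 0.0, [0.0] * nr, [0.0] * nc
    for _ in range(max_iter):
        prev = [r[:] for r in R]
        for i in range(nr):
            d = _lomed(R[i])
            for j in range(nc):
                R[i][j] -= d
            row[i] += d
        d = _lomed(col)
        col = [c - d for c in col]
        overall += d
        for j in range(nc):
            d = _lomed([R[i][j] for i in range(nr)])
            for i in range(nr):
                R[i][j] -= d
            col[j] += d
        d = _lomed(row)
        row = [r - d for r in row]
        overall += d
        if max(abs(R[i][j] - prev[i][j]) for i in range(nr) for j in range(nc)) < tol:
            break
    return overall, row, col, R


# ---------------------------------------------------------------------------
# Welch t oracle: textbook formula

def welch_p_oracle(a, b) -> float:
    from scipy.stats import t as tdist

    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * tdist.sf(abs(t), df)


# ---------------------------------------------------------------------------
# Random model generators shared by several tests

def random_transcripts(
    rng: np.random.Generator,
    n: int,
    biotype: Biotype = Biotype.LNCRNA,
    chroms: tuple[str, ...] = ("chrA",),
    strands: tuple[str, ...] = ("+", "-"),
    max_exons: int = 8,
    coord_range: int = 3000,
    prefix: str = "T",
) -> list[TranscriptModel]:
    """Random multi-exon transcripts with positive intron lengths."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        strand = strands[int(rng.integers(len(strands)))]
        n_exons = int(rng.integers(1, max_exons + 1))
        start = int(rng.integers(0, coord_range))
        exons = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(10, 120))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(1, 150))
        out.append(TranscriptModel(f"{prefix}{i:04d}", f"{prefix}{i:04d}",
                                   exons, biotype))
    return out
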