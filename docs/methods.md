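# Methods

## Problem and approach

Affymetrix exon arrays tile ~25-nt probes across the whole length of
every gene, grouped into two annotation levels: *probe sets* (one per
exon) and *transcript clusters* (all isoforms of a gene).  `lncexon`
rebuilds this two-level annotation for long non-coding RNAs so that the
same arrays measure lncRNA gene expression and lncRNA exon usage:

1. **Probe placement.** Probe sequences are placed on the genome by
   exact matching (a zero-mismatch aligner degenerates to exact string
   search).  A hash index stores every probe-length genome window;
   querying a probe and its reverse complement yields + and − strand
   placements.  Probes with zero placements are `unmapped`, probes with
   two or more (both strands counted) are `multimapped` and discarded.
   An even-length reverse-complement palindrome matching one locus
   yields two placements and is discarded as multimapped; with the
   default odd probe length (25) this situation cannot arise, but the
   rule keeps the index consistent for any k.  `N` in the genome never
   matches any base.
2. **Coding-exon exclusion.** All exons of all supplied protein-coding
   annotation sources are merged per (chromosome, strand).  Any uniquely
   placed probe overlapping this mask by ≥ 1 bp *on the same strand* is
   removed.  Intronic and antisense probes survive: the exclusion is
   exon-level, not gene-span-level.
3. **lncRNA length filter.** Transcripts with spliced length (sum of
   exon lengths, not genomic span) ≤ 200 nt are removed — the
   conventional size floor of the lncRNA class.
4. **Transcript clustering.** lncRNAs whose exons overlap by ≥ 1 bp on
   the same strand are combined into transcript clusters = connected
   components of the exon-overlap graph.  Overlap is exon-level by
   design: a transcript nested inside another's intron shares no
   transcribed sequence and stays separate.  The implementation is a
   sorted sweep over exon intervals with union–find; the test suite
   checks it against an O(n²) pairwise brute force.
5. **Probe-set segmentation.** Within a cluster, the exonic footprint
   (union of member exons) is cut at every exon start/end of every
   member.  The resulting maximal uninterrupted intervals are the probe
   sets: each one measures a region with a constant set of covering
   isoforms, which is what makes exon-level signals attributable to
   specific isoform structures.
6. **Probe assignment and pruning.** A probe is assigned to a probe set
   iff its placement is fully contained in the probe-set interval on the
   same strand.  Probes straddling a probe-set boundary are dropped —
   a straddling 25-mer would mix the signal of two segments.  Probe
   sets without probes are deleted, then clusters without probe sets.
7. **Positional classification.** Each cluster is classified relative
   to protein-coding genes into seven categories, evaluated in the
   precedence order **sense** (exon overlap, same strand) >
   **antisense** (exon overlap, opposite strand) > **intronic**
   (entirely within one intron) > **bidirectional** (non-overlapping,
   opposite strand, 5′ ends facing, gap < 1000 bp) > **extension**
   (non-overlapping, same strand, gap < 1000 bp) > **close**
   (non-overlapping, opposite strand, gap < 1000 bp, not head-to-head)
   > **intergenic**.  The precedence makes the categories a partition.
   Each coding transcript is treated as its own gene when no gene
   grouping is supplied.  The reported distance is the gap to the
   category-defining gene (0 for the overlap categories).

### Expression model

Pre-processing is a deterministic RMA-lite: **quantile normalization**
of linear probe intensities (each column's sorted values replaced by the
across-column mean of sorted values; ties receive the mean of their
target quantiles), log2 transform, and **Tukey median polish**
summarization.  No background correction is applied; the pipeline is
self-contained and reproducible bit-for-bit.

Median polish alternates row- and column-median sweeps until the largest
residual change is < 1e-6 or 10 iterations.  Medians use the
lower-median convention for even-length vectors, which keeps every sweep
an exact data value and makes the decomposition reproducible across
platforms; on exactly additive data the residuals vanish after one
sweep.  The per-sample summary is overall + column effect.

Cluster-level expression pools **all** retained probes of the cluster
(not the average of probe-set summaries), mirroring the gene-level
meta-probe-set design in which the gene signal uses every probe of the
transcript cluster.

Exon-level signal:

* **GNI** (gene-level normalized intensity), per sample:
  `GNI[p, s] = log2 probeset_expr[p, s] − log2 cluster_expr[cluster(p), s]`.
* **Splice Index**: `SI = mean GNI(group1) − mean GNI(group2)` — the
  log2 fold change of the exon-specific signal.  group1 is the
  lexicographically smaller label, so the sign convention is
  deterministic and swapping group labels negates SI exactly (bitwise).

Per probe set, GNI values are compared between groups with Welch's
two-sample t-test; p-values are adjusted with Benjamini–Hochberg across
all probe sets.  Cluster-level differential expression uses the same
test on the cluster summaries.  When both groups have zero variance the
p-value is defined as 1 for equal means and 0 otherwise rather than NaN.
Welch + BH replaces moderated-t machinery deliberately: the annotation,
GNI and SI are the method; the two-group test is a standard exchangeable
component, and the contract (fold change, p, FDR per feature) is
unchanged.

A variance filter (`select_top_variance`, default n = 150) reproduces
the common "most variable features" pre-selection used before sample
clustering and heat maps.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `probe_length` | 25 nt | exon-array probe length; also the index word size |
| `min_lncrna_spliced_length` | 201 bp | keep lncRNAs strictly longer than 200 nt |
| `proximate_distance` | 1000 bp | gap threshold for extension / close / bidirectional |
| `min_probes_per_set` | 1 | probe sets below this are deleted |
| report `--fc`, `--si` | 1.0 | |log2 change| cut for the convenience report |
| report `--fdr` | 0.05 | BH FDR cut for the convenience report |

## Synthetic fixtures

The generators are pure functions of their seeds (byte-identical
reruns) and define the default study conditions:

* **Genome**: uniform random ACGT chromosomes (2 × 60 kb by default),
  with an optional duplicated 200-bp segment planting known
  multimapping 25-mers.
* **Transcriptome**: deterministic scenario blocks.  Six coding genes
  (3–5 exons of 150–350 bp, introns 800–1500 bp) each carry one
  satellite lncRNA realizing one positional category; the remaining
  lncRNAs are intergenic and include a staggered same-strand
  overlapping pair (producing a cluster with ≥ 3 probe sets), one
  transcript of spliced length 180 nt (removed by the length filter)
  and one transcript deliberately left without probes (its cluster is
  deleted by the pruning rule).  ≥ 60 % of lncRNAs are multi-exon.
* **Probe table**: 25-mers copied from the genome every 35 bp along
  each exon on the transcript's sense strand, plus known-unmapped
  (random sequences verified absent) and known-multimapped (taken from
  the duplicated segment) probes.
* **Intensities**: log-additive Gaussian model,
  `log2 I = μ + a_i + e[cluster, s] + δ[probeset or cluster, group] + ε`
  with baseline μ = 7, probe affinities a ~ N(0, 0.5²), cluster
  baselines ~ N(0, 1²), noise ε ~ N(0, 0.25²), returned on the linear
  scale.  Default experiment: two groups of 5 samples, one probe set
  with a planted splice effect of 2.0 log2, one cluster with a planted
  gene-level effect.

What the fixtures do **not** emulate: cross-hybridization, GC-dependent
probe affinity, heavy-tailed noise, batch effects, and realistic array
size (hundreds of probes instead of millions).  Passing tests therefore
demonstrate correctness of the algorithms and calibration of the
statistics under the stated model, not robustness to real-array
artifacts.

## Numerical choices and problem sizes

* Quantile normalization ties: tied values within a column receive the
  mean of the reference values their ranks span.
* Median polish: lower-median, tolerance 1e-6, ≤ 10 iterations.
* Cluster and probe-set identifiers are ordinal over (chromosome,
  strand, start), so outputs are byte-identical across reruns.
* Result TSVs are written with `%.10g` floats; matrix TSVs with full
  `repr` precision so read→write round-trips are exact.
* Oracle-equivalence tests run at desk scale: 1000 random clusters
  (≤ 20 transcripts × ≤ 8 exons) for segmentation, 200 instances
  (n ≤ 50) for clustering, 50 random 20-kb genomes × 500 probes for
  the mapper, and 100 seeded replicates for statistic recovery —
  sizes chosen so the whole suite runs comfortably on one CPU while
  keeping the comparisons exhaustive at each size.

## Known limitations

* **Quantile normalization with few probes.** With only a few hundred
  simulated probes, a strongly shifted cluster occupies the extreme
  upper ranks of the affected samples and displaces the ranks of other
  high-expressed probes; forcing all samples onto the common reference
  distribution then attenuates planted effects and can leak apparent
  fold change into unaffected high-expression clusters.  This is an
  inherent property of quantile normalization when the "most features
  unchanged" assumption is strained, and it shrinks as the probe
  complement grows; real exon arrays carry millions of probes.  The
  acceptance report's recovered effect sizes should be read with this
  attenuation in mind.
* A cluster span that overlaps a gene span without exon overlap and
  without lying inside a single intron (straddling a gene edge through
  an intron) does not fit any of the seven categories' definitions and
  is reported as intergenic with distance 0.
* Touching-but-not-overlapping neighbours (gap 0) are not "proximate":
  extension / close / bidirectional require a positive gap.
* Only two-group, unpaired designs; no detection p-values, batch
  correction or background modelling.
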