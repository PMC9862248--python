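# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage, what the synthetic-data generator does and
does not emulate, and the design decisions taken where more than one
reasonable choice existed.

## Study design emulated by the generator

The generator reproduces the statistical structure of a three-condition
eccDNA survey of fed-batch CHO cultures: a pooled Day 0 group (four
biologically identical replicates), a Control Day 12 group and a
lactate-stressed Day 12 group (two replicates each). Per-condition
profiles (`CONDITION_PROFILES`) fix the observed composition targets:

| condition | mean length (bp) | gene-bearing | tRNA-bearing | ORI-bearing | replicates |
|-----------|-----------------:|-------------:|-------------:|------------:|-----------:|
| D0        | 4063 | 3.52% | 9.81% | 10.07% | 4 |
| C12       | 3579 | 3.23% | 7.86% |  0.89% | 2 |
| ST12      | 3534 | 2.96% | 7.56% |  0.078% | 2 |

Circle lengths are lognormal (σ_log = 0.8, mean parameterized per
condition) resampled into the observed support [21, 24,309] bp; the
upper truncation pulls the realized mean ~2–3% below the nominal mean,
within the 5% tolerance the distributional checks use. Each circle is a
contiguous genomic excision — no chimeric multi-locus circles — because
the downstream mapping analysis assigns each eccDNA a single biogenesis
locus. Composition is enforced by construction: each circle is drawn as
gene-bearing, tRNA-bearing, ORI-bearing or background with the profile
probabilities, and non-gene categories reject gene-body overlaps (the
background additionally rejects all planted motif sites). Fractions
recovered downstream are therefore exact Bernoulli targets, not
incidental overlaps. Background excision starts follow per-window
multinomial weights in which hotspot-overlapping windows carry an
enrichment factor (default 5, configurable); the weight table is exposed
(`background_window_weights`) and serves as the oracle for enrichment
tests.

The toy genome plants, over a uniform-random background: non-overlapping
gene models (slotted placement), dispersed direct and inverted copies of
a labeled repeat library (SINE/LINE/LTR/DNA/satellite/simple/
low-complexity motifs), tRNA and replication-origin motif sites, and
repeat-dense hotspot intervals containing a tandem motif array plus an
inverted copy. Chromosomes shorter than two windows are refused.

Reads: one rolling-circle read per circle — the circle repeated from a
uniform random phase for a fractional pass count (default uniform 2–8;
the terminal pass ends mid-circle), then independent per-base errors.
The default error model is HiFi-like: 0.5% substitutions, 0.05% 1-bp
indels. No quality strings are modeled (FASTA, not FASTQ), and read
abundance is one read per circle: rolling-circle enrichment is not
quantitative, so the simulator deliberately makes no abundance claims.

RNA-seq counts are negative-binomial (var = μ + φμ²) with per-gene
baseline means, dispersions and planted per-condition log2 fold changes.
The default DE plan plants loss genes (down in both Day-12 conditions)
and per-condition gain genes with |log2FC| drawn uniformly from
[2.5, 4]. The magnitude floor of 2.5 is a design choice: flagging uses a
hard |log2FC| ≥ 2 cut, and a gene planted exactly at the boundary would
be recovered only half the time by any unbiased estimator (the
fold-change estimator's SD is ≈ 0.25 at mean 1000, dispersion 0.05, 2–4
replicates); in the emulated study the flagged genes also passed a
significance filter, i.e. they sit clearly inside the flagged region,
which is what the floor encodes.

Planted eccDNA-private SNPs flip one base of a gene-overlapping circle
segment away from the genome and emit a three-source pileup: reference
DNA reads fixed for the genome allele, the eccDNA consensus fixed for
the alternate allele, and RNA reads carrying the alternate allele with a
configurable per-base error. Control (SNP-free) sites can be added for
precision checks.

All randomness flows from one integer seed through named generators
(crc32-keyed child seeds), so adding a new stream never perturbs
existing ones and outputs are byte-stable across platforms.

**What passing on synthetic data does not show:** real rolling-circle
reads have chimeras, branch artifacts and length-dependent capture bias;
real repeat families are diverged copies of consensus models rather than
near-exact motif plantings; real RNA-seq has gene-length and GC biases.
Recovery rates here certify the algorithms against their own generative
assumptions, not performance on instrument data.

## Deconcatenation

Period detection is seeded self-matching: candidate shifts come from
spacings of repeated 13-mers (short reads ≤ 2 kbp use an exhaustive
shift scan instead); a shift *d* is accepted when the read aligns to
itself shifted by *d* with edit-based identity ≥ 0.85 over the overlap;
among acceptable shifts the smallest is taken (period minimality) and
refined ±2 bp to the locally best shift. Passes = length / period; a
circle is called only at ≥ 2.0 full passes, since one pass cannot
distinguish a circular from a linear template. Rejected reads carry
machine-readable reasons (insufficient length / no periodicity /
insufficient passes / length out of bounds).

Consensus: monomers are period-length slices from phase 0; votes are
projected onto the first monomer's columns through an edit alignment
(edlib) with a gapless fast path when a monomer matches the reference
length at ≥ 90% positional identity. The projection is what makes the
consensus robust to indels — a gapless stack lets a single 1-bp indel
shift the rest of that monomer out of register. Column ties break by
fixed base order A < C < G < T; a column is dropped only when deletion
votes strictly beat the best base. The final consensus is reported in
canonical (lexicographically minimal, Booth's algorithm) rotation, so
any read phase of the same circle yields a byte-identical record.
Acceptance thresholds (minimum passes, identity, length bounds
21–30,000 bp) are package choices exposed on `DeconcatParams`.

## Clustering

Identity is edit-distance-based: the shorter sequence (and its reverse
complement) is aligned in infix mode against the doubled longer
sequence, which scores every relative rotation of two circular
sequences in O(nm) once rather than per rotation; identity = matched
fraction of the shorter length, reproducing the shorter-denominator
convention for nested fragments. Because gapped alignment against a
doubled target is not symmetric in its arguments, equal-length pairs
evaluate both directions and keep the better, making the function
symmetric. At an exact join threshold an edit-based identity can differ
from a mismatch-count identity by ~1 base per 100; oracle comparisons
therefore use planted instances separated from the threshold. Greedy
clustering is longest-first (ties by id), join-first-acceptable, with
≥ 0.90 treated as joining (the boundary is inclusive).

## Annotation

Motif search is seeded: exact 11-mer anchors propose placements, each
scored by positional identity over the motif window (±1 refinement),
both strands, with circular wrap-around (a motif split across the
canonical-rotation origin still scores full length). Repeat masking
accepts ≥ 80% identity over ≥ 30 bp and resolves cross-class overlaps by
precedence (interspersed SINE/LINE/LTR/DNA > satellite > simple >
low-complexity), making per-class masked-bp totals additive. tRNA
motifs use ≥ 90% identity and ORI motifs ≥ 95% over the full motif
length (a sub-seed is not an origin); both thresholds are arguments.
This is a deliberate stand-in for covariance-model tRNA scanning and
full repeat-family masking: same contract, simpler search, and hits
below ~70% identity cannot seed (irrelevant at the 80%+ thresholds
used). Gene content requires ≥ 1 bp gene-body overlap (fragments
count); no ab initio gene prediction is attempted.

Summary rows report mean length = total bases / count (rounded half-up
to the nearest bp), GC% over all bases including masked ones (one GC
value per condition), and gene/tRNA/ORI percentages over the clustered
sequence count, all rounded half-up to two decimals; every percentage is
recomputable from its numerator and denominator. Both
sequences-with-≥1-tRNA-motif and total motif hits are reported, since
the two readings of a "tRNA count" differ.

## Biogenesis windows

Windows tile each chromosome at a fixed size (default 500 kbp); the
terminal window may be short but still counts. Each eccDNA increments
exactly one window — the window containing its placement start, which is
the leftmost window it touches. Z-scores standardize counts by the mean
and *population* SD over all windows including empty ones: the emulated
study's per-window means only reproduce when every window enters the
denominator, and windows are the full population of bins rather than a
sample. With mean 9.64 and SD 8.02 the smallest integer count at Z ≥ 2
is ⌈9.64 + 2·8.02⌉ = 26. Per-window means are reported rounded half-up
to two decimals; note that a published mean of 9.64 for 44,402/4,602 =
9.6484 suggests truncation rather than rounding — the package rounds,
and the one value it reproduces (14,457/4,602 = 3.1414 → 3.14) is
insensitive to the difference. A degenerate all-equal count vector
yields all-zero Z with a warning. The self-dotplot reports maximal
exact-15-mer chains on forward×forward (direct) and
forward×reverse-complement (inverted) comparisons, excluding the main
diagonal; k < 8 is refused as a spurious-match guard and k-mers with
more than 64 occurrences are skipped to bound pair counts in
low-complexity regions.

## Dynamics

"Presence" means the gene was annotated on at least one clustered eccDNA
of the condition. The Venn partition counts genes by how many conditions
they appear in; counts always sum to the union size. Fold changes are
computed on the counts-per-million scale with pseudocount 1.0 added to
group means (finite for unexpressed genes; swapping groups negates
values exactly). Significance testing is out of scope: an external DE
table can be supplied, and in-package flagging is fold-change-driven.
Day-0-unique genes are loss-correlated when log2FC ≤ −2 in at least one
Day-12 contrast; genes unique to one Day-12 condition are
gain-correlated when that condition's contrast shows log2FC ≥ +2; genes
shared by both Day-12 conditions but absent at Day 0 are reported as a
separate "day12-shared" class (their gain/loss attribution is ambiguous
between the two conditions) and flagged by the larger contrast. Genes
absent from the expression data flag as "no-expression-data" rather than
erroring. CPM normalization carries a composition caveat: when planted
(or real) DE genes are a large fraction of the transcriptome, library
sizes absorb part of the effect; recovery studies therefore use a
400-gene transcriptome so planted effects are a small fraction, matching
the regime real count data occupy.

## Transcript assignment

Site classification is a pure function of counts and thresholds. A site
is eccDNA-supported when (1) the RNA majority allele equals the eccDNA
consensus allele, (2) both the eccDNA allele fraction and the RNA
majority fraction are ≥ 0.9 (homozygous-style evidence, generalizing the
clean 100%-of-reads case to noisy pileups), (3) the allele differs from
the *reference-read majority* — read evidence, not the reference FASTA
base alone, defines the chromosomal allele, so an assembly error at the
site does not masquerade as eccDNA evidence — and (4) RNA depth ≥ 10.
RNA majority = reference majority classifies as chromosomal; zero RNA
depth as no-coverage; anything else as ambiguous. Raising either
threshold can only shrink the supported set. Site tables are 1-based
(variant convention); placements are converted internally from 0-based.
Candidate transcripts are those with ≥ 1 supported site, ranked by
supported-site count; "informative" sites are covered sites where the
eccDNA allele differs from the reference base. Depth/fraction defaults
are declared package choices (the evidence thresholds of the emulated
analysis are not published) and are exposed on every entry point.

## Pipeline, sizes and runtime choices

The pipeline (simulate → deconcat → cluster → annotate → windows →
dynamics → transcripts) writes each stage's artifacts as plain-text
standard formats (FASTA, GFF3 1-based inclusive, BED 0-based half-open,
TSV) so stages are independently re-runnable, and a report of per-stage
record counts and summary tables. Identical (config, seed) reproduces
every table byte-for-byte; wall time is the only nondeterministic field.
Pipeline-scale defaults (two 1 Mbp chromosomes, 100 kbp windows, 240
circles, 800 bp mean length) and the recovery-study sizes in
`benchmarks` (200 circles for confirmation fidelity, 30 sequences for
cluster recovery, 20 seeds × 2,000 placements for hotspot detection, 50
planted DE genes, 20 seeds × 5 SNPs for transcript recovery) are chosen
so the full battery completes in minutes on a single core while keeping
binomial noise well inside the asserted margins.

## Known limitations

- The deconcatenator processes reads independently; it cannot merge
  evidence across reads of the same circle, and circles longer than half
  their read are unrecoverable by design (< 2 passes).
- Greedy clustering is order-dependent (longest-first); representatives
  are not centroids, matching the behavior of standard greedy-incremental
  tools rather than optimal clustering.
- The motif scanner's exact-k-mer seeding misses hits below ~70%
  identity; acceptable at the 80–95% thresholds used, wrong for remote
  homology.
- Fold-change flagging without dispersion-aware testing over- and
  under-flags near the threshold exactly as a hard cut must; the package
  deliberately leaves significance to dedicated DE tools and can import
  their output.
- The dual-reference variant comparison of the emulated analysis is
  represented by a single primary reference plus the reference-read
  majority rule; a second reference pileup can be supplied as an
  additional column but no joint calling is performed.
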