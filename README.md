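# circulome

Analysis of extrachromosomal circular DNA (eccDNA) populations — the
*circulome* — from rolling-circle-amplified long reads, built around the
study design of multi-condition CHO fed-batch cultures (Day 0 pooled,
Control Day 12, Lactate-stressed Day 12).

EccDNA are circularized segmental DNAs that carry genes, tRNA motifs and
replication origins, arise preferentially from repeat-dense genomic
regions, and segregate unevenly at division — a fast-access pool of
genetic heterogeneity relevant to cell-line stability in
biomanufacturing. This package is for computational biologists who want
a tested, seedable implementation of the complete analysis chain, plus a
synthetic-data generator that emits ground truth for every stage so the
chain can be validated end to end.

## What it computes

- **Deconcatenation** — a rolling-circle read is the circle repeated in
  tandem. For read *R* of length *L*, the circle length *p* is found by
  seeded self-matching: *p* = argmin { d : identity(R[d:], R[:-d]) ≥ τ }
  with refinement, passes = *L*/*p*. Reads with ≥ 2 full passes yield a
  per-column majority consensus in canonical (lexicographically minimal)
  rotation.
- **Clustering** — greedy, longest-first collapse at ≥ 90% identity,
  where identity = matched bases of the shorter sequence in its best
  alignment against the longer, over all rotations and both strands.
- **Annotation** — repeat masking (≥ 80% identity over ≥ 30 bp, class
  precedence on overlap), tRNA motifs (≥ 90%), replication-origin motifs
  (≥ 95% over the full motif), gene content (≥ 1 bp gene-body overlap),
  summarized per condition (counts, mean length, GC%, masked%,
  gene/tRNA/ORI fractions).
- **Biogenesis hotspots** — placements binned into fixed 500 kbp genome
  windows; per-window Z = (count − μ)/σ over *all* windows (population
  SD); hotspots are windows with Z ≥ 2; hotspot architecture is
  characterized by a direct/inverted-repeat self-dotplot.
- **Gene-content dynamics** — Venn partition of eccDNA genes across
  conditions; log2FC = log2((CPM̄_b + 1)/(CPM̄_a + 1)); condition-unique
  genes with concordant shifts (≤ −2 for Day-0-unique, ≥ +2 for
  Day-12-unique) are flagged loss-/gain-correlated.
- **Transcript assignment** — a site supports an eccDNA template when
  RNA reads and the eccDNA consensus are near-fixed (≥ 90%) for the same
  allele while the reference-read majority differs; transcripts with ≥ 1
  supported site are ranked candidates.
- **Synthetic data** — a toy genome with planted genes, motif sites and
  repeat-dense hotspots; circle populations with per-condition length
  and composition targets; concatemer reads with HiFi-like errors;
  negative-binomial RNA counts with planted fold changes; eccDNA-private
  SNPs surfacing in RNA pileups — all with truth tables.

## Worked example

```bash
python examples/05_hotspot_scan.py
```

```
2000 placements over 8 windows (mean 250.00, SD 331.64, 0 empty)
1 hotspot window(s) at z >= 2:
chrom  index  start    end  count        z
 chr1      0      0 500000   1127 2.644399

hotspot self-alignment: 7 direct and 11 inverted repeat matches (longest 1400 bp)
```

2,000 circles were excised with a 10-fold preference for one
repeat-dense window; that window collected 1,127 of the 2,000 placements
(z = 2.64 against a window mean of 250) and is the only window called a
hotspot, and its self-alignment shows the planted tandem array (direct
matches) and inverted repeat copy. The other scripts in `examples/`
walk one capability each: simulation, deconcatenation, clustering,
annotation, dynamics and transcript assignment.

The full pipeline runs from one config:

```bash
circulome run --seed 42 --outdir run/      # or: python -m circulome.cli
```

writing per-stage artifacts (FASTA/GFF3/BED/TSV) and a consolidated
`report.json`. Each stage is also an independent subcommand
(`circulome deconcat|cluster|annotate|hotspots|dynamics|ecc-transcripts`).

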