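# promarch

Core-promoter architecture analysis for TSS-seq data, on a fully synthetic,
fully controlled test-bed.

## The problem

TSS-seq (oligo-capping 5'-end sequencing) maps the exact transcription start
sites (TSS) of a genome: each mapped read start marks one initiation event.
For a fragmented, AT-rich insect genome assembly, the analysis questions are:

* Where do reads pile up into *tag clusters*, and which clusters sit on a
  gene's first coding exon / 5'UTR (promoter-bearing) rather than elsewhere?
* Is initiation at each promoter *narrow* (focused) or *broad*, and if
  broad, does one position still dominate?
* Which canonical core-promoter elements — BREu, TATA, BREd, INR, MTE,
  DPE — occur in the 100 bp core promoter, at their biologically functional
  positions, more often than chance?
* Do motifs co-occur non-randomly, how do TATA-containing and TATA-less
  promoters differ, and which GO terms dominate each promoter class?

`promarch` implements this pipeline end to end and ships a synthetic-data
generator that emulates the inputs (AT-rich scaffolds, gene models with
5'UTRs, three read-distribution archetypes, transposons, planted consensus
motifs, skewed GO maps), so every stage is testable against a known truth.

## The statistics at the core

**Peakedness.** For a tag cluster *g* with *m* tags at the modal TSS
position, *n* tags in total and a TSS distribution of width *w* (bp),

    S_g = m / (n · w)

so a single-TSS cluster has S_g = 1, and S_g falls as initiation spreads.
Clusters with ≤ 10 distinct TSS positions are *narrow*; broader clusters are
*broad with peak* when the mode holds ≥ 50 % of tags, else *broad without
peak*.

**Motif calls.** Each motif is a position frequency matrix; matches are
log-odds-scored against a mononucleotide background estimated from the input
promoters, and each score gets an exact p-value from a dynamic-programming
convolution of the per-column score distributions (lattice step 10⁻³ bits —
equal to brute-force enumeration of all 4^L words). Hits need p ≤ 10⁻² and a
start inside the motif's functional window (e.g. TATA at −31…−24) ± 5 bp.

**Enrichment.** True promoters are compared with per-sequence shuffled
promoters (identical base composition) by an exact one-sided binomial test;
k-way motif co-occurrence is flagged against a 95 % Wald band around the
independence expectation; GO terms are called over-represented per promoter
class by a nearest-rank 75th-percentile rule.

## Worked example

Run the numbered drivers in order (defaults: 60 genes, seed 42; outputs under
`results/`):

```bash
python analysis/01_simulate.py
python analysis/02_cluster_tags.py
python analysis/03_promoter_shape.py
python analysis/04_composition.py
python analysis/05_motifs.py
python analysis/06_enrichment.py
```

`01` reports a genome of 10 scaffolds with A+T = 0.649 (two scaffolds stay
gene-less), 17,139 mapped reads. `02` merges them into 260 raw clusters of
which 60 pass the 100-tag threshold, all classified promoter-bearing. `03`
prints the shape table

```
broad_without_peak     42  (70%)
broad_with_peak        16  (27%)
narrow                  2  (3%)
```

with S_g ranging 0.0003–0.0595 here (only a single-TSS cluster would reach
S_g = 1), and 3 promoters excluded for transposon overlap. `04` shows the
core stays AT-rich (A+T ≈ 0.646) and the modal −1/+1 dinucleotide is CA
(0.250) — the planted initiator's C⁻¹A⁺¹ signature. `05` annotates motifs at
p ≤ 0.01 in functional windows (e.g. INR in 49.1 % of promoters, TATA in
31.6 %), and `06` finds BREu, INR and MTE significantly enriched over the
shuffled background (p = 0.019, <10⁻⁴, 0.045), no pairwise co-occurrence
outside its 95 % band in this small run, and per-class over-represented GO
terms. Planted-motif truth is recovered for >90 % of plantings when
promoters are anchored at the true TSS (see `tests/test_acceptance.py`);
with measured TSSs, recovery drops on broad promoters because the dominant
TSS wobbles — a property of broad initiation, not of the scanner.

## Layout

* `src/promarch/` — library: `synthetic_data`, `tag_clustering`,
  `promoter_shape`, `nucleotide_composition`, `motif_annotation`,
  `enrichment_stats`, `pipeline`, `io`.
* `analysis/` — the numbered drivers above (thin wrappers over the library).
* `tests/` — unit, property and end-to-end suites.
* `docs/methods.md` — models, parameter choices, numerical details and
  limitations.
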