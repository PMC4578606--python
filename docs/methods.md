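# Methods

## Pipeline overview

The analysis chain is: mapped TSS-seq read intervals (BED6) → strand-aware
tag clusters → size filter (≥ 100 tags) → positional classification against
gene models → per-gene promoter cluster → dominant TSS and peakedness →
shape class → −50/+50 core promoter (transposon-flagged) → composition
profiles → window-restricted PWM motif annotation → shuffled-background
enrichment, co-occurrence, TATA partition and GO statistics. All coordinates
are 0-based half-open internally; GFF3 is written/read 1-based closed.
TSS-relative coordinates have no position 0: +1 is the TSS base, so the
−50…+50 core promoter is exactly 100 nt.

## Tag clustering

Reads merge transitively when they share ≥ 1 base on the same scaffold and
strand. The merge criterion is exposed as `merge_gap`: the default −1
requires true overlap; `merge_gap=1` reproduces the gap-tolerant semantics
of `bedtools merge -d 1`, since it is ambiguous which of the two an upstream
BEDTOOLS run would have produced — the stated intent (shared bases) is the
default. Clusters are never formed across strands; antisense reads over a
gene are classified only against same-strand features.

Each cluster records a histogram of read 5'-end positions (interval start on
+, last base on −). Cluster classification precedence: (a) *five_prime* when
the cluster overlaps a gene's 5'UTR or first coding exon, or lies within
300 bp (a typical mean 5'UTR length, configurable) upstream of the 5'UTR
start — anchored on the first coding exon instead when the 5'UTR is absent
or ≤ 10 bp; (b) *other_genic* on any other same-strand gene overlap; (c)
*geneless_scaffold*; (d) *periphery* when within one median gene length of a
scaffold end (clusters there cannot be confidently assigned to a gene on a
fragmented assembly); (e) *intergenic*. five_prime outranks other_genic
because the promoter-bearing class is what the downstream analysis consumes.

## Peakedness and shape

S_g = m/(n·w) with m the modal tag count, n the total and w the *span of
distinct TSS positions* (max − min + 1). Using the TSS-distribution span
rather than the merged-interval width (which read length inflates) is
deliberate: a single-TSS cluster must reach S_g = 1, which is impossible
under interval width. Ties for the dominant TSS break toward the upstream
position in transcript orientation; ties between candidate clusters of one
gene break the same way after the tag-count criterion. Shape classes:
≤ 10 distinct positions → narrow; otherwise mode ≥ 50 % of tags → broad
with peak, else broad without peak.

## Core promoters and composition

The core promoter is the genomic −50/+50 window around the dominant TSS,
reverse-complemented on −; windows reaching past a scaffold end are N-padded
with a warning. Promoters whose genomic window intersects any transposon
interval by ≥ 1 bp are flagged and excluded from motif annotation (motif
statistics inside mobile elements would reflect the element, not the
promoter). Composition profiles (−200/+100) exclude N from numerator and
denominator, so every counted row is a proper distribution; the −1/+1
dinucleotide table is computed the same way.

## Motif annotation

Six canonical elements with default functional windows of allowed match
*start* positions (TSS-relative): BREu −38…−32, TATA −31…−24, BREd −23…−17,
INR −2…+4, MTE +18…+27, DPE +28…+32, each ± 5 bp elasticity. These are
canonical metazoan placements shipped as configurable defaults, not
assertions about any particular species. Scanning is in transcript
orientation only — core elements are orientation-specific. PFMs are smoothed
with a pseudocount of 0.8 per cell before column normalization; scores are
log₂ odds against a mononucleotide background estimated from the input
promoters (zero frequencies floored at 10⁻⁴ and renormalized).

P-values are exact: per-column scores are discretized to a 10⁻³-bit lattice
and the total-score distribution under the background is built by
dynamic-programming convolution; the scanner evaluates matches on the same
lattice, so the DP tail probability equals full 4^L enumeration up to float
summation error (verified to 10⁻⁶ for L ≤ 8). Retained hits need
p ≤ 10⁻² and a window-consistent start; multiple hits of one motif collapse
to presence/absence, since all downstream statistics are per-promoter
occurrence. Promoters containing N are skipped by the scanner with a
warning (they are rare and would need an N-scoring convention).

## Enrichment statistics

Shuffled promoter sets permute each sequence's own bases (per-sequence
composition preserved exactly, seeded). Motif-count enrichment between true
and shuffled sets uses an exact one-sided binomial comparison conditional on
the combined count: p = P(X ≥ true_count) with
X ~ Binomial(true + random, ½). This is the calibrated reading of a paired
real-vs-random comparison: simulating both counts from one Binomial(n, p)
null rejects at ~1–4 % at α = 0.05. An alternative formulation — a
one-sample binomial tail against the shuffled rate
p̂ = (random + 0.5)/(n + 1) — is available as `method="estimated-null"`;
it is anti-conservative (~10–12 % null rejection) because it ignores the
sampling noise of the shuffled count, and is kept for comparison only.

Co-occurrence examines all C(6,2) = 15 pairs and C(6,3) = 20 triples per
shape class: observed joint percent vs the product of the class marginals,
flagged when outside a 95 % Wald band expected ± 1.96·√(e(1−e)/N). The band
is centred on the independence expectation with the class size N; note that
when the expectation is estimated from the same sample, observed and
expected are positively correlated and the flag rate under true independence
falls *below* the nominal 5 % — the band is a screening device, not a
calibrated test. The interval construction itself is calibrated: an
observed proportion drawn independently at the expectation exits the band
~5 % of the time (checked in the acceptance suite).

GO over-representation per shape class counts term occurrences and reports
terms at or above the nearest-rank 75th percentile of the class's count
distribution — deterministic and well-defined for the short count vectors
involved. No multiple-testing correction is applied anywhere; the procedures
are reported as-is.

## Synthetic data generator

The generator emulates the study inputs, not any particular genome:

* **Scaffolds** — i.i.d. bases with A+T = 0.65 by default (AT-rich insect
  regime); 10 scaffolds × 75 kb, the last two kept gene-less.
* **Genes** — 60 by default, 1.5–7.5 kb (median ≈ 4.5 kb), placed in
  non-overlapping slots with 400 bp free margins; each has a 50–300 bp
  5'UTR and one or two CDS exons (an intron when room permits).
* **Read archetypes** — narrow: point mass (0.55) plus a truncated
  geometric tail over ≤ 10 positions; broad with peak: discretized Gaussian
  (σ = 20, clipped at ± 60) with a 0.62 modal spike; broad without peak:
  the Gaussian alone (σ = 18). Mixture 5/23/72 % and 150–400 reads per gene
  by default — a deep-coverage regime where the three archetypes are
  separable by the shape rules (≥ 95 % recovery at 200 reads/gene). Widths
  are tunable, not calibrated to any real dispersion, which is unknown.
* **Background reads** — 200 scattered locations with 1–3 reads, placed
  ≥ 300 bp from any true TSS so noise exercises the size filter without
  corrupting gene clusters.
* **Motifs** — consensus strings (BREu GGGCGCC, TATA TATAAA, BREd GTTTGTT,
  INR TCAGTT, MTE CGAACGGA, DPE AGACGT) written at the centre of each
  functional window with per-motif Bernoulli rates (TATA 0.30, INR 0.40,
  …), on the coding strand in transcript orientation. Consensus planting
  guarantees PWM-detectable instances without asserting any specific
  matrix; the shipped default PFMs are sharp matrices around the same
  consensi, and external JASPAR files can be substituted.
* **Transposons** — uniform 200–1000 bp intervals to ~2 % genome coverage,
  so a few percent of promoters get flagged, as in real fragmented
  assemblies.
* **GO map** — 60 % of genes get 1–3 of 20 terms drawn with Zipf(1.5)
  weights, giving the few-common/many-rare skew the percentile rule needs.

Everything is a deterministic function of the config seed (reads and GO use
child seeds of it), and written outputs are byte-identical across runs.

What the generator does *not* emulate: sequencing error, adapter artefacts,
multi-mapping, realistic scaffold-length distributions, degenerate motif
instances, or correlated motif placement. Passing tests therefore show the
*procedures* are correct and calibrated on data with known truth — not that
any biological conclusion transfers to a real genome.

## Problem sizes and determinism

The test and acceptance suites run at deliberately modest sizes chosen as
the package's own working scale: 150 genes × 200 reads for archetype and
planted-motif recovery, 1,000 random read sets for the clustering oracle,
4^L enumeration up to L = 8 for the p-value check, 2,000 replicates for the
null calibrations. All randomness flows through explicit seeds
(`numpy.random.default_rng`), and property tests run derandomised.

## Known limitations

* Dominant-TSS wobble on broad promoters displaces motif windows; planted
  motif recovery is therefore specified at the true TSS. On measured TSSs
  recovery degrades with initiation width — a real phenomenon any TSS-seq
  motif analysis inherits.
* The exact functional-window coordinates and PFM versions are inputs, not
  facts the package asserts; all defaults are configurable.
* One promoter per gene: alternative promoters are discarded by design
  (the best-supported cluster wins).
* The Wald co-occurrence band and the 75th-percentile GO rule are screening
  heuristics, reported without multiplicity control.
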