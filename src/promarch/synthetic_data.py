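"""Synthetic AT-rich genome, TSS-seq read and GO-annotation generator.

The generator emulates the inputs of an insect TSS-seq promoter study:
fragmented AT-rich scaffolds carrying single-transcript genes with 5'UTRs,
mapped 5'-end read distributions of three initiation archetypes (narrow;
broad with a dominant peak; broad without a peak), transposon intervals,
canonical core-promoter motif consensi planted at their functional windows,
and a sparse, skewed gene-to-GO map.  Every output is a pure function of
the :class:`SimConfig` (including its seed), byte for byte.

Initiation archetypes
---------------------
* ``narrow`` — a point mass at the true TSS plus a geometric tail truncated
  to at most 10 distinct positions.
* ``broad_with_peak`` — a discretized Gaussian with an injected modal spike
  so the mode carries at least half the tags.
* ``broad_without_peak`` — a discretized Gaussian alone; the mode stays far
  below half the tags and more than 10 positions are hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BED6_COLUMNS, GeneModel
from .motif_annotation import MOTIF_CONSENSUS, DEFAULT_WINDOWS, MOTIF_NAMES

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SHAPE_CLASSES = ("narrow", "broad_with_peak", "broad_without_peak")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    Defaults mirror the study conditions the pipeline is meant to exercise:
    an AT-rich genome (A+T ~ 0.65), genes a few kb long with 5'UTRs up to
    ~300 bp, deep tag coverage per gene (well above the 100-tag cluster
    threshold), a shape mixture dominated by broad initiation, and a ~2 %
    transposon load.
    """

    n_scaffolds: int = 10
    scaffold_length: int = 75_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (1_500, 7_500)
    utr_length_range: tuple[int, int] = (50, 300)
    at_fraction: float = 0.65
    shape_mix: tuple[float, float, float] = (0.05, 0.23, 0.72)
    reads_per_gene_range: tuple[int, int] = (150, 400)
    read_length: int = 25
    motif_plant_rates: dict[str, float] = field(
        default_factory=lambda: {
            "BREu": 0.15,
            "BREd": 0.15,
            "TATA": 0.30,
            "INR": 0.40,
            "MTE": 0.20,
            "DPE": 0.25,
        }
    )
    transposon_density: float = 0.02
    n_background_reads: int = 200
    n_go_terms: int = 20
    go_annotation_rate: float = 0.6
    go_skew: float = 1.5
    seed: int = 42

    def __post_init__(self) -> None:
        if abs(sum(self.shape_mix) - 1.0) > 1e-9:
            raise ValueError("shape_mix must sum to 1")
        for lo, hi in (self.gene_length_range, self.utr_length_range, self.reads_per_gene_range):
            if lo > hi:
                raise ValueError("range low must be <= high")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValueError("at_fraction must lie in [0, 1]")
        unknown = set(self.motif_plant_rates) - set(MOTIF_NAMES)
        if unknown:
            raise ValueError(f"unknown motifs in motif_plant_rates: {sorted(unknown)}")


@dataclass
class SimGenome:
    """In-memory result of :func:`generate_genome`."""

    scaffolds: dict[str, str]
    genes: list[GeneModel]
    transposons: pd.DataFrame  # BED6 columns
    truth: pd.DataFrame  # gene_id, scaffold, strand, true_tss, true_shape, planted_motifs


class CapacityError(ValueError):
    """Requested gene density cannot be placed on the requested scaffolds."""


# Margin kept free of genes on each side of a gene slot; leaves room for the
# -200 composition window, read scatter (<= ~85 bp) and keeps neighbouring
# read clouds from merging into one tag cluster.
_SLOT_MARGIN = 400


def _tss_relative_to_offset(pos: int) -> int:
    """Map a TSS-relative position (no 0; +1 is the TSS base) to a 0-based offset."""
    if pos == 0:
        raise ValueError("TSS-relative coordinates have no position 0")
    return pos if pos < 0 else pos - 1


def _plant_start(window: tuple[int, int], motif_len: int) -> int:
    """TSS-relative start used when planting a consensus inside its window."""
    lo, hi = window
    span = (hi - lo + 1) - (1 if lo < 0 < hi else 0)  # window skips position 0
    start = lo + max(0, (span - motif_len) // 2)
    if start == 0:
        start = 1
    return start


def generate_genome(config: SimConfig) -> SimGenome:
    """Simulate scaffolds, gene models, transposons and the per-gene truth table.

    Genes are placed on all but the last two scaffolds (those stay gene-less
    to exercise the gene-less-scaffold classification), in non-overlapping
    slots with a fixed free margin.  Raises :class:`CapacityError` when the
    requested genes cannot fit.
    """
    rng = np.random.default_rng(config.seed)
    scaffold_names = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]

    p_at = config.at_fraction / 2.0
    p_gc = (1.0 - config.at_fraction) / 2.0
    base_probs = np.array([p_at, p_gc, p_gc, p_at])  # A C G T
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {
        name: rng.choice(bases, size=config.scaffold_length, p=base_probs).copy()
        for name in scaffold_names
    }

    n_gene_scaffolds = max(1, config.n_scaffolds - 2) if config.n_scaffolds > 1 else 1
    gene_scaffolds = scaffold_names[:n_gene_scaffolds]
    slot_size = config.gene_length_range[1] + 2 * _SLOT_MARGIN
    slots_per_scaffold = (config.scaffold_length - 2 * _SLOT_MARGIN) // slot_size
    capacity = slots_per_scaffold * len(gene_scaffolds)
    if config.n_genes > capacity:
        raise CapacityError(
            f"cannot place {config.n_genes} genes: capacity is {capacity} "
            f"({slots_per_scaffold} slots on each of {len(gene_scaffolds)} scaffolds)"
        )

    slots = [
        (scaf, _SLOT_MARGIN + j * slot_size)
        for scaf in gene_scaffolds
        for j in range(slots_per_scaffold)
    ]

    genes: list[GeneModel] = []
    truth_rows = []
    shape_draws = rng.choice(len(SHAPE_CLASSES), size=config.n_genes, p=list(config.shape_mix))
    for i in range(config.n_genes):
        scaf, slot_start = slots[i]
        glen = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        ulen = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        jitter = int(rng.integers(0, slot_size - glen - 2 * _SLOT_MARGIN + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = slot_start + _SLOT_MARGIN + jitter
        gend = gstart + glen
        gene_id = f"gene_{i + 1:04d}"

        if strand == "+":
            tss = gstart
            utr5 = (gstart, gstart + ulen)
            cds = _split_cds(gstart + ulen, gend, rng)
        else:
            tss = gend - 1
            utr5 = (gend - ulen, gend)
            cds = _split_cds(gstart, gend - ulen, rng)

        genes.append(GeneModel(gene_id, scaf, strand, gstart, gend, utr5, cds))

        planted = sorted(
            m for m, rate in config.motif_plant_rates.items() if rng.random() < rate
        )
        _plant_motifs(seqs[scaf], tss, strand, planted)
        truth_rows.append(
            {
                "gene_id": gene_id,
                "scaffold": scaf,
                "strand": strand,
                "true_tss": tss,
                "true_shape": SHAPE_CLASSES[shape_draws[i]],
                "planted_motifs": ",".join(planted),
            }
        )

    transposons = _place_transposons(rng, scaffold_names, config)
    scaffolds = {name: arr.tobytes().decode("ascii") for name, arr in seqs.items()}
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "scaffold", "strand", "true_tss", "true_shape", "planted_motifs"],
    )
    return SimGenome(scaffolds=scaffolds, genes=genes, transposons=transposons, truth=truth)


def _split_cds(start: int, end: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Two CDS exons separated by an intron when there is room, else one."""
    length = end - start
    if length >= 900:
        exon1 = int(rng.integers(200, length // 2))
        intron = int(rng.integers(100, 300))
        return [(start, start + exon1), (start + exon1 + intron, end)]
    return [(start, end)]


def _plant_motifs(seq: np.ndarray, tss: int, strand: str, motifs: list[str]) -> None:
    for name in motifs:
        consensus = MOTIF_CONSENSUS[name]
        rel_start = _plant_start(DEFAULT_WINDOWS[name], len(consensus))
        pos = rel_start
        for base in consensus:
            off = _tss_relative_to_offset(pos)
            if strand == "+":
                seq[tss + off] = base.encode()
            else:
                seq[tss - off] = base.translate(COMPLEMENT).encode()
            pos += 1
            if pos == 0:
                pos = 1


def _place_transposons(
    rng: np.random.Generator, scaffold_names: list[str], config: SimConfig
) -> pd.DataFrame:
    total = config.n_scaffolds * config.scaffold_length
    target = config.transposon_density * total
    rows = []
    covered = 0.0
    i = 0
    while covered < target:
        length = int(rng.integers(200, 1_001))
        scaf = scaffold_names[int(rng.integers(len(scaffold_names)))]
        start = int(rng.integers(0, config.scaffold_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((scaf, start, start + length, f"TE_{i + 1:04d}", 0, strand))
        covered += length
        i += 1
    df = pd.DataFrame(rows, columns=BED6_COLUMNS)
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSS-seq reads


def _narrow_offsets(rng: np.random.Generator, n: int) -> np.ndarray:
    """Point mass at 0 plus a geometric tail over offsets 1..9 (<=10 positions)."""
    tail = 0.5 ** np.arange(1, 10)
    probs = np.concatenate([[0.55], 0.45 * tail / tail.sum()])
    return rng.choice(np.arange(10), size=n, p=probs)


def _broad_offsets(rng: np.random.Generator, n: int, spike: bool) -> np.ndarray:
    sigma = 20.0 if spike else 18.0
    gauss = np.rint(rng.normal(0.0, sigma, size=n)).astype(int)
    gauss = np.clip(gauss, -60, 60)
    if spike:
        at_mode = rng.random(n) < 0.62
        gauss[at_mode] = 0
    return gauss


def generate_tss_reads(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Simulate mapped TSS-seq read intervals (BED6) from the truth table.

    Read 5' ends are drawn from the gene's archetype distribution around its
    true TSS; each read is a ``read_length`` interval oriented with the gene
    strand.  Scattered low-count background reads are added in intergenic
    space well away from any true TSS so they stay below the cluster-size
    threshold without perturbing gene clusters.
    """
    if truth.empty:
        raise ValueError("truth table is empty; generate a genome with genes first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    rl = config.read_length
    for rec in truth.itertuples():
        n_reads = int(rng.integers(*config.reads_per_gene_range, endpoint=True))
        if rec.true_shape == "narrow":
            offsets = _narrow_offsets(rng, n_reads)
        else:
            offsets = _broad_offsets(rng, n_reads, spike=rec.true_shape == "broad_with_peak")
        if rec.strand == "+":
            five = rec.true_tss + offsets
            starts, ends = five, five + rl
        else:
            five = rec.true_tss - offsets
            starts, ends = five - rl + 1, five + 1
        for j, (s, e) in enumerate(zip(starts, ends)):
            rows.append(
                (rec.scaffold, max(int(s), 0), min(int(e), config.scaffold_length),
                 f"{rec.gene_id}_r{j + 1}", 0, rec.strand)
            )

    tss_by_scaffold: dict[str, list[int]] = {}
    for rec in truth.itertuples():
        tss_by_scaffold.setdefault(rec.scaffold, []).append(rec.true_tss)
    scaffold_names = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    placed = 0
    k = 0
    while placed < config.n_background_reads and k < 50 * (config.n_background_reads + 1):
        k += 1
        scaf = scaffold_names[int(rng.integers(len(scaffold_names)))]
        pos = int(rng.integers(0, config.scaffold_length - rl))
        if any(abs(pos - t) < 300 for t in tss_by_scaffold.get(scaf, [])):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        copies = int(rng.integers(1, 4))
        for c in range(copies):
            rows.append((scaf, pos, pos + rl, f"bg_{placed + 1}_{c + 1}", 0, strand))
        placed += 1

    df = pd.DataFrame(rows, columns=BED6_COLUMNS)
    return df.sort_values(["chrom", "start", "end", "name"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GO annotations


def generate_go_annotations(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Assign 1-3 GO terms to a subset of genes with Zipf-skewed term usage."""
    if config.n_go_terms < 1:
        raise ValueError("n_go_terms must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    terms = np.array([f"GO:{i + 1:07d}" for i in range(config.n_go_terms)])
    weights = 1.0 / np.arange(1, config.n_go_terms + 1) ** config.go_skew
    probs = weights / weights.sum()
    rows = []
    for rec in truth.itertuples():
        if rng.random() >= config.go_annotation_rate:
            continue
        k = min(int(rng.integers(1, 4)), config.n_go_terms)
        chosen = rng.choice(terms, size=k, replace=False, p=probs)
        for term in sorted(chosen):
            rows.append((rec.gene_id, term))
    return pd.DataFrame(rows, columns=["gene_id", "go_term"])
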