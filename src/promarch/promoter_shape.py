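"""Promoter shape: dominant TSS, peakedness score and core promoter extraction.

The individual peakedness score of a tag cluster g is

    S_g = m / (n * w)

with m the tag count at the modal (dominant) TSS position, n the total tag
count, and w the width of the TSS 5'-end distribution (max - min position
+ 1).  A single-TSS cluster has S_g = 1, the maximum.  Shape classes:
clusters with at most 10 distinct TSS positions are *narrow*; broader
clusters are *broad_with_peak* when the mode holds at least half the tags,
else *broad_without_peak*.

Core promoters are the 100 bases around the dominant TSS, positions
-50..-1,+1..+50 in transcript orientation (no position 0; +1 is the TSS
base).  Promoters whose genomic window touches a transposon are flagged and
excluded from motif annotation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import fetch
from .tag_clustering import TagCluster

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterShape:
    m: int  # tag count at the modal TSS position
    n: int  # total tags in the cluster
    w: int  # width of the TSS position distribution (bp)
    sg: float
    n_positions: int
    shape_class: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.m <= self.n and 1 <= self.n_positions <= self.w):
            raise ValueError("inconsistent peakedness components")
        if abs(self.sg - self.m / (self.n * self.w)) > 1e-12:
            raise ValueError("sg must equal m/(n*w)")


@dataclass
class CorePromoter:
    gene_id: str
    scaffold: str
    tss: int  # genomic position of the +1 base (0-based)
    strand: str
    sequence: str  # 100 nt, transcript orientation
    transposon_overlap: bool

    def __post_init__(self) -> None:
        if len(self.sequence) != 100:
            raise ValueError("core promoter must be exactly 100 nt")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("core promoter alphabet is A/C/G/T/N")


def dominant_tss(cluster: TagCluster) -> int:
    """The modal 5'-end position; ties break toward the upstream position."""
    if not cluster.tss_histogram:
        raise ValueError("empty TSS histogram")
    best = max(cluster.tss_histogram.values())
    candidates = [p for p, c in cluster.tss_histogram.items() if c == best]
    return min(candidates) if cluster.strand == "+" else max(candidates)


def peakedness(cluster: TagCluster) -> PromoterShape:
    """Compute the peakedness components (m, n, w, S_g) of a cluster."""
    hist = cluster.tss_histogram
    if not hist:
        raise ValueError("empty TSS histogram")
    m = max(hist.values())
    n = sum(hist.values())
    w = max(hist) - min(hist) + 1
    return PromoterShape(m=m, n=n, w=w, sg=m / (n * w), n_positions=len(hist))


def classify_shape(shape: PromoterShape) -> str:
    """narrow (<=10 TSS positions), else split broad clusters on the 50% mode rule."""
    if shape.n_positions <= 10:
        cls = "narrow"
    elif shape.m >= 0.5 * shape.n:
        cls = "broad_with_peak"
    else:
        cls = "broad_without_peak"
    shape.shape_class = cls
    return cls


def select_gene_cluster(candidates: list[TagCluster]) -> TagCluster:
    """Pick the gene's promoter cluster: most tags, ties toward upstream."""
    if not candidates:
        raise ValueError("no candidate clusters for this gene")

    def key(c: TagCluster):
        upstream = c.start if c.strand == "+" else -c.end
        return (-c.tag_count, upstream)

    return min(candidates, key=key)


def extract_window(genome, scaffold: str, tss: int, strand: str,
                   upstream: int, downstream: int) -> str:
    """Sequence at -upstream..-1,+1..+downstream around a TSS, transcript orientation.

    Position +1 is the TSS base; position 0 does not exist, so the result has
    exactly ``upstream + downstream`` bases.  Flanks falling off the scaffold
    are N-padded with a warning.
    """
    if strand == "+":
        g_start, g_end = tss - upstream, tss + downstream
    else:
        g_start, g_end = tss - downstream + 1, tss + upstream + 1
    seq = fetch(genome, scaffold, g_start, g_end)
    if "N" in seq and (g_start < 0 or g_end > len(genome[scaffold])):
        warnings.warn(
            f"TSS {scaffold}:{tss} within {max(upstream, downstream)} bp of a scaffold end; "
            "flank padded with N",
            stacklevel=2,
        )
    return seq if strand == "+" else _revcomp(seq)


def extract_core_promoter(genome, scaffold: str, tss: int, strand: str,
                          transposons: pd.DataFrame | None = None,
                          gene_id: str = ".") -> CorePromoter:
    """Extract the -50/+50 core promoter and flag transposon entanglement.

    The transposon flag is set when the genomic 100-bp window shares at least
    one base with any transposon interval (BED6 frame), regardless of strand.
    """
    sequence = extract_window(genome, scaffold, tss, strand, upstream=50, downstream=50)
    if strand == "+":
        g_start, g_end = tss - 50, tss + 50
    else:
        g_start, g_end = tss - 49, tss + 51
    overlap = False
    if transposons is not None and len(transposons):
        on_scaf = transposons[transposons["chrom"] == scaffold]
        overlap = bool(((on_scaf["start"] < g_end) & (on_scaf["end"] > g_start)).any())
    return CorePromoter(gene_id, scaffold, tss, strand, sequence, overlap)
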