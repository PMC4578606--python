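"""Strand-aware merging of mapped TSS-seq reads into tag clusters.

Reads on the same scaffold and strand that share at least one base are
merged transitively into one cluster; each cluster keeps a histogram of
read 5'-end positions (the interval start on +, the last base on -).
Clusters are then size-filtered (the deep-coverage threshold is 100 tags)
and classified against gene models: promoter-bearing (first coding exon /
5'UTR / proximal upstream), other genic, intergenic, gene-less scaffold,
or scaffold periphery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel

CATEGORIES = ("five_prime", "other_genic", "intergenic", "geneless_scaffold", "periphery")


@dataclass
class TagCluster:
    scaffold: str
    strand: str
    start: int  # half-open 0-based merged interval
    end: int
    tag_count: int
    tss_histogram: dict[int, int]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cluster end must exceed start")
        if self.tag_count != sum(self.tss_histogram.values()) or self.tag_count < 1:
            raise ValueError("tag_count must equal the histogram total (>= 1)")
        if any(not self.start <= p < self.end for p in self.tss_histogram):
            raise ValueError("histogram positions must lie inside the cluster interval")


@dataclass
class ClusterAnnotation:
    cluster: TagCluster
    category: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        needs_gene = self.category in ("five_prime", "other_genic")
        if needs_gene != (self.gene_id is not None):
            raise ValueError("gene_id must be present iff the category is genic")


def merge_reads(reads: pd.DataFrame, merge_gap: int = -1) -> list[TagCluster]:
    """Merge read intervals into tag clusters per (scaffold, strand).

    Two reads merge when ``next.start - current.end <= merge_gap``; the
    default ``merge_gap=-1`` requires a true overlap of at least one base
    (abutting reads stay separate).  ``merge_gap=1`` reproduces the gap-1
    tolerance of ``bedtools merge -d 1``.  Output is sorted by scaffold,
    strand and start.
    """
    clusters: list[TagCluster] = []
    if reads.empty:
        return clusters
    for (scaf, strand), grp in reads.groupby(["chrom", "strand"], sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.lexsort((ends, starts))
        starts, ends = starts[order], ends[order]
        five = starts if strand == "+" else ends - 1
        cur_start, cur_end = int(starts[0]), int(ends[0])
        hist: dict[int, int] = {int(five[0]): 1}
        for i in range(1, len(starts)):
            if starts[i] - cur_end <= merge_gap:
                cur_end = max(cur_end, int(ends[i]))
                hist[int(five[i])] = hist.get(int(five[i]), 0) + 1
            else:
                clusters.append(
                    TagCluster(scaf, strand, cur_start, cur_end, sum(hist.values()), hist)
                )
                cur_start, cur_end = int(starts[i]), int(ends[i])
                hist = {int(five[i]): 1}
        clusters.append(TagCluster(scaf, strand, cur_start, cur_end, sum(hist.values()), hist))
    clusters.sort(key=lambda c: (c.scaffold, c.strand, c.start))
    return clusters


def filter_clusters(clusters: list[TagCluster], min_tags: int = 100) -> list[TagCluster]:
    """Keep clusters with at least ``min_tags`` reads, preserving order."""
    if min_tags < 1:
        raise ValueError("min_tags must be >= 1")
    return [c for c in clusters if c.tag_count >= min_tags]


def median_gene_length(genes: list[GeneModel]) -> float:
    """Median gene length in bp; the mean of the two middle values when even."""
    if not genes:
        raise ValueError("median gene length needs at least one gene")
    return float(np.median([g.length for g in genes]))


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _five_prime_region(gene: GeneModel, utr_upstream: int) -> list[tuple[int, int]]:
    """Genomic intervals whose overlap marks a cluster as promoter-bearing.

    The 5'UTR, the first coding exon, and the ``utr_upstream`` window upstream
    (in transcript orientation) of the 5'UTR start — or of the first coding
    exon when the 5'UTR is absent or at most 10 bp.
    """
    regions: list[tuple[int, int]] = []
    utr_usable = gene.utr5 is not None and (gene.utr5[1] - gene.utr5[0]) > 10
    if gene.utr5 is not None:
        regions.append(gene.utr5)
    first_cds = gene.first_cds_exon
    if first_cds is not None:
        regions.append(first_cds)
    anchor_iv = gene.utr5 if utr_usable else (first_cds or gene.utr5)
    if anchor_iv is not None:
        if gene.strand == "+":
            regions.append((anchor_iv[0] - utr_upstream, anchor_iv[0]))
        else:
            regions.append((anchor_iv[1], anchor_iv[1] + utr_upstream))
    return regions


def annotate_cluster(cluster: TagCluster, genes: list[GeneModel],
                     scaffold_len: dict[str, int], utr_upstream: int = 300,
                     periphery_margin: float | None = None) -> ClusterAnnotation:
    """Classify one tag cluster against same-strand gene models.

    Precedence: promoter-bearing (five_prime) > other_genic > gene-less
    scaffold > periphery > intergenic.  ``periphery_margin`` defaults to the
    median gene length of the annotation.
    """
    if cluster.scaffold not in scaffold_len:
        raise KeyError(f"scaffold {cluster.scaffold!r} absent from the genome index")
    if periphery_margin is None:
        periphery_margin = median_gene_length(genes) if genes else 0.0

    same_strand = [
        g for g in genes if g.scaffold == cluster.scaffold and g.strand == cluster.strand
    ]
    for gene in same_strand:
        for start, end in _five_prime_region(gene, utr_upstream):
            if _overlaps(cluster.start, cluster.end, start, end):
                return ClusterAnnotation(cluster, "five_prime", gene.gene_id)
    for gene in same_strand:
        if _overlaps(cluster.start, cluster.end, gene.start, gene.end):
            return ClusterAnnotation(cluster, "other_genic", gene.gene_id)

    if not any(g.scaffold == cluster.scaffold for g in genes):
        return ClusterAnnotation(cluster, "geneless_scaffold")
    length = scaffold_len[cluster.scaffold]
    if cluster.start < periphery_margin or cluster.end > length - periphery_margin:
        return ClusterAnnotation(cluster, "periphery")
    return ClusterAnnotation(cluster, "intergenic")


def annotate_clusters(clusters: list[TagCluster], genes: list[GeneModel],
                      scaffold_len: dict[str, int], utr_upstream: int = 300,
                      periphery_margin: float | None = None) -> list[ClusterAnnotation]:
    if periphery_margin is None and genes:
        periphery_margin = median_gene_length(genes)
    return [
        annotate_cluster(c, genes, scaffold_len, utr_upstream, periphery_margin)
        for c in clusters
    ]


def clusters_to_frame(annotations: list[ClusterAnnotation]) -> pd.DataFrame:
    """Tabular view of annotated clusters for TSV export."""
    rows = [
        {
            "cluster_id": f"TC_{i + 1:05d}",
            "scaffold": a.cluster.scaffold,
            "strand": a.cluster.strand,
            "start": a.cluster.start,
            "end": a.cluster.end,
            "tag_count": a.cluster.tag_count,
            "category": a.category,
            "gene_id": a.gene_id or ".",
        }
        for i, a in enumerate(annotations)
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "scaffold", "strand", "start", "end", "tag_count", "category", "gene_id"],
    )
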