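#!/usr/bin/env python
"""Merge mapped TSS-seq reads into strand-aware tag clusters, keep clusters
with at least 100 tags, and classify each against the gene models
(promoter-bearing / other genic / intergenic / gene-less scaffold /
periphery).

Reads <results>/sim/, writes <results>/clusters.tsv.
"""

import argparse
from pathlib import Path

from promarch.io import read_bed, read_fasta, read_gff3, scaffold_lengths
from promarch.tag_clustering import (
    annotate_clusters,
    clusters_to_frame,
    filter_clusters,
    median_gene_length,
    merge_reads,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", default="results")
    parser.add_argument("--min-tags", type=int, default=100)
    args = parser.parse_args()

    results = Path(args.results_dir)
    sim = results / "sim"
    reads = read_bed(sim / "reads.bed")
    genes = read_gff3(sim / "genes.gff3")
    lengths = scaffold_lengths(read_fasta(sim / "genome.fa"))

    raw = merge_reads(reads)
    clusters = filter_clusters(raw, args.min_tags)
    annotations = annotate_clusters(clusters, genes, lengths)
    table = clusters_to_frame(annotations)
    table.to_csv(results / "clusters.tsv", sep="\t", index=False)

    print(f"{len(reads):,} reads -> {len(raw)} raw clusters -> "
          f"{len(clusters)} tag clusters with >= {args.min_tags} tags")
    print(f"median gene length: {median_gene_length(genes):.0f} bp (periphery margin)")
    print("cluster categories:")
    for cat, count in table["category"].value_counts().items():
        print(f"  {cat:18s} {count}")
    print(f"wrote {results / 'clusters.tsv'}")


if __name__ == "__main__":
    main()
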