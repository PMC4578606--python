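#!/usr/bin/env python
"""Simulate the study inputs: an AT-rich scaffolded genome with annotated
genes, transposon intervals, mapped TSS-seq read intervals of three
initiation archetypes, and a skewed gene-to-GO map.

Writes FASTA/GFF3/BED/TSV under <results>/sim/.
"""

import argparse
from pathlib import Path

from promarch import SimConfig, generate_genome, generate_go_annotations, generate_tss_reads
from promarch.io import write_bed, write_fasta, write_gff3


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", default="results")
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--n-genes", type=int, default=60)
    args = parser.parse_args()

    cfg = SimConfig(n_genes=args.n_genes, seed=args.seed)
    sim = generate_genome(cfg)
    reads = generate_tss_reads(sim.truth, cfg)
    go = generate_go_annotations(sim.truth, cfg)

    out = Path(args.results_dir) / "sim"
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.scaffolds, out / "genome.fa")
    write_gff3(sim.genes, out / "genes.gff3")
    write_bed(sim.transposons, out / "transposons.bed")
    write_bed(reads, out / "reads.bed")
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    go.to_csv(out / "go.tsv", sep="\t", index=False, header=False)

    genome = "".join(sim.scaffolds.values())
    at = (genome.count("A") + genome.count("T")) / len(genome)
    with_genes = {g.scaffold for g in sim.genes}
    print(f"simulated {cfg.n_scaffolds} scaffolds of {cfg.scaffold_length:,} bp "
          f"(A+T = {at:.3f}), {len(sim.genes)} genes on {len(with_genes)} scaffolds "
          f"({cfg.n_scaffolds - len(with_genes)} gene-less)")
    print(f"{len(reads):,} mapped reads, {len(sim.transposons)} transposon intervals, "
          f"{go['gene_id'].nunique()} GO-annotated genes")
    print(f"true shape mix: {sim.truth['true_shape'].value_counts().to_dict()}")
    print(f"outputs in {out}/")


if __name__ == "__main__":
    main()
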