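#!/usr/bin/env python
"""Per-position nucleotide composition of the -200/+100 regions around each
dominant TSS, and the -1/+1 initiator dinucleotide spectrum.

Reads <results>/sim/ + shapes.tsv, writes <results>/composition.tsv and
<results>/dinucleotides.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from promarch.io import read_fasta
from promarch.nucleotide_composition import composition_profile, initiator_dinucleotide
from promarch.promoter_shape import extract_window


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", default="results")
    args = parser.parse_args()

    results = Path(args.results_dir)
    genome = read_fasta(results / "sim" / "genome.fa")
    shapes = pd.read_csv(results / "shapes.tsv", sep="\t")

    wide = [
        extract_window(genome, r.scaffold, r.dominant_tss, r.strand, 200, 100)
        for r in shapes.itertuples()
    ]
    profile = composition_profile(wide, upstream=200, downstream=100)
    profile.index.name = "position"
    profile.to_csv(results / "composition.tsv", sep="\t")

    dinucs = initiator_dinucleotide(
        [extract_window(genome, r.scaffold, r.dominant_tss, r.strand, 50, 50)
         for r in shapes.itertuples()],
        upstream=50,
    )
    dinucs.rename("frequency").to_csv(results / "dinucleotides.tsv", sep="\t")

    at = (profile["A"] + profile["T"]).mean()
    core_at = (profile.loc[-50:50, "A"] + profile.loc[-50:50, "T"]).mean()
    top = dinucs.sort_values(ascending=False).head(3)
    print(f"{len(wide)} TSS-anchored -200/+100 regions profiled")
    print(f"mean A+T: {at:.3f} overall, {core_at:.3f} in the core (-50/+50)")
    print("top -1/+1 dinucleotides: "
          + ", ".join(f"{d}={f:.3f}" for d, f in top.items()))
    print(f"wrote {results / 'composition.tsv'} and {results / 'dinucleotides.tsv'}")


if __name__ == "__main__":
    main()
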