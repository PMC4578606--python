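#!/usr/bin/env python
"""Annotate the six canonical core-promoter motifs (BREu, TATA, BREd, INR,
MTE, DPE) in the extracted core promoters: PWM scan at p <= 1e-2 against a
background estimated from the input promoters, restricted to each motif's
functional window (+/-5 bp elasticity).

The PFMs are first serialized to JASPAR format and read back, so the run
exercises the same input path an external matrix set would take.  Writes
<results>/pfms.jaspar, motif_hits.tsv, motif_profiles.tsv, occurrence.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from promarch.motif_annotation import (
    ScoreDistribution,
    background_model,
    default_motif_models,
    motif_profiles,
    read_jaspar,
    scan_promoter,
    write_jaspar,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", default="results")
    parser.add_argument("--p-threshold", type=float, default=1e-2)
    parser.add_argument("--elasticity", type=int, default=5)
    args = parser.parse_args()

    results = Path(args.results_dir)
    pfm_path = results / "pfms.jaspar"
    write_jaspar(default_motif_models(elasticity=args.elasticity), pfm_path)
    models = read_jaspar(pfm_path, elasticity=args.elasticity)

    shapes = pd.read_csv(results / "shapes.tsv", sep="\t")
    seqs = {}
    for line in (results / "core_promoters.fa").read_text().splitlines():
        if line.startswith(">"):
            gene = line[1:].split("|")[0]
        elif line:
            seqs[gene] = line
    promoters = shapes[~shapes["transposon_overlap"]].copy()
    promoters["sequence"] = promoters["gene_id"].map(seqs)

    background = background_model(promoters["sequence"])
    dists = {m.name: ScoreDistribution(m, background) for m in models}
    hit_rows = []
    for rec in promoters.itertuples():
        for m in models:
            for h in scan_promoter(rec.sequence, m, background, args.p_threshold,
                                   distribution=dists[m.name]):
                hit_rows.append(
                    {"gene_id": rec.gene_id, "motif": h.motif, "start": h.start,
                     "score_bits": round(h.score, 3), "p_value": h.p_value}
                )
    pd.DataFrame(hit_rows).to_csv(results / "motif_hits.tsv", sep="\t", index=False)

    profiles, occurrence = motif_profiles(promoters, models, background, args.p_threshold)
    profiles.to_csv(results / "motif_profiles.tsv", sep="\t", index=False)
    occurrence.round(2).to_csv(results / "occurrence.tsv", sep="\t")

    bg = ", ".join(f"{b}={f:.3f}" for b, f in zip("ACGT", background))
    print(f"background from {len(promoters)} promoters: {bg}")
    print(f"{len(hit_rows)} retained window-consistent hits (p <= {args.p_threshold:g})")
    print("percent occurrence per motif:")
    print(occurrence.round(1).to_string())
    print(f"wrote {results / 'motif_hits.tsv'}, motif_profiles.tsv, occurrence.tsv")


if __name__ == "__main__":
    main()
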