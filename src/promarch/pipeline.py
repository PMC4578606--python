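"""End-to-end orchestration: simulate -> cluster -> shape -> promoters ->
composition -> motifs -> enrichment.

Each stage is a thin call into the corresponding module; the bundle this
returns is what the analysis drivers, the test-suite and the acceptance
script consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import enrichment_stats as es
from . import motif_annotation as ma
from . import nucleotide_composition as nc
from . import promoter_shape as ps
from . import synthetic_data as sd
from . import tag_clustering as tc


@dataclass
class PipelineResult:
    config: sd.SimConfig
    sim: sd.SimGenome
    reads: pd.DataFrame
    clusters: list[tc.TagCluster]
    annotations: list[tc.ClusterAnnotation]
    shapes: pd.DataFrame        # one row per gene with a promoter cluster
    promoters: pd.DataFrame     # gene_id, sequence, shape_class, flags
    composition: pd.DataFrame | None = None
    dinucleotides: pd.Series | None = None
    profiles: pd.DataFrame | None = None
    occurrence: pd.DataFrame | None = None
    shuffled_profiles: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    cooccurrence2: pd.DataFrame | None = None
    cooccurrence3: pd.DataFrame | None = None
    tata_table: pd.DataFrame | None = None
    go_map: pd.DataFrame | None = None
    go_table: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def gene_promoters(sim: sd.SimGenome, reads: pd.DataFrame, min_tags: int = 100,
                   merge_gap: int = -1) -> tuple[list[tc.TagCluster], list[tc.ClusterAnnotation], pd.DataFrame, pd.DataFrame]:
    """Cluster reads and derive one core promoter per promoter-bearing gene."""
    scaffold_len = {name: len(seq) for name, seq in sim.scaffolds.items()}
    clusters = tc.filter_clusters(tc.merge_reads(reads, merge_gap), min_tags)
    annotations = tc.annotate_clusters(clusters, sim.genes, scaffold_len)

    by_gene: dict[str, list[tc.TagCluster]] = {}
    for ann in annotations:
        if ann.category == "five_prime":
            by_gene.setdefault(ann.gene_id, []).append(ann.cluster)

    shape_rows = []
    promoter_rows = []
    for gene_id in sorted(by_gene):
        cluster = ps.select_gene_cluster(by_gene[gene_id])
        shape = ps.peakedness(cluster)
        cls = ps.classify_shape(shape)
        tss = ps.dominant_tss(cluster)
        promoter = ps.extract_core_promoter(
            sim.scaffolds, cluster.scaffold, tss, cluster.strand, sim.transposons, gene_id
        )
        shape_rows.append(
            {
                "gene_id": gene_id,
                "scaffold": cluster.scaffold,
                "strand": cluster.strand,
                "dominant_tss": tss,
                "m": shape.m,
                "n": shape.n,
                "w": shape.w,
                "sg": shape.sg,
                "n_positions": shape.n_positions,
                "shape_class": cls,
            }
        )
        promoter_rows.append(
            {
                "gene_id": gene_id,
                "scaffold": cluster.scaffold,
                "strand": cluster.strand,
                "tss": tss,
                "sequence": promoter.sequence,
                "shape_class": cls,
                "transposon_overlap": promoter.transposon_overlap,
            }
        )
    shapes = pd.DataFrame(shape_rows)
    promoters = pd.DataFrame(promoter_rows)
    return clusters, annotations, shapes, promoters


def run_pipeline(config: sd.SimConfig, models: Sequence[ma.MotifModel] | None = None,
                 p_threshold: float = ma.DEFAULT_P_THRESHOLD, min_tags: int = 100,
                 with_statistics: bool = True) -> PipelineResult:
    """Run the whole analysis on one simulated study."""
    sim = sd.generate_genome(config)
    reads = sd.generate_tss_reads(sim.truth, config)
    clusters, annotations, shapes, promoters = gene_promoters(sim, reads, min_tags)
    result = PipelineResult(config, sim, reads, clusters, annotations, shapes, promoters)
    if promoters.empty:
        return result

    wide = [
        ps.extract_window(sim.scaffolds, r.scaffold, r.tss, r.strand, 200, 100)
        for r in promoters.itertuples()
    ]
    result.composition = nc.composition_profile(wide, upstream=200, downstream=100)
    result.dinucleotides = nc.initiator_dinucleotide(promoters["sequence"], upstream=50)

    if models is None:
        models = ma.default_motif_models()
    scannable = promoters[~promoters["transposon_overlap"]].reset_index(drop=True)
    result.extras["n_transposon_excluded"] = int(promoters["transposon_overlap"].sum())
    if scannable.empty:
        return result
    background = ma.background_model(scannable["sequence"])
    profiles, occurrence = ma.motif_profiles(scannable, models, background, p_threshold)
    result.profiles, result.occurrence = profiles, occurrence

    if not with_statistics:
        return result

    shuffled = scannable.copy()
    shuffled["sequence"] = es.shuffle_promoters(
        list(scannable["sequence"]), seed=config.seed + 101
    )
    shuffled_bg = ma.background_model(shuffled["sequence"])
    shuffled_profiles, _ = ma.motif_profiles(shuffled, models, shuffled_bg, p_threshold)
    result.shuffled_profiles = shuffled_profiles

    result.enrichment = es.enrichment_table(profiles, shuffled_profiles)
    result.cooccurrence2 = es.cooccurrence_frame(es.cooccurrence(profiles, 2))
    result.cooccurrence3 = es.cooccurrence_frame(es.cooccurrence(profiles, 3))
    result.tata_table = es.tata_partition_table(profiles)

    result.go_map = sd.generate_go_annotations(sim.truth, config)
    gene_classes = promoters[["gene_id", "shape_class"]]
    result.go_table = es.go_overrepresentation(result.go_map, gene_classes)
    return result
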