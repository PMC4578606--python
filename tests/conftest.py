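import numpy as np
import pandas as pd
import pytest

import promarch as pa
from promarch.io import BED6_COLUMNS


@pytest.fixture(scope="session")
def small_config():
    return pa.SimConfig(n_genes=30, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return pa.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_reads(small_sim, small_config):
    return pa.generate_tss_reads(small_sim.truth, small_config)


@pytest.fixture(scope="session")
def default_models():
    return pa.default_motif_models()


def make_reads(rows):
    """BED6 frame from (chrom, start, end, strand) tuples."""
    return pd.DataFrame(
        [(c, s, e, f"r{i}", 0, st) for i, (c, s, e, st) in enumerate(rows)],
        columns=BED6_COLUMNS,
    )


def random_reads(rng, n, n_scaffolds=2, span=500, read_len=30):
    rows = []
    for i in range(n):
        scaf = f"s{rng.integers(n_scaffolds)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, read_len))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((scaf, start, start + length, strand))
    return make_reads(rows)


def brute_force_clusters(reads):
    """Connected components of the pairwise same-scaffold/strand overlap graph.

    Independent oracle for merge_reads: builds the full overlap adjacency and
    takes graph components via scipy; returns a sorted list of
    (scaffold, strand, start, end, tag_count).
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(reads)
    if n == 0:
        return []
    chrom = reads["chrom"].to_numpy()
    strand = reads["strand"].to_numpy()
    start = reads["start"].to_numpy()
    end = reads["end"].to_numpy()
    same = (chrom[:, None] == chrom[None, :]) & (strand[:, None] == strand[None, :])
    overlap = (start[:, None] < end[None, :]) & (start[None, :] < end[:, None])
    adj = same & overlap
    ii, jj = np.nonzero(adj)
    graph = coo_matrix((np.ones_like(ii), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    out = []
    for lab in np.unique(labels):
        members = labels == lab
        out.append(
            (
                chrom[members][0],
                strand[members][0],
                int(start[members].min()),
                int(end[members].max()),
                int(members.sum()),
            )
        )
    return sorted(out)
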