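"""Shuffled-background motif enrichment, co-occurrence and GO statistics.

The motif annotation of the true promoter set is contrasted with the same
annotation run on shuffled promoters (per-sequence base permutations, which
preserve each promoter's nucleotide composition exactly).  Motif counts are
compared with an exact binomial test; two- and three-way motif combinations
are tested against their independence expectation with a 95% Wald interval;
GO terms are called over-represented per promoter class by a nearest-rank
75th-percentile rule on the term-count distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .motif_annotation import MOTIF_NAMES

Z_95 = 1.96


@dataclass
class EnrichmentResult:
    motif: str
    shape_class: str
    true_count: int
    random_count: int
    n_promoters: int
    p_value: float


@dataclass
class CooccurrenceResult:
    combination: tuple[str, ...]
    shape_class: str
    observed_percent: float
    expected_percent: float
    ci_low_percent: float
    ci_high_percent: float
    flag: str  # over / under / none


def shuffle_promoters(sequences: Sequence[str], seed: int) -> list[str]:
    """Independently permute the bases of each sequence (composition-preserving)."""
    rng = np.random.default_rng(seed)
    out = []
    for seq in sequences:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        rng.shuffle(arr)
        out.append(arr.tobytes().decode())
    return out


def binomial_enrichment(true_count: int, random_count: int, n: int,
                        motif: str = ".", shape_class: str = "all",
                        method: str = "conditional") -> EnrichmentResult:
    """One-sided exact binomial comparison of true vs shuffled motif counts.

    ``conditional`` (default): condition on the combined count and test
    whether the true set holds more than its half share —
    p = P(X >= true_count), X ~ Binomial(true+random, 1/2).  This paired
    comparison is calibrated under a null where both counts share one rate.

    ``estimated-null``: a one-sample binomial tail against the shuffled-set
    rate, p-hat = (random_count + 0.5)/(n + 1); anti-conservative when the
    null rate must be estimated, kept for comparison.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= true_count <= n and 0 <= random_count <= n):
        raise ValueError("counts must lie in [0, n]")
    if method == "conditional":
        total = true_count + random_count
        p = float(binom.sf(true_count - 1, total, 0.5)) if total else 1.0
    elif method == "estimated-null":
        p_hat = (random_count + 0.5) / (n + 1)
        p = float(binom.sf(true_count - 1, n, p_hat))
    else:
        raise ValueError(f"unknown method {method!r}")
    return EnrichmentResult(motif, shape_class, true_count, random_count, n, min(p, 1.0))


def enrichment_table(true_profiles: pd.DataFrame, random_profiles: pd.DataFrame,
                     motif_names: Sequence[str] = MOTIF_NAMES,
                     method: str = "conditional") -> pd.DataFrame:
    """Per-motif, per-shape-class enrichment of true vs shuffled promoters."""
    rows = []
    classes = ["all", *sorted(true_profiles["shape_class"].unique())]
    for cls in classes:
        t = true_profiles if cls == "all" else true_profiles[true_profiles["shape_class"] == cls]
        r = random_profiles if cls == "all" else random_profiles[random_profiles["shape_class"] == cls]
        if not len(t):
            continue
        for name in motif_names:
            res = binomial_enrichment(
                int(t[name].sum()), int(r[name].sum()), len(t), name, cls, method
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def wald_flag(observed_prop: float, expected_prop: float, n: int,
              z: float = Z_95) -> tuple[float, float, str]:
    """95% Wald band around an expected proportion and the over/under flag."""
    half = z * np.sqrt(expected_prop * (1.0 - expected_prop) / n)
    low, high = expected_prop - half, expected_prop + half
    if observed_prop > high:
        flag = "over"
    elif observed_prop < low:
        flag = "under"
    else:
        flag = "none"
    return low, high, flag


def cooccurrence(profiles: pd.DataFrame, k: int,
                 motif_names: Sequence[str] = MOTIF_NAMES) -> list[CooccurrenceResult]:
    """Observed vs independence-expected k-way motif co-occurrence per class.

    For each of the C(6,2)=15 pairs or C(6,3)=20 triples and each shape class,
    the observed joint frequency is compared with the product of the class
    marginals; flags mark exits from the 95% Wald band around the expectation.
    Classes with no promoters are omitted with a warning.
    """
    if k not in (2, 3):
        raise ValueError("co-occurrence order k must be 2 or 3")
    results: list[CooccurrenceResult] = []
    classes = ["all", *sorted(profiles["shape_class"].unique())]
    for cls in classes:
        sub = profiles if cls == "all" else profiles[profiles["shape_class"] == cls]
        n = len(sub)
        if n == 0:
            warnings.warn(f"shape class {cls!r} has no promoters; omitted", stacklevel=2)
            continue
        marginals = {name: sub[name].mean() for name in motif_names}
        for combo in itertools.combinations(motif_names, k):
            observed = float(sub[list(combo)].all(axis=1).mean())
            expected = float(np.prod([marginals[name] for name in combo]))
            low, high, flag = wald_flag(observed, expected, n)
            results.append(
                CooccurrenceResult(
                    combination=combo,
                    shape_class=cls,
                    observed_percent=100.0 * observed,
                    expected_percent=100.0 * expected,
                    ci_low_percent=100.0 * low,
                    ci_high_percent=100.0 * high,
                    flag=flag,
                )
            )
    return results


def cooccurrence_frame(results: list[CooccurrenceResult]) -> pd.DataFrame:
    rows = [
        {**r.__dict__, "combination": "+".join(r.combination)}
        for r in results
    ]
    return pd.DataFrame(rows)


def tata_partition_table(profiles: pd.DataFrame,
                         motif_names: Sequence[str] = MOTIF_NAMES) -> pd.DataFrame:
    """Per-motif occurrence (%) in TATA-containing vs TATA-less promoters."""
    if not len(profiles):
        raise ValueError("no promoter profiles")
    data = {}
    for status in ("TATA_containing", "TATA_less"):
        sub = profiles[profiles["tata_status"] == status]
        if not len(sub):
            warnings.warn(f"no promoters with status {status}", stacklevel=2)
            data[status] = {name: np.nan for name in motif_names}
        else:
            data[status] = {name: 100.0 * sub[name].mean() for name in motif_names}
    return pd.DataFrame(data)


def nearest_rank_percentile(values: Sequence[float], percentile: float = 75.0) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    ordered = sorted(values)
    if not ordered:
        raise ValueError("empty value set")
    rank = int(np.ceil(percentile / 100.0 * len(ordered)))
    return ordered[max(rank, 1) - 1]


def go_overrepresentation(go_map: pd.DataFrame, gene_classes: pd.DataFrame,
                          percentile: float = 75.0) -> pd.DataFrame:
    """GO terms over-represented per promoter class by the 75th-percentile rule.

    ``go_map`` has columns gene_id/go_term; ``gene_classes`` has columns
    gene_id/shape_class.  Within each class, term occurrences are counted and
    terms whose count reaches the nearest-rank percentile threshold of the
    class's count distribution are reported.  Classes without annotated genes
    are omitted with a warning.
    """
    merged = go_map.merge(gene_classes, on="gene_id", how="inner")
    rows = []
    for cls in sorted(gene_classes["shape_class"].unique()):
        sub = merged[merged["shape_class"] == cls]
        if not len(sub):
            warnings.warn(f"shape class {cls!r} has no GO-annotated genes; omitted", stacklevel=2)
            continue
        counts = sub["go_term"].value_counts()
        threshold = nearest_rank_percentile(counts.to_numpy(), percentile)
        for term, count in counts.items():
            rows.append(
                {
                    "shape_class": cls,
                    "go_term": term,
                    "count": int(count),
                    "threshold": threshold,
                    "over_represented": bool(count >= threshold),
                }
            )
    return pd.DataFrame(rows, columns=["shape_class", "go_term", "count", "threshold", "over_represented"])
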