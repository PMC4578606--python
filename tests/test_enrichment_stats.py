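"""Shuffled backgrounds, binomial enrichment, co-occurrence and GO statistics."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from promarch.enrichment_stats import (
    binomial_enrichment,
    cooccurrence,
    go_overrepresentation,
    nearest_rank_percentile,
    shuffle_promoters,
    tata_partition_table,
    wald_flag,
)
from promarch.motif_annotation import MOTIF_NAMES


def make_profiles(presence, classes=None):
    """Profiles frame from a dict motif -> boolean array."""
    n = len(next(iter(presence.values())))
    df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)]})
    for name in MOTIF_NAMES:
        df[name] = np.asarray(presence.get(name, np.zeros(n, dtype=bool)), dtype=bool)
    df["shape_class"] = classes if classes is not None else "broad_without_peak"
    df["tata_status"] = np.where(df["TATA"], "TATA_containing", "TATA_less")
    return df


class TestShufflePromoters:
    def test_base_multiset_preserved_per_sequence(self):
        seqs = ["AACGT", "TTTTA", "ACGTACGTAC"]
        for orig, shuf in zip(seqs, shuffle_promoters(seqs, seed=1)):
            assert Counter(orig) == Counter(shuf)

    def test_seed_determinism(self):
        seqs = ["ACGT" * 25] * 5
        assert shuffle_promoters(seqs, 7) == shuffle_promoters(seqs, 7)

    def test_shuffle_actually_permutes(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 100))
        differs = sum(shuffle_promoters([seq], seed)[0] != seq for seed in range(100))
        assert differs >= 99


class TestBinomialEnrichment:
    def test_estimated_null_example(self):
        res = binomial_enrichment(10, 5, 10, method="estimated-null")
        assert res.p_value == pytest.approx(0.5**10, rel=1e-9)

    def test_estimated_null_never_significant_at_its_own_mean(self):
        for n in (10, 100, 1000):
            res = binomial_enrichment(n // 2, n // 2, n, method="estimated-null")
            assert res.p_value >= 0.38

    @pytest.mark.parametrize("method", ["conditional", "estimated-null"])
    def test_zero_true_count_gives_p_one(self, method):
        assert binomial_enrichment(0, 5, 10, method=method).p_value == 1.0

    def test_conditional_tail_closed_form(self):
        # all 15 combined instances in the true set: p = 0.5^15
        res = binomial_enrichment(15, 0, 20)
        assert res.p_value == pytest.approx(0.5**15, rel=1e-9)

    def test_conditional_equal_counts_not_significant(self):
        assert binomial_enrichment(50, 50, 200).p_value > 0.4

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binomial_enrichment(1, 1, 0)
        with pytest.raises(ValueError):
            binomial_enrichment(11, 0, 10)
        with pytest.raises(ValueError):
            binomial_enrichment(1, 1, 10, method="bogus")


class TestCooccurrence:
    def test_pair_and_triple_combination_counts(self):
        rng = np.random.default_rng(0)
        profiles = make_profiles({m: rng.random(50) < 0.4 for m in MOTIF_NAMES})
        pairs = cooccurrence(profiles, 2)
        triples = cooccurrence(profiles, 3)
        per_class_pairs = [r for r in pairs if r.shape_class == "all"]
        per_class_triples = [r for r in triples if r.shape_class == "all"]
        assert len(per_class_pairs) == 15 and len(per_class_triples) == 20

    def test_perfect_correlation_flags_over(self):
        together = np.zeros(100, dtype=bool)
        together[:50] = True  # TATA and INR always co-occur, each marginal 0.5
        profiles = make_profiles({"TATA": together, "INR": together})
        res = [
            r for r in cooccurrence(profiles, 2)
            if r.shape_class == "all" and set(r.combination) == {"TATA", "INR"}
        ][0]
        assert res.observed_percent == pytest.approx(50.0)
        assert res.expected_percent == pytest.approx(25.0)
        assert res.flag == "over"

    def test_observed_bounded_by_min_marginal(self):
        rng = np.random.default_rng(1)
        profiles = make_profiles({m: rng.random(200) < rng.uniform(0.2, 0.8) for m in MOTIF_NAMES})
        marginals = {m: 100.0 * profiles[m].mean() for m in MOTIF_NAMES}
        for r in cooccurrence(profiles, 2) + cooccurrence(profiles, 3):
            if r.shape_class != "all":
                continue
            assert r.observed_percent <= min(marginals[m] for m in r.combination) + 1e-9

    def test_independent_motifs_mostly_unflagged(self):
        rng = np.random.default_rng(2)
        profiles = make_profiles({m: rng.random(500) < 0.4 for m in MOTIF_NAMES})
        results = [r for r in cooccurrence(profiles, 2) if r.shape_class == "all"]
        assert sum(r.flag == "none" for r in results) >= 0.9 * len(results)

    def test_empty_class_warns(self):
        profiles = make_profiles({m: np.ones(5, dtype=bool) for m in MOTIF_NAMES})
        empty = profiles.iloc[0:0]
        with pytest.warns(UserWarning):
            assert cooccurrence(empty, 2) == []

    def test_invalid_order_rejected(self):
        profiles = make_profiles({"TATA": np.ones(5, dtype=bool)})
        with pytest.raises(ValueError):
            cooccurrence(profiles, 4)


class TestWaldFlag:
    def test_flag_directions(self):
        low, high, flag = wald_flag(0.5, 0.25, 50)
        assert flag == "over" and low < 0.25 < high
        assert wald_flag(0.01, 0.25, 50)[2] == "under"
        assert wald_flag(0.26, 0.25, 50)[2] == "none"


class TestTataPartition:
    def test_tata_column_definitions(self):
        rng = np.random.default_rng(3)
        tata = rng.random(100) < 0.4
        profiles = make_profiles({"TATA": tata, "INR": rng.random(100) < 0.5})
        table = tata_partition_table(profiles)
        assert table.loc["TATA", "TATA_containing"] == 100.0
        assert table.loc["TATA", "TATA_less"] == 0.0

    def test_inr_planted_only_without_tata(self):
        tata = np.zeros(100, dtype=bool)
        tata[:40] = True
        inr = ~tata
        table = tata_partition_table(make_profiles({"TATA": tata, "INR": inr}))
        assert table.loc["INR", "TATA_less"] > table.loc["INR", "TATA_containing"]

    def test_all_tata_containing_warns(self):
        profiles = make_profiles({"TATA": np.ones(10, dtype=bool)})
        with pytest.warns(UserWarning):
            table = tata_partition_table(profiles)
        assert np.isnan(table.loc["INR", "TATA_less"])


class TestGoOverrepresentation:
    def _tables(self, counts, cls="narrow"):
        rows = []
        i = 0
        for term, k in counts.items():
            for _ in range(k):
                rows.append({"gene_id": f"g{i}", "go_term": term})
                i += 1
        go = pd.DataFrame(rows)
        classes = pd.DataFrame({"gene_id": go["gene_id"].unique()})
        classes["shape_class"] = cls
        return go, classes

    def test_nearest_rank_threshold_by_hand(self):
        # counts {A:10, B:4, C:2, D:1}: ceil(0.75*4)=3rd smallest = 4
        go, classes = self._tables({"A": 10, "B": 4, "C": 2, "D": 1})
        table = go_overrepresentation(go, classes)
        over = set(table[table["over_represented"]]["go_term"])
        assert over == {"A", "B"}
        assert (table["threshold"] == 4).all()

    def test_single_term_is_over_represented(self):
        go, classes = self._tables({"A": 3})
        table = go_overrepresentation(go, classes)
        assert table["over_represented"].all()

    def test_degenerate_equal_counts_all_reported(self):
        go, classes = self._tables({"A": 2, "B": 2, "C": 2})
        table = go_overrepresentation(go, classes)
        assert table["over_represented"].all()

    def test_unannotated_class_omitted_with_warning(self):
        go, classes = self._tables({"A": 5})
        classes = pd.concat(
            [classes, pd.DataFrame({"gene_id": ["zz"], "shape_class": ["broad_with_peak"]})]
        )
        with pytest.warns(UserWarning):
            table = go_overrepresentation(go, classes)
        assert set(table["shape_class"]) == {"narrow"}

    def test_nearest_rank_percentile_basics(self):
        assert nearest_rank_percentile([1, 2, 4, 10]) == 4
        assert nearest_rank_percentile([5]) == 5
        with pytest.raises(ValueError):
            nearest_rank_percentile([])
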