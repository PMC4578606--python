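"""JASPAR parsing, background estimation, exact PWM p-values and window scans."""

import itertools

import numpy as np
import pandas as pd
import pytest

from promarch.motif_annotation import (
    DEFAULT_WINDOWS,
    MOTIF_CONSENSUS,
    MOTIF_NAMES,
    MotifModel,
    PSEUDOCOUNT,
    ScoreDistribution,
    background_model,
    default_motif_models,
    motif_profiles,
    pfm_from_consensus,
    read_jaspar,
    scan_promoter,
    tss_relative_position,
    write_jaspar,
)

UNIFORM = np.full(4, 0.25)


def encode(word):
    return np.array([["ACGT".index(c) for c in word]])


class TestJasparIO:
    def test_parse_toy_matrix(self, tmp_path):
        p = tmp_path / "toy.pfm"
        p.write_text(
            ">TATA\ttoy\n"
            "A  [ 10 80 10 80 80 80 ]\n"
            "C  [ 30  5 30  5  5  5 ]\n"
            "G  [ 30  5 30  5  5  5 ]\n"
            "T  [ 27  7 27  7  7  7 ]\n"
        )
        (model,) = read_jaspar(p)
        assert model.length == 6
        assert np.allclose(model.pfm.sum(axis=0), 97)
        assert model.window == DEFAULT_WINDOWS["TATA"]

    def test_empty_file_warns_and_returns_nothing(self, tmp_path):
        p = tmp_path / "empty.pfm"
        p.write_text("")
        with pytest.warns(UserWarning):
            assert read_jaspar(p) == []

    def test_round_trip_identity(self, tmp_path):
        models = default_motif_models()
        p = tmp_path / "all.pfm"
        write_jaspar(models, p)
        back = read_jaspar(p)
        assert [m.name for m in back] == [m.name for m in models]
        for a, b in zip(models, back):
            assert np.array_equal(a.pfm, b.pfm)

    def test_unknown_motif_needs_a_window(self, tmp_path):
        p = tmp_path / "x.pfm"
        p.write_text(">XX\txx\nA [ 1 ]\nC [ 1 ]\nG [ 1 ]\nT [ 1 ]\n")
        with pytest.raises(KeyError):
            read_jaspar(p)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("bad", np.array([[1.0, -1.0]] * 4), (-10, 10))
        with pytest.raises(ValueError):
            MotifModel("bad", np.zeros((4, 3)), (-10, 10))


class TestBackgroundModel:
    def test_all_a_is_floored_and_renormalized(self):
        bg = background_model(["AAAA" * 10])
        assert bg.sum() == pytest.approx(1.0)
        assert bg[0] == pytest.approx(1.0, abs=1e-3)
        assert (bg[1:] > 0).all()

    def test_at_only_input(self):
        bg = background_model(["AT" * 50, "TA" * 50])
        assert bg[0] == pytest.approx(0.5, abs=1e-3) and bg[3] == pytest.approx(0.5, abs=1e-3)
        assert bg[1] < 1e-3 and bg[2] < 1e-3

    def test_uniform_random_sequences(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 1000)) for _ in range(40)]
        assert np.allclose(background_model(seqs), 0.25, atol=0.01)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            background_model(["NNNN"])


class TestScoreDistribution:
    @pytest.mark.parametrize("seed,length", [(0, 4), (1, 5), (2, 6)])
    def test_dp_matches_brute_force_enumeration(self, seed, length):
        rng = np.random.default_rng(seed)
        bg = rng.dirichlet(np.ones(4) * 3)
        bg = np.maximum(bg, 1e-4)
        bg = bg / bg.sum()
        pfm = rng.integers(0, 40, size=(4, length)).astype(float) + 1
        dist = ScoreDistribution(MotifModel("X", pfm, (-20, 20)), bg)
        words = np.array(list(itertools.product(range(4), repeat=length)))
        scores = dist.lattice[words, np.arange(length)].sum(axis=1)
        probs = bg[words].prod(axis=1)
        for s in np.unique(scores):
            assert abs(probs[scores >= s].sum() - float(dist.p_value(s))) <= 1e-6

    def test_p_value_monotone_in_score(self):
        dist = ScoreDistribution(default_motif_models()[0], UNIFORM)
        scores = np.arange(dist.offset, dist.offset + len(dist.sf), 50)
        pvals = dist.p_value(scores)
        assert (np.diff(pvals) <= 1e-15).all()

    def test_consensus_score_closed_form_under_uniform(self):
        model = MotifModel("TATA", pfm_from_consensus(MOTIF_CONSENSUS["TATA"]), (-31, -24))
        expected = np.log2(model.ppm(PSEUDOCOUNT).max(axis=0) / 0.25).sum()
        dist = ScoreDistribution(model, UNIFORM)
        observed = dist.lattice_scores(encode(MOTIF_CONSENSUS["TATA"]))[0] * dist.step
        # agreement up to half a lattice step per column
        assert observed == pytest.approx(expected, abs=model.length * dist.step / 2)


class TestScanPromoter:
    @pytest.fixture
    def at_background(self):
        return np.array([0.325, 0.175, 0.175, 0.325])

    def _promoter_with(self, name, rng, start=None):
        """AT-rich 100-mer with a consensus written at its functional window."""
        seq = list(rng.choice(list("AT"), 100))
        consensus = MOTIF_CONSENSUS[name]
        window = DEFAULT_WINDOWS[name]
        rel = window[0] if start is None else start
        idx = rel + 50 if rel < 0 else rel + 49
        seq[idx : idx + len(consensus)] = consensus
        return "".join(seq)

    def test_planted_tata_is_found(self, at_background):
        rng = np.random.default_rng(0)
        model = [m for m in default_motif_models() if m.name == "TATA"][0]
        seq = self._promoter_with("TATA", rng)
        hits = scan_promoter(seq, model, at_background)
        assert any(h.start == DEFAULT_WINDOWS["TATA"][0] for h in hits)
        assert all(h.p_value <= 1e-2 for h in hits)

    def test_consensus_beyond_elastic_window_is_discarded(self, at_background):
        rng = np.random.default_rng(1)
        model = [m for m in default_motif_models() if m.name == "DPE"][0]
        start = DEFAULT_WINDOWS["DPE"][1] + model.elasticity + 6
        seq = self._promoter_with("DPE", rng, start=start)
        windowed = scan_promoter(seq, model, at_background)
        free = scan_promoter(seq, model, at_background, apply_window=False)
        assert not any(h.start == start for h in windowed)
        assert any(h.start == start for h in free)

    def test_window_filter_is_a_pure_restriction(self, at_background):
        rng = np.random.default_rng(2)
        model = default_motif_models()[3]  # INR
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 100))
            windowed = scan_promoter(seq, model, at_background)
            free = scan_promoter(seq, model, at_background, apply_window=False)
            assert {(h.start, h.p_value) for h in windowed} <= {(h.start, h.p_value) for h in free}

    def test_ambiguous_promoter_is_skipped(self, at_background):
        model = default_motif_models()[0]
        with pytest.warns(UserWarning):
            assert scan_promoter("N" * 100, model, at_background) == []

    def test_short_promoter_yields_no_hits(self, at_background):
        model = default_motif_models()[0]
        with pytest.warns(UserWarning):
            assert scan_promoter("ACG", model, at_background) == []

    def test_tss_relative_positions_skip_zero(self):
        assert tss_relative_position(49) == -1
        assert tss_relative_position(50) == 1
        assert tss_relative_position(0) == -50
        assert tss_relative_position(99) == 50


class TestMotifProfiles:
    def test_tata_only_promoter(self):
        rng = np.random.default_rng(4)
        scan = TestScanPromoter()
        seq = scan._promoter_with("TATA", rng)
        promoters = pd.DataFrame(
            [{"gene_id": "g1", "sequence": seq, "shape_class": "narrow"}]
        )
        bg = np.array([0.325, 0.175, 0.175, 0.325])
        profiles, table = motif_profiles(promoters, default_motif_models(), bg)
        row = profiles.iloc[0]
        assert row["TATA"] and row["tata_status"] == "TATA_containing"
        gc_rich = [m for m in ("BREu", "MTE", "DPE") if row[m]]
        assert not gc_rich  # GC-heavy motifs cannot appear in an AT-only background
        assert table.loc["TATA", "narrow"] == 100.0

    def test_empty_promoter_set(self):
        promoters = pd.DataFrame(columns=["gene_id", "sequence", "shape_class"])
        profiles, table = motif_profiles(promoters, default_motif_models(), UNIFORM)
        assert profiles.empty
        assert table.loc["n_promoters"].eq(0).all() or table.empty

    def test_motif_names_cover_the_six_canonical_elements(self):
        assert set(MOTIF_NAMES) == {"BREu", "BREd", "TATA", "INR", "MTE", "DPE"}
        for m in default_motif_models():
            lo, hi = m.window
            assert -50 <= lo < hi <= 50
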