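"""Motif parsing, log-odds scoring, exact score p-values, similarity, UPGMA."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifassoc.motifs import (
    DEFAULT_GRANULARITY,
    MotifMatrix,
    MotifParseError,
    best_site_score,
    make_scoring_matrix,
    motif_similarity,
    parse_meme_minimal,
    parse_motifs,
    parse_tabular_pfm,
    reverse_complement,
    score_distribution,
    similarity_matrix,
    upgma_cluster,
    write_meme_minimal,
    write_tabular_pfm,
)

from conftest import random_dna


# ---------------------------------------------------------------------------
# parsing


class TestParsing:
    def test_identity_parse_consensus(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(">m1\n1 0 0 0\n0 1 0 0\n0 0 0 1\n")
        (m,) = parse_motifs(p, "tabular_pfm")
        assert m.consensus() == "ACT"

    @pytest.mark.parametrize("fmt,writer,parser", [
        ("meme_minimal", write_meme_minimal, parse_meme_minimal),
        ("tabular_pfm", write_tabular_pfm, parse_tabular_pfm),
    ])
    def test_round_trip(self, tmp_path, toy_motif, fmt, writer, parser):
        other = MotifMatrix("second", np.array([[3, 3, 2, 2], [1, 1, 1, 7.0]]),
                            gene_label="GeneX")
        path = tmp_path / f"rt.{fmt}"
        writer([toy_motif, other], path)
        back = parser(path)
        assert [m.id for m in back] == ["toy6", "second"]
        assert back[1].gene_label == "GeneX"
        for orig, rt in zip([toy_motif, other], back):
            np.testing.assert_allclose(rt.probabilities, orig.probabilities,
                                       atol=1e-5)

    def test_zero_row_rejected(self, tmp_path):
        p = tmp_path / "bad.pfm"
        p.write_text(">m1\n1 0 0 0\n0 0 0 0\n")
        with pytest.raises(MotifParseError, match="summing to 0"):
            parse_tabular_pfm(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.pfm"
        p.write_text(">m1\n1 0 0 0\n>m1\n0 1 0 0\n")
        with pytest.raises(MotifParseError, match="duplicate"):
            parse_tabular_pfm(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.pfm"
        p.write_text(">m1\n1 0 0\n")
        with pytest.raises(MotifParseError, match="line 2"):
            parse_tabular_pfm(p)


# ---------------------------------------------------------------------------
# log-odds construction


class TestScoringMatrix:
    def test_uniform_position_scores_zero(self):
        m = MotifMatrix("u", np.array([[0.25, 0.25, 0.25, 0.25]]))
        sm = make_scoring_matrix(m, pseudocount=0.0)
        np.testing.assert_allclose(sm.scores, 0.0, atol=1e-12)

    def test_pure_position_two_bits(self):
        m = MotifMatrix("a", np.array([[1.0, 0, 0, 0]]))
        with pytest.warns(RuntimeWarning):
            sm = make_scoring_matrix(m, pseudocount=0.0)
        assert sm.scores[0, 0] == pytest.approx(2.0)
        assert np.isneginf(sm.scores[0, 1])

    def test_pseudocount_formula_by_hand(self):
        # position (8,2,0,0), uniform background, pseudocount 0.4:
        # each base adds 0.4*0.25 = 0.1; denominator 10.4; then /0.25
        m = MotifMatrix("h", np.array([[8.0, 2, 0, 0]]))
        sm = make_scoring_matrix(m, pseudocount=0.4)
        expected = np.log2(np.array([8.1, 2.1, 0.1, 0.1]) / 10.4 / 0.25)
        np.testing.assert_allclose(sm.scores[0], expected, rtol=1e-12)

    def test_background_must_be_valid(self, toy_motif):
        with pytest.raises(ValueError):
            make_scoring_matrix(toy_motif, background=np.array([0.5, 0.5, 0.2, 0.2]))


# ---------------------------------------------------------------------------
# best site scoring


class TestBestSiteScore:
    def test_consensus_hits_max_score(self, toy_sm, toy_motif):
        score, offset, strand = best_site_score(toy_sm, toy_motif.consensus())
        assert score == pytest.approx(toy_sm.max_score)
        assert (offset, strand) == (0, "+")

    def test_reverse_complement_strand_symmetry(self, toy_sm, rng):
        seq = random_dna(80, rng)
        s_fwd = best_site_score(toy_sm, seq)
        s_rev = best_site_score(toy_sm, reverse_complement(seq))
        assert s_fwd[0] == pytest.approx(s_rev[0])

    def test_minus_strand_reported(self, toy_sm, toy_motif):
        seq = "GG" + reverse_complement(toy_motif.consensus()) + "GG"
        score, offset, strand = best_site_score(toy_sm, seq)
        assert score == pytest.approx(toy_sm.max_score)
        assert strand == "-"

    def test_short_sequence_gives_sentinel(self, toy_sm):
        score, offset, _ = best_site_score(toy_sm, "ACG")
        assert score == pytest.approx(toy_sm.min_score - DEFAULT_GRANULARITY)
        assert offset == -1

    def test_n_windows_skipped(self, toy_sm):
        # only the last 6-mer is N-free
        seq = "NNNNNNACGTAT"
        score, offset, strand = best_site_score(toy_sm, seq, both_strands=False)
        assert offset == 6

    def test_empty_sequence_warns(self, toy_sm):
        with pytest.warns(UserWarning, match="empty"):
            score, _, _ = best_site_score(toy_sm, "")
        assert score == toy_sm.sentinel_score

    def test_softmask_respected_only_when_asked(self, toy_sm, toy_motif):
        seq = toy_motif.consensus().lower() + "ACGTAT"
        hard = best_site_score(toy_sm, seq, respect_softmask=True)
        soft = best_site_score(toy_sm, seq, respect_softmask=False)
        assert soft[0] == pytest.approx(toy_sm.max_score)
        assert hard[0] < soft[0]


# ---------------------------------------------------------------------------
# exact score distribution vs exhaustive enumeration


class TestScoreDistribution:
    @staticmethod
    def brute_force_tail(sm, granularity, threshold):
        """P(discretized score >= threshold) over all 4^L words.

        Uses the same per-position score discretization as the DP, so the
        two computations must agree to float accumulation error.
        """
        bins = np.rint(sm.scores / granularity).astype(np.int64)
        tbin = int(np.rint(threshold / granularity))
        total = 0.0
        for word in itertools.product(range(4), repeat=sm.length):
            if sum(bins[i, b] for i, b in enumerate(word)) >= tbin:
                total += float(np.prod([sm.background[b] for b in word]))
        return total

    @pytest.mark.parametrize("length", [2, 4, 6])
    def test_matches_enumeration(self, length, rng):
        counts = rng.integers(1, 20, size=(length, 4)).astype(float)
        sm = make_scoring_matrix(MotifMatrix("e", counts), pseudocount=0.1)
        dist = score_distribution(sm)
        probes = np.linspace(sm.min_score, sm.max_score, 11)
        for thr in probes:
            assert dist.pvalue_of_score(thr) == pytest.approx(
                self.brute_force_tail(sm, dist.granularity, thr), abs=1e-9
            )

    def test_tail_one_at_min_score(self, toy_sm):
        dist = score_distribution(toy_sm)
        assert dist.pvalue_of_score(toy_sm.min_score) == pytest.approx(1.0)
        assert dist.tail[0] == pytest.approx(1.0)

    def test_tail_monotone_in_unit_interval(self, toy_sm):
        dist = score_distribution(toy_sm)
        assert np.all(np.diff(dist.tail) <= 1e-15)
        assert np.all((dist.tail >= 0) & (dist.tail <= 1))

    def test_single_position_quarter(self):
        m = MotifMatrix("s", np.array([[1.0, 0, 0, 0]]))
        with pytest.warns(RuntimeWarning):
            sm = make_scoring_matrix(m, pseudocount=0.0)
        dist = score_distribution(sm)
        assert dist.pvalue_of_score(sm.max_score) == pytest.approx(0.25)

    def test_threshold_inversion_consistent(self, toy_sm):
        dist = score_distribution(toy_sm)
        for p in (1e-2, 1e-3):
            s = dist.score_at_pvalue(p)
            assert dist.pvalue_of_score(s) <= p
            assert dist.pvalue_of_score(s - dist.granularity) > p

    def test_pvalue_near_1e5_stable_to_granularity(self, toy_sm):
        # the default bin width must not distort small tail probabilities
        coarse = score_distribution(toy_sm)
        fine = score_distribution(toy_sm, granularity=DEFAULT_GRANULARITY / 10)
        s = fine.score_at_pvalue(1e-4)
        p_c, p_f = coarse.pvalue_of_score(s), fine.pvalue_of_score(s)
        assert abs(p_c - p_f) / p_f < 0.05


# ---------------------------------------------------------------------------
# similarity and clustering


class TestSimilarity:
    def test_self_similarity_is_one(self, toy_motif):
        assert motif_similarity(toy_motif, toy_motif) == pytest.approx(1.0)

    def test_reverse_complement_similarity_is_one(self, toy_motif):
        rc = toy_motif.reverse_complement()
        assert motif_similarity(toy_motif, rc) == pytest.approx(1.0)

    def test_symmetry(self, toy_motif, rng):
        b = MotifMatrix("b", rng.integers(1, 9, size=(5, 4)).astype(float))
        assert motif_similarity(toy_motif, b) == pytest.approx(
            motif_similarity(b, toy_motif), abs=1e-12
        )

    def test_hand_computed_pcc_at_best_offset(self):
        # two 4-column motifs aligned without shift: the only offset with
        # overlap >= 4 is full overlap (plus orientations)
        a = MotifMatrix("a", np.array(
            [[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1],
             [0.1, 0.1, 0.7, 0.1], [0.1, 0.1, 0.1, 0.7]]))
        b = MotifMatrix("b", np.array(
            [[0.4, 0.2, 0.2, 0.2], [0.2, 0.4, 0.2, 0.2],
             [0.2, 0.2, 0.4, 0.2], [0.2, 0.2, 0.2, 0.4]]))

        def pcc(x, y):
            x, y = np.ravel(x), np.ravel(y)
            xc, yc = x - x.mean(), y - y.mean()
            return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))

        expected = max(
            pcc(a.probabilities, b.probabilities),
            pcc(a.probabilities, b.reverse_complement().probabilities),
        )
        assert motif_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_min_overlap_enforced(self):
        a = MotifMatrix("a", np.array([[1.0, 0, 0, 0]] * 3))
        with pytest.raises(ValueError, match="overlap"):
            motif_similarity(a, a)


class TestUpgma:
    def test_two_leaves_join_at_half_distance(self):
        root = upgma_cluster(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
        assert root.height == pytest.approx(1.5)
        assert root.to_newick() == "(a:1.5,b:1.5):0;"

    def test_three_leaf_hand_trace(self):
        # d(AB)=2, d(AC)=d(BC)=8: A,B join at height 1; (AB),C at height 4
        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        root = upgma_cluster(d, ["A", "B", "C"])
        assert root.height == pytest.approx(4.0)
        inner = [c for c in root.children if c.children][0]
        assert inner.height == pytest.approx(1.0)
        assert {c.label for c in inner.children} == {"A", "B"}

    def test_identical_rows_join_at_zero(self):
        d = np.zeros((4, 4))
        root = upgma_cluster(d)
        assert root.height == pytest.approx(0.0)

    def test_heights_non_decreasing_toward_root(self, rng):
        x = rng.random((8, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        root = upgma_cluster(d)

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(root)

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="NaN"):
            upgma_cluster(d)

    def test_similarity_matrix_to_tree(self, toy_motif, rng):
        motifs = [toy_motif] + [
            MotifMatrix(f"r{i}", rng.integers(1, 9, size=(6, 4)).astype(float))
            for i in range(3)
        ]
        sim = similarity_matrix(motifs)
        tree = upgma_cluster(1 - sim, [m.id for m in motifs])
        nwk = tree.to_newick()
        assert all(m.id in nwk for m in motifs)


# ---------------------------------------------------------------------------
# properties


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=10, max_size=60), st.integers(0, 10**6))
def test_best_site_revcomp_invariance_property(seq, seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 9, size=(4, 4)).astype(float)
    sm = make_scoring_matrix(MotifMatrix("p", counts))
    assert best_site_score(sm, seq)[0] == pytest.approx(
        best_site_score(sm, reverse_complement(seq))[0]
    )
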