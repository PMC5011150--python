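import itertools

import numpy as np
import pytest
from Bio import Align

from globinscan.alignment import (
    ScoringParams,
    alignment_stats,
    internal_duplications,
    lalign_params,
    simple_matrix,
    sw_align,
    sweep_parameters,
    waterman_eggert,
)

TOY = simple_matrix("TOY54", "ABCD", match=5, mismatch=-4)
TOY_PARAMS = ScoringParams(TOY, gap_open=4.0, gap_extend=1.0)


def biopython_local_score(a, b, params):
    """Independent optimal-local-score oracle (Biopython PairwiseAligner).

    Biopython charges open+extend for the first gap residue when
    open_gap_score = -(open+extend) and extend_gap_score = -extend,
    matching our convention that a length-L gap costs open + L*extend.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    mat = params.matrix
    alphabet = sorted(mat)
    from Bio.Align import substitution_matrices

    arr = substitution_matrices.Array(alphabet="".join(alphabet), dims=2)
    for x in alphabet:
        for y in alphabet:
            arr[x, y] = mat[x][y]
    aligner.substitution_matrix = arr
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return max(aligner.score(a, b), 0.0)


class TestSwAlign:
    def test_self_alignment_is_gapless_and_fully_identical(self):
        r = sw_align("ACDE", "ACDE", lalign_params())
        assert r.aligned_a == r.aligned_b == "ACDE"
        assert r.pct_identity == 100.0
        mat = lalign_params().matrix
        assert r.score == sum(mat[c][c] for c in "ACDE")

    def test_no_positive_pair_gives_empty_alignment(self):
        nomatch = simple_matrix("NOMATCH", "PG", match=-1, mismatch=-2)
        r = sw_align("PPPP", "GGGG", ScoringParams(nomatch, 4, 1))
        assert r.is_empty and r.score == 0.0
        assert (r.start_a, r.end_a, r.start_b, r.end_b) == (0, 0, 0, 0)

    def test_unknown_residue_is_named_in_error(self):
        with pytest.raises(KeyError, match="'Z'"):
            sw_align("ABZ", "AB", TOY_PARAMS)

    def test_score_matches_exhaustive_oracle_on_short_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            a = "".join(rng.choice(list("ABCD"), size=int(rng.integers(1, 8))))
            b = "".join(rng.choice(list("ABCD"), size=int(rng.integers(1, 8))))
            got = sw_align(a, b, TOY_PARAMS)
            assert got.score == biopython_local_score(a, b, TOY_PARAMS)
            if not got.is_empty:
                assert got.rescore(TOY_PARAMS) == got.score

    def test_score_matches_oracle_on_protein_pairs(self, globins):
        params = lalign_params()
        for a, b in itertools.combinations(sorted(globins), 2):
            got = sw_align(globins[a], globins[b], params)
            assert got.score == biopython_local_score(
                globins[a].residues, globins[b].residues, params
            )

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = "".join(rng.choice(list("ABCD"), size=int(rng.integers(1, 15))))
            b = "".join(rng.choice(list("ABCD"), size=int(rng.integers(1, 15))))
            assert (
                sw_align(a, b, TOY_PARAMS).score
                == sw_align(b, a, TOY_PARAMS).score
            )

    def test_monotone_in_sequence_extension(self):
        rng = np.random.default_rng(13)
        a = "".join(rng.choice(list("ABCD"), size=12))
        b = "".join(rng.choice(list("ABCD"), size=12))
        base = sw_align(a, b, TOY_PARAMS).score
        for extra in ("A", "BC", "DAB"):
            assert sw_align(a + extra, b, TOY_PARAMS).score >= base
            assert sw_align(a, b + extra, TOY_PARAMS).score >= base

    def test_alignment_strings_reconstruct_slices(self, globins):
        r = sw_align(globins["CYGB"], globins["MB"], lalign_params())
        assert r.aligned_a.replace("-", "") == globins["CYGB"].slice(
            r.start_a, r.end_a
        )
        assert r.aligned_b.replace("-", "") == globins["MB"].slice(
            r.start_b, r.end_b
        )
        assert all(
            not (x == "-" and y == "-")
            for x, y in zip(r.aligned_a, r.aligned_b)
        )
        assert 0.0 <= r.pct_identity <= r.pct_similar <= 100.0
        assert r.rescore(lalign_params()) == r.score


class TestWatermanEggert:
    def test_k1_equals_optimal(self):
        a, b = "ABAB", "AB"
        (only,) = waterman_eggert(a, b, TOY_PARAMS, k=1)
        assert only.score == sw_align(a, b, TOY_PARAMS).score

    def test_two_copies_found_disjointly(self):
        rs = waterman_eggert("ABAB", "AB", TOY_PARAMS, k=3)
        assert len(rs) == 2
        assert rs[0].score == rs[1].score == 10.0
        assert {rs[0].start_a, rs[1].start_a} == {1, 3}
        assert not (rs[0].aligned_pairs & rs[1].aligned_pairs)

    def test_non_intersecting_and_non_increasing(self, globins):
        rs = waterman_eggert(
            globins["HBA"], globins["HBB"], lalign_params(), k=4
        )
        for r1, r2 in itertools.combinations(rs, 2):
            assert not (r1.aligned_pairs & r2.aligned_pairs)
        assert all(x.score >= y.score for x, y in zip(rs, rs[1:]))

    def test_list_shorter_than_k_when_nothing_remains(self):
        rs = waterman_eggert("A", "A", TOY_PARAMS, k=5)
        assert len(rs) == 1  # the single cell is used up after one pass


class TestStats:
    def test_identical_pair(self):
        pid, psim, n = alignment_stats(
            "ACDEFGHIKL", "ACDEFGHIKL", lalign_params()
        )
        assert (pid, psim, n) == (100.0, 100.0, 10)

    def test_one_conservative_substitution(self):
        # I->L scores positively under BLOSUM50
        pid, psim, n = alignment_stats(
            "ACDEFGHIKL", "ACDEFGHLKL", lalign_params()
        )
        assert n == 10
        assert pid == 90.0
        assert psim == 100.0

    def test_gap_columns_count_as_neither(self):
        pid, psim, n = alignment_stats("AB-B", "ABBB", TOY_PARAMS)
        assert n == 4
        assert pid == pytest.approx(75.0)
        assert psim == pytest.approx(75.0)


class TestPublishedAlignments:
    """The published pairwise statistics, reproduced at the calibrated
    setting (BLOSUM50, open 12, extend 2 — the lalign36 defaults)."""

    @pytest.mark.parametrize(
        "pa,pb,score,pid,psim,overlap,coords",
        [
            ("CYGB", "MB", 251, 29.4, 63.4, 153, (19, 171, 3, 152)),
            ("CYGB", "HBA", 227, 28.9, 63.1, 149, (19, 167, 3, 142)),
            ("MB", "HBB", 161, 25.5, 58.6, 145, (3, 147, 4, 146)),
        ],
    )
    def test_cross_pairs(self, globins, pa, pb, score, pid, psim, overlap, coords):
        r = sw_align(globins[pa], globins[pb], lalign_params())
        assert r.score == score
        assert round(r.pct_identity, 1) == pid
        assert round(r.pct_similar, 1) == psim
        assert r.overlap_length == overlap
        assert (r.start_a, r.end_a, r.start_b, r.end_b) == coords

    def test_myoglobin_internal_duplication(self, globins):
        (dup, *_) = internal_duplications(globins["MB"], k=1)
        assert dup.score == 41
        assert round(dup.pct_identity, 1) == 39.3
        assert round(dup.pct_similar, 1) == 46.4
        assert dup.overlap_length == 28
        assert (dup.start_a, dup.end_a, dup.start_b, dup.end_b) == (
            17, 39, 57, 84,
        )


def test_sweep_grid_covers_both_matrix_families(globins):
    results = sweep_parameters("ACDEFG", "ACDEFG")
    names = {p.matrix_name for p, _ in results}
    assert names == {"BLOSUM50", "BLOSUM62"}
    assert len(results) == 24
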