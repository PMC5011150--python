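import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from globinscan.motifs import (
    BUILTIN_PATTERNS,
    MotifMatch,
    cholesterol_sites,
    collapse_to_domains,
    count_domains,
    enumerate_matches,
    scan_caveolin,
    scan_cholesterol,
)
from globinscan.seq_io import SequenceRecord

from conftest import brute_force_caveolin, brute_force_cholesterol


def crac_carc_triples(seq, kind):
    return sorted(
        (m.start, m.central, m.end)
        for m in enumerate_matches(seq, BUILTIN_PATTERNS[kind])
    )


class TestEnumerate:
    def test_consensus_example_has_exactly_one_crac(self):
        # the canonical CRAC illustration: V-TK-Y-WFY-R
        assert crac_carc_triples("VTKYWFYR", "CRAC") == [(1, 4, 8)]

    def test_anchor_free_background_matches_nothing(self):
        for cls in BUILTIN_PATTERNS:
            assert enumerate_matches("A" * 30, BUILTIN_PATTERNS[cls]) == []

    def test_x_satisfies_spacers_but_never_anchors(self):
        # X in spacer positions is fine...
        assert crac_carc_triples("VXYXK", "CRAC") == [(1, 3, 5)]
        # ...but an X where the central Y must sit is not a match
        assert crac_carc_triples("VXXXK", "CRAC") == []

    def test_overlapping_matches_all_reported(self):
        # two L/V starts share one central Y and one terminal R
        triples = crac_carc_triples("LVAYAR", "CRAC")
        assert triples == [(1, 4, 6), (2, 4, 6)]

    @pytest.mark.parametrize("kind", ["CRAC", "CARC"])
    @pytest.mark.parametrize(
        "profile",
        [
            "uniform",
            "anchor_rich",
            "anchor_poor",
        ],
    )
    def test_matches_equal_brute_force(self, kind, profile):
        rng = np.random.default_rng(hash((kind, profile)) % 2**32)
        alphabets = {
            "uniform": "ACDEFGHIKLMNPQRSTVWY",
            "anchor_rich": "LVYFKRAG",
            "anchor_poor": "ACDEGLYK",
        }
        alpha = alphabets[profile]
        for _ in range(20):
            n = int(rng.integers(20, 400))
            seq = "".join(rng.choice(list(alpha), size=n))
            assert crac_carc_triples(seq, kind) == brute_force_cholesterol(
                seq, kind
            )

    @pytest.mark.parametrize("kind", ["CAV_8A", "CAV_8B", "CAV_11"])
    def test_caveolin_matches_equal_brute_force(self, kind):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(12, 300))
            seq = "".join(rng.choice(list("WYFACDEG"), size=n))
            got = [
                (m.start, m.end)
                for m in enumerate_matches(seq, BUILTIN_PATTERNS[kind])
            ]
            assert got == brute_force_caveolin(seq, kind)

    def test_matched_text_is_the_sequence_slice(self):
        seq = SequenceRecord(id="s", residues="AAVTKYWFYRAA")
        (m,) = enumerate_matches(seq, BUILTIN_PATTERNS["CRAC"])
        assert m.matched_text == seq.slice(m.start, m.end)
        assert 5 <= m.length <= 13
        assert m.start < m.central < m.end


@settings(max_examples=150, derandomize=True)
@given(st.text(alphabet="LVYFKRAG", min_size=5, max_size=60))
def test_mirror_property(seq):
    """A CRAC in s is exactly a central-Y CARC in reversed s, at the
    mirrored coordinates (central-F CARCs have no CRAC mirror)."""
    n = len(seq)
    crac = crac_carc_triples(seq, "CRAC")
    carc_rev = [
        (n - j + 1, n - c + 1, n - i + 1)
        for i, c, j in crac_carc_triples(seq[::-1], "CARC")
        if seq[::-1][c - 1] == "Y"
    ]
    assert sorted(crac) == sorted(carc_rev)


class TestCollapse:
    def test_transitive_merge_within_class(self):
        ms = [
            MotifMatch(10, 18, 14, "CRAC", "X" * 9),
            MotifMatch(12, 20, 16, "CRAC", "X" * 9),
        ]
        (d,) = collapse_to_domains(ms)
        assert (d.start, d.end) == (10, 20)
        assert len(d.support) == 2

    def test_cross_class_never_merges(self):
        ms = [
            MotifMatch(121, 127, 123, "CARC", "KEFTPPV"),
            MotifMatch(127, 133, 131, "CRAC", "VQAAYQK"),
        ]
        doms = collapse_to_domains(ms)
        assert len(doms) == 2
        assert {d.class_name for d in doms} == {"CARC", "CRAC"}

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("LVYFKRAG"), size=200))
        matches = enumerate_matches(seq, BUILTIN_PATTERNS["CRAC"])
        doms = collapse_to_domains(matches)
        again = collapse_to_domains(m for d in doms for m in d.support)
        assert [(d.start, d.end) for d in again] == [
            (d.start, d.end) for d in doms
        ]
        assert len(doms) <= len(matches)

    def test_domain_span_is_union_of_support(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("LVYFKRAGCD"), size=300))
        for cls in ("CRAC", "CARC"):
            for d in collapse_to_domains(
                enumerate_matches(seq, BUILTIN_PATTERNS[cls])
            ):
                assert d.start == min(m.start for m in d.support)
                assert d.end == max(m.end for m in d.support)


class TestCaveolin:
    def test_eight_mer_variant(self):
        # F-Q-Y-N-C-R-Q-F: aromatics at relative 1, 3, 8
        (d,) = scan_caveolin("AQ" + "FQYNCRQF" + "QA")
        assert d.class_name == "CAV_8B"
        assert (d.start, d.end) == (3, 10)

    def test_longest_variant_wins(self):
        # Y-P-W-T-Q-R-F-F-E-S-F matches the 8-mer and the 11-mer
        # grammars over the same anchors; the 11-mer is reported
        (d,) = scan_caveolin("YPWTQRFFESF")
        assert d.class_name == "CAV_11"
        assert (d.start, d.end) == (1, 11)
        assert {m.class_name for m in d.support} >= {"CAV_8B", "CAV_11"}

    def test_no_aromatics_no_motif(self):
        assert scan_caveolin("ACDEGKLRVACDEGKLRV") == []


class TestCounting:
    def test_worked_example_counts(self):
        c = count_domains("VTKYWFYR")
        assert c.combined_cholesterol == 1
        assert c.caveolin_domains == 0

    def test_anchor_free_background_counts_zero(self):
        c = count_domains("ACDEG" * 40)
        assert c.combined_cholesterol == c.caveolin_domains == 0
        assert c.cholesterol_sites == 0

    def test_shared_central_aromatic_is_one_site(self):
        # KVAYAKV: CARC K1-Y4-V7 and CRAC V2-Y4-K6 read the same
        # central Y4 in opposite orientations -> one docking site
        chol = scan_cholesterol("KVAYAKV")
        assert len(chol["CRAC"]) == len(chol["CARC"]) == 1
        sites = cholesterol_sites(chol["CRAC"], chol["CARC"])
        assert len(sites) == 1

    def test_distinct_sites_merge_only_on_shared_central(self, globins):
        # cytoglobin carries the textbook case: the CRAC at 119-125 and
        # the overlapping CARC read off the same central Y123
        chol = scan_cholesterol(globins["CYGB"])
        sites = cholesterol_sites(chol["CRAC"], chol["CARC"])
        assert len(chol["CRAC"]) + len(chol["CARC"]) == 4
        assert len(sites) == 3
        merged = [g for g in sites if len(g) > 1]
        assert len(merged) == 1
        assert {d.class_name for d in merged[0]} == {"CRAC", "CARC"}
        shared = frozenset.intersection(
            *(d.centrals for d in merged[0])
        )
        assert 123 in shared


def test_scan_is_invariant_under_numbering_shift(globins):
    from globinscan.seq_io import NumberingScheme, renumber

    rec = globins["HBB"]
    mature = renumber(rec, NumberingScheme.MATURE)
    met = {
        (d.class_name, d.start, d.end)
        for d in scan_cholesterol(rec)["CARC"]
    }
    mat = {
        (d.class_name, d.start + 1, d.end + 1)
        for d in scan_cholesterol(mature)["CARC"]
    }
    assert met == mat
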