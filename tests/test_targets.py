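import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import best_scores_by_interval

from mircascade.sequence_io import DomainError, SequenceRecord, revcomp
from mircascade.targets import (
    BIN_FAVORABLE,
    BIN_LESS,
    BIN_UNFAVORABLE,
    GU,
    MATCH,
    MISMATCH,
    TargetAlignment,
    bin_score,
    cotarget_union,
    family_score_profile,
    find_target_sites,
    score_alignment,
)


def gapless(mirna, states):
    """A gapless alignment object with the given per-position states."""
    return TargetAlignment(
        mirna_seq=mirna, transcript_id="t", site_interval=(1, len(mirna)),
        states=list(states), mirna_positions=list(range(1, len(mirna) + 1)),
    )


class TestScoreAlignment:
    def test_perfect_complement_scores_zero(self):
        assert score_alignment(gapless("A" * 21, [MATCH] * 21)) == 0.0

    @pytest.mark.parametrize("pos,state,expected", [
        (1, GU, 0.5),        # GU outside the doubled window
        (5, MISMATCH, 2.0),  # mismatch inside positions 2-13: doubled
        (13, GU, 1.0),       # GU at the window's inclusive upper bound
        (14, MISMATCH, 1.0), # just outside the window
    ])
    def test_single_defect_penalties(self, pos, state, expected):
        states = [MATCH] * 21
        states[pos - 1] = state
        assert score_alignment(gapless("A" * 21, states)) == expected

    def test_additive_over_columns(self):
        states = [MATCH] * 21
        states[0], states[4] = GU, MISMATCH
        assert score_alignment(gapless("A" * 21, states)) == 0.5 + 2.0

    @given(st.lists(st.sampled_from([MATCH, GU, MISMATCH]), min_size=20,
                    max_size=24))
    def test_scores_are_half_integer_and_monotone(self, states):
        aln = gapless("A" * len(states), states)
        score = score_alignment(aln)
        assert score >= 0 and (2 * score) == int(2 * score)
        # degrading any match column never decreases the score
        for i, s in enumerate(states):
            if s == MATCH:
                worse = list(states)
                worse[i] = MISMATCH
                assert score_alignment(gapless("A" * len(states), worse)) >= score
                break


class TestBinScore:
    @pytest.mark.parametrize("score,label", [
        (5.0, BIN_FAVORABLE),      # inclusive boundary
        (6.0, BIN_LESS),
        (7.0, BIN_LESS),           # inclusive boundary
        (7.5, BIN_UNFAVORABLE),
        (0.0, BIN_FAVORABLE),
    ])
    def test_boundaries(self, score, label):
        assert bin_score(score) == label

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            bin_score(-0.5)


class TestFindTargetSites:
    def test_exact_complement_found_at_zero(self):
        mirna = "TGACAGAAGAGAGTGAGCACA"
        transcript = SequenceRecord("t", "AAAA" + revcomp(mirna) + "GGGG")
        sites = find_target_sites(mirna, transcript, max_score=3)
        assert sites[0].score == 0.0
        assert sites[0].site_interval == (5, 5 + len(mirna) - 1)

    def test_no_window_under_threshold_gives_empty(self):
        transcript = SequenceRecord("t", "A" * 60)
        assert find_target_sites("G" * 21, transcript, max_score=2) == []

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            L = int(rng.integers(5, 11))
            n = int(rng.integers(L + 5, 61))
            mirna = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
            tseq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            check_against_oracle(mirna, tseq, max_score=6.0)


def check_against_oracle(mirna, tseq, max_score):
    """Compare the DP search against window-by-window enumeration."""
    oracle = best_scores_by_interval(mirna, tseq)
    sites = find_target_sites(mirna, SequenceRecord("t", tseq), max_score)
    got = {a.site_interval: a.score for a in sites}
    # every reported site carries the interval's true minimal score
    for iv, sc in got.items():
        assert oracle[iv] == sc, (mirna, tseq, iv, sc, oracle[iv])
    # the global optimum is never missed
    best_oracle = min((s for s in oracle.values()), default=math.inf)
    if best_oracle <= max_score:
        assert min(got.values()) == best_oracle
    # every qualifying interval is reported unless an overlapping
    # equal-score site 5' of it was kept instead
    for iv, sc in oracle.items():
        if sc > max_score or iv in got:
            continue
        assert any(o_iv[0] <= iv[0] and o_iv[1] >= iv[0] and o_sc == sc
                   for o_iv, o_sc in got.items()), (mirna, tseq, iv, sc)


class TestFamilyProfile:
    def test_planted_scores_fall_in_distinct_bins(self):
        rng = np.random.default_rng(23)
        mirna = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
        comp = revcomp(mirna)
        nonpair = {"A": "A", "T": "C", "G": "G", "C": "C"}

        def mutate(site, mirna_positions):
            # a mismatch opposite miRNA position p: site index len-p
            s = list(site)
            for p in mirna_positions:
                s[len(site) - p] = nonpair[mirna[p - 1].replace("U", "T")]
            return "".join(s)

        pad5 = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        pad3 = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        family = [
            # 4.0: two doubled mismatches (positions 4 and 8)
            SequenceRecord("m4", pad5 + mutate(comp, [4, 8]) + pad3),
            # 6.0: three doubled mismatches
            SequenceRecord("m6", pad5 + mutate(comp, [4, 8, 11]) + pad3),
            # 8.0: four doubled mismatches
            SequenceRecord("m8", pad5 + mutate(comp, [3, 5, 8, 11]) + pad3),
        ]
        counts = family_score_profile(mirna, family)
        assert counts == {BIN_FAVORABLE: 1, BIN_LESS: 1, BIN_UNFAVORABLE: 1}

    def test_counts_partition_family(self):
        mirna = "ACGTACGTACGTACGTACGTA"
        family = [SequenceRecord(f"m{i}", revcomp(mirna) + "ACGTACGT" * 5)
                  for i in range(3)]
        counts = family_score_profile(mirna, family)
        assert sum(counts.values()) == 3
        assert counts[BIN_FAVORABLE] == 3


class TestCotargetUnion:
    def test_reported_myb_union(self):
        sizes = {"miR159": 9, "miR828": 19, "miR858": 66}
        overlaps = {frozenset({"miR858", "miR828"}): 11,
                    frozenset({"miR858", "miR159"}): 2,
                    frozenset({"miR828", "miR159"}): 0}
        assert cotarget_union(sizes, overlaps, triple_overlap=0) == 81

    def test_disjoint_and_identical_sets(self):
        assert cotarget_union({"a": 4, "b": 6}, {frozenset({"a", "b"}): 0}) == 10
        assert cotarget_union({"a": 5, "b": 5}, {frozenset({"a", "b"}): 5}) == 5

    def test_inconsistent_overlap_rejected(self):
        with pytest.raises(DomainError):
            cotarget_union({"a": 2, "b": 6}, {frozenset({"a", "b"}): 3})
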