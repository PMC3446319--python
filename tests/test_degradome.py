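import numpy as np
import pytest

from oracles import categorize_bruteforce

from mircascade.degradome import (
    AmbiguousCleavageError,
    DegradomeTag,
    TPlot,
    build_tplot,
    categorize,
    predicted_cleavage_site,
    validate_target,
)
from mircascade.sequence_io import DomainError, SequenceRecord, revcomp
from mircascade.targets import (
    BULGE_TARGET,
    MATCH,
    TargetAlignment,
    find_target_sites,
)


def tplot(values, total=None):
    arr = np.asarray(values, dtype=np.int64)
    return TPlot("t", arr, total or max(1, int(arr.sum())))


def gapless_alignment(start, end):
    L = end - start + 1
    return TargetAlignment(
        mirna_seq="A" * L, transcript_id="t", site_interval=(start, end),
        states=[MATCH] * L, mirna_positions=list(range(1, L + 1)),
    )


class TestBuildTPlot:
    def test_counts_accumulate_per_position(self):
        t = SequenceRecord("t", "A" * 50)
        plot = build_tplot([DegradomeTag("t", 5, 3), DegradomeTag("t", 5, 2)],
                           t, total_tags=100)
        assert plot.abundance[4] == 5

    def test_total_conserved(self):
        t = SequenceRecord("t", "A" * 50)
        tags = [DegradomeTag("t", p, c) for p, c in [(1, 4), (9, 2), (50, 7)]]
        plot = build_tplot(tags, t, total_tags=13)
        assert plot.abundance.sum() == 13

    def test_out_of_range_position_rejected(self):
        t = SequenceRecord("t", "A" * 10)
        with pytest.raises(DomainError):
            build_tplot([DegradomeTag("t", 11, 1)], t, total_tags=1)


class TestPredictedCleavage:
    @pytest.mark.parametrize("start,end,expected", [
        (100, 120, 111),  # 21-nt gapless site: end - 9
        (100, 121, 112),  # 22-nt gapless site
    ])
    def test_gapless_geometry(self, start, end, expected):
        assert predicted_cleavage_site(gapless_alignment(start, end)) == expected

    def test_target_bulge_shifts_by_walking_columns(self):
        # 22-nt site for a 21-nt miRNA: one extra site base between
        # miRNA positions 5 and 6 (3' of the position-10 pairing)
        states = [MATCH] * 5 + [BULGE_TARGET] + [MATCH] * 16
        positions = list(range(1, 6)) + [None] + list(range(6, 22))
        aln = TargetAlignment("A" * 21, "t", (100, 121), states, positions)
        # walk: position 10 is the 11th column, consuming the 11th site
        # nucleotide from the 3' end -> 121 - 10 = 111
        assert predicted_cleavage_site(aln) == 111

    def test_bulge_at_position_ten_is_ambiguous(self):
        from mircascade.targets import BULGE_MIRNA
        states = [MATCH] * 9 + [BULGE_MIRNA] + [MATCH] * 11
        positions = list(range(1, 22))
        aln = TargetAlignment("A" * 21, "t", (100, 119), states, positions)
        with pytest.raises(AmbiguousCleavageError):
            predicted_cleavage_site(aln)


class TestCategorize:
    @pytest.mark.parametrize("values,pos,expected", [
        ([5, 1, 1, 1], 1, 0),        # unique maximum
        ([5, 5, 2], 1, 1),           # tied maximum
        ([5, 5, 2], 2, 1),
        ([10, 4, 2, 2, 1], 2, 2),    # median 2 < 4 < 10
        ([10, 4, 2, 2, 1], 5, 4),    # singleton tag
        ([10, 4, 2, 2, 0], 3, 3),    # at the median
        ([10, 4, 0, 0, 0], 3, None), # no tag: no call
    ])
    def test_category_definitions(self, values, pos, expected):
        assert categorize(tplot(values), pos) == expected

    def test_matches_bruteforce_on_random_tplots(self):
        rng = np.random.default_rng(29)
        for _ in range(300):
            n = int(rng.integers(5, 60))
            values = rng.choice([0, 0, 1, 1, 2, 3, 5, 8, 20], size=n)
            plot = tplot(values)
            pos = int(rng.integers(1, n + 1))
            assert categorize(plot, pos) == categorize_bruteforce(list(values), pos)

    def test_scale_invariant_above_singleton(self):
        values = [10, 4, 2, 2, 1]
        for pos in (1, 2, 3):
            base = categorize(tplot(values), pos)
            scaled = categorize(tplot([v * 7 for v in values]), pos)
            assert base == scaled


class TestValidateTarget:
    def _setup(self, signal_at, signal=90, background=10):
        mirna = "TGACAGAAGAGAGTGAGCACA"
        seq = "C" * 99 + revcomp(mirna) + "C" * 80
        t = SequenceRecord("t", seq)
        rng = np.random.default_rng(31)
        tags = [DegradomeTag("t", signal_at, signal)]
        for p in rng.choice(
                [p for p in range(1, len(seq)) if p != signal_at],
                size=20, replace=False):
            tags.append(DegradomeTag("t", int(p), 1 + int(rng.integers(0, 3))))
        plot = build_tplot(tags, t, total_tags=sum(x.count for x in tags))
        return mirna, t, plot

    def test_planted_cleavage_called_category_zero(self):
        # site at 100..120 -> cleavage at 111
        mirna, t, plot = self._setup(signal_at=111)
        calls = validate_target(mirna, t, plot, max_score=4.5)
        assert len(calls) == 1
        assert calls[0].cleavage_pos == 111
        assert calls[0].category == 0

    def test_tag_free_transcript_yields_no_calls(self):
        mirna = "TGACAGAAGAGAGTGAGCACA"
        t = SequenceRecord("t", "C" * 99 + revcomp(mirna) + "C" * 80)
        plot = TPlot("t", np.zeros(len(t.seq), dtype=np.int64), 1)
        assert validate_target(mirna, t, plot, max_score=4.5) == []

    def test_sites_above_threshold_excluded(self):
        mirna, t, plot = self._setup(signal_at=111)
        # a threshold below 0 excludes even the perfect site
        assert validate_target(mirna, t, plot, max_score=-1) == []
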