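"""miRNA target-site search and Allen penalty scoring.

Plant miRNA targets are recognized by near-perfect antiparallel pairing of
the miRNA with a transcript site. The alignment score used throughout the
package is the classic additive penalty: mismatches and single-nucleotide
bulges or gaps cost 1, GU wobble pairs cost 0.5, and penalties falling at
miRNA positions 2 through 13 (counted from the miRNA 5' end) are doubled.
Lower scores are more cleavage-favorable; a score of 0 is a perfect
complement.

The site search is a bounded dynamic program over every transcript window,
allowing a configurable number of single-nucleotide bulge columns on
either strand, and returns the minimal-score alignment per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequence_io import DomainError, SequenceRecord, dna

#: column states of a miRNA:target alignment
MATCH, GU, MISMATCH, BULGE_MIRNA, BULGE_TARGET = (
    "match", "GU", "mismatch", "bulge_mirna", "bulge_target"
)

#: miRNA positions whose penalties are doubled (inclusive bounds)
DOUBLE_WINDOW = (2, 13)

#: score-bin labels and their boundaries (<=5, (5,7], >7)
BIN_FAVORABLE = "cleavage-favorable"
BIN_LESS = "less cleavage-favorable"
BIN_UNFAVORABLE = "cleavage-unfavorable"
SCORE_BINS = (BIN_FAVORABLE, BIN_LESS, BIN_UNFAVORABLE)

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _pair_state(mirna_base: str, target_base: str) -> str:
    """Classify one paired column: Watson-Crick match, GU wobble, or mismatch.

    Bases are in DNA space; GU wobble maps to {G:T, T:G}.
    """
    if _COMPLEMENT.get(mirna_base) == target_base:
        return MATCH
    if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
        return GU
    return MISMATCH


@dataclass
class TargetAlignment:
    """An antiparallel miRNA:site alignment with per-column states.

    Columns are ordered by ascending miRNA position; miRNA position 1 pairs
    the 3'-most nucleotide of the site. ``mirna_positions[k]`` is None for
    bulge_target columns (the site nucleotide has no miRNA partner).
    """

    mirna_seq: str
    transcript_id: str
    site_interval: tuple[int, int]
    states: list[str]
    mirna_positions: list[int | None]
    score: float = 0.0
    site_seq: str = ""

    def render(self) -> str:
        """Three-line diagram: site 5'->3' over glyphs over miRNA 3'->5'.

        Glyphs: ``|`` match, ``o`` GU wobble, space otherwise.
        """
        q = dna(self.mirna_seq)
        site = dna(self.site_seq)
        top, mid, bot = [], [], []
        ti = len(site) - 1
        glyph = {MATCH: "|", GU: "o", MISMATCH: " "}
        for state, mp in zip(self.states, self.mirna_positions):
            if state == BULGE_MIRNA:
                top.append("-")
                mid.append(" ")
                bot.append(q[mp - 1])
            elif state == BULGE_TARGET:
                top.append(site[ti])
                mid.append(" ")
                bot.append("-")
                ti -= 1
            else:
                top.append(site[ti])
                mid.append(glyph[state])
                bot.append(q[mp - 1])
                ti -= 1
        # columns were built 3'->5' along the site; print site 5'->3'
        return "\n".join(
            "".join(reversed(line)) for line in (top, mid, bot)
        )


def score_alignment(aln: TargetAlignment,
                    double_window: tuple[int, int] = DOUBLE_WINDOW) -> float:
    """Additive alignment penalty: mismatch/bulge 1, GU 0.5, window doubled.

    A bulge_target column inherits the doubling decision of the adjacent
    5'-ward miRNA position (the last miRNA position consumed before it).
    """
    if len(aln.states) != len(aln.mirna_positions):
        raise DomainError("states and mirna_positions lengths differ")
    lo, hi = double_window
    total = 0.0
    last_pos = 0
    for state, mp in zip(aln.states, aln.mirna_positions):
        if state == BULGE_TARGET:
            pos = last_pos
        else:
            if mp is None:
                raise DomainError("non-bulge_target column lacks a miRNA position")
            pos = mp
            last_pos = mp
        if state == MATCH:
            pen = 0.0
        elif state == GU:
            pen = 0.5
        elif state in (MISMATCH, BULGE_MIRNA, BULGE_TARGET):
            pen = 1.0
        else:
            raise DomainError(f"invalid column state {state!r}")
        if lo <= pos <= hi:
            pen *= 2
        total += pen
    return total


def bin_score(score: float) -> str:
    """Bin an alignment score: <=5 favorable, (5,7] less favorable, >7 unfavorable."""
    if score < 0:
        raise DomainError("alignment score must be non-negative")
    if score <= 5:
        return BIN_FAVORABLE
    if score <= 7:
        return BIN_LESS
    return BIN_UNFAVORABLE


# ---------------------------------------------------------------------------
# Site search
# ---------------------------------------------------------------------------

def find_target_sites(mirna: str, transcript: SequenceRecord,
                      max_score: float, max_bulges: int = 1,
                      double_window: tuple[int, int] = DOUBLE_WINDOW,
                      ) -> list[TargetAlignment]:
    """Find all target sites of ``mirna`` on ``transcript`` scoring <= max_score.

    For every transcript window (with up to ``max_bulges`` single-nucleotide
    bulge columns on either strand, never terminal) the minimal-score
    alignment is computed by dynamic programming anchored at the site 3'
    end. Results are sorted by (score, site start); overlapping sites with
    identical score are deduplicated keeping the 5'-most.
    """
    q = dna(mirna)
    t = dna(transcript.seq)
    L, n = len(q), len(t)
    if n <= L:
        return []
    lo, hi = double_window

    def pen(state: str, pos: int) -> float:
        base = {MATCH: 0.0, GU: 0.5}.get(state, 1.0)
        return base * 2 if lo <= pos <= hi else base

    sites: list[TargetAlignment] = []
    # a site with b miRNA-side bulges spans L-b nucleotides, so anchors may
    # sit as close as L - max_bulges to the transcript 5' end
    for t3 in range(max(1, L - max_bulges), n + 1):
        # DP over states (i consumed miRNA, bm, bt) -> (score, backpointer)
        # first and last columns must be paired columns
        best: dict[tuple[int, int, int], tuple[float, tuple | None]] = {}
        first_state = _pair_state(q[0], t[t3 - 1])
        best[(1, 0, 0)] = (pen(first_state, 1), (None, first_state, 1))
        for i in range(1, L):
            level = [k for k in best if k[0] == i]
            # target-side bulges first: they stay at level i, so apply them
            # (repeatedly, up to the bulge budget) before consuming i+1
            frontier = level
            for _ in range(max_bulges):
                added = []
                for key in frontier:
                    ci, bm, bt = key
                    sc = best[key][0]
                    if bm + bt >= max_bulges:
                        continue
                    tpos = t3 - (i + bt - bm)
                    if tpos < 1:
                        continue
                    cand = sc + pen(BULGE_TARGET, i)
                    nkey = (i, bm, bt + 1)
                    if cand <= max_score and (nkey not in best or cand < best[nkey][0]):
                        best[nkey] = (cand, (key, BULGE_TARGET, None))
                        added.append(nkey)
                if not added:
                    break
                frontier = added
            for key in [k for k in best if k[0] == i]:
                ci, bm, bt = key
                sc = best[key][0]
                # paired column for miRNA position i+1
                tpos = t3 - (i + bt - bm)  # 1-based target pos to consume
                if tpos >= 1:
                    st = _pair_state(q[i], t[tpos - 1])
                    cand = sc + pen(st, i + 1)
                    nkey = (i + 1, bm, bt)
                    if cand <= max_score and (nkey not in best or cand < best[nkey][0]):
                        best[nkey] = (cand, (key, st, i + 1))
                # miRNA-side bulge (miRNA position i+1 unpaired), not terminal
                if bm + bt < max_bulges and i + 1 < L:
                    cand = sc + pen(BULGE_MIRNA, i + 1)
                    nkey = (i + 1, bm + 1, bt)
                    if cand <= max_score and (nkey not in best or cand < best[nkey][0]):
                        best[nkey] = (cand, (key, BULGE_MIRNA, i + 1))

        finals = [(sc, key) for key, (sc, _) in best.items() if key[0] == L]
        if not finals:
            continue
        # minimal score per distinct site interval
        by_interval: dict[tuple[int, int], tuple[float, tuple]] = {}
        for sc, key in finals:
            _, bm, bt = key
            start = t3 - (L + bt - bm) + 1
            if start < 1:
                continue
            iv = (start, t3)
            if iv not in by_interval or sc < by_interval[iv][0]:
                by_interval[iv] = (sc, key)
        for (start, end), (sc, key) in by_interval.items():
            states: list[str] = []
            positions: list[int | None] = []
            k: tuple | None = key
            while k is not None:
                entry = best[k]
                prev, st, mp = entry[1]
                states.append(st)
                positions.append(mp)
                k = prev
            states.reverse()
            positions.reverse()
            sites.append(TargetAlignment(
                mirna_seq=mirna, transcript_id=transcript.id,
                site_interval=(start, end), states=states,
                mirna_positions=positions, score=sc,
                site_seq=transcript.seq[start - 1:end],
            ))

    # dedupe overlapping equal-score sites to the 5'-most
    kept: list[TargetAlignment] = []
    for aln in sorted(sites, key=lambda a: a.site_interval[0]):
        drop = False
        for other in kept:
            if (other.score == aln.score
                    and other.site_interval[1] >= aln.site_interval[0]
                    and other.site_interval[0] <= aln.site_interval[1]):
                drop = True
                break
        if not drop:
            kept.append(aln)
    kept.sort(key=lambda a: (a.score, a.site_interval[0]))
    return kept


def best_site_score(mirna: str, transcript: SequenceRecord,
                    max_bulges: int = 1) -> float:
    """Minimal alignment score over all windows (inf when none exists)."""
    sites = find_target_sites(mirna, transcript, max_score=math.inf,
                              max_bulges=max_bulges)
    return sites[0].score if sites else math.inf


def family_score_profile(mirna: str, family: Sequence[SequenceRecord],
                         max_bulges: int = 1) -> dict[str, int]:
    """Per-member best-site scores over a gene family, binned.

    Returns counts over the three score bins; counts sum to the family size
    (members with no feasible alignment fall in the unfavorable bin).
    """
    if not family:
        raise DomainError("family is empty")
    counts = {b: 0 for b in SCORE_BINS}
    for member in family:
        sc = best_site_score(mirna, member, max_bulges=max_bulges)
        label = BIN_UNFAVORABLE if math.isinf(sc) else bin_score(sc)
        counts[label] += 1
    return counts


def cotarget_union(set_sizes: Mapping[str, int],
                   pairwise_overlaps: Mapping[frozenset, int],
                   triple_overlap: int = 0) -> int:
    """Inclusion-exclusion union size over up to three target sets."""
    names = list(set_sizes)
    if len(names) > 3:
        raise DomainError("at most three sets supported")
    for pair, ov in pairwise_overlaps.items():
        if ov > min(set_sizes[x] for x in pair):
            raise DomainError(f"overlap {ov} exceeds a set size for {set(pair)}")
        if ov < 0:
            raise DomainError("negative overlap")
    if pairwise_overlaps and triple_overlap > min(pairwise_overlaps.values()):
        raise DomainError("triple overlap exceeds a pairwise overlap")
    total = sum(set_sizes.values()) - sum(pairwise_overlaps.values())
    if len(names) == 3:
        total += triple_overlap
    return total


def write_site_report(alignments: Iterable[TargetAlignment], path,
                      header_comment: str = "") -> None:
    """Site report TSV: mirna, transcript, site_start, site_end, score, bin."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("mirna\ttranscript\tsite_start\tsite_end\tscore\tbin\talignment\n")
        for a in alignments:
            diagram = a.render().replace("\n", ";")
            fh.write(
                f"{a.mirna_seq}\t{a.transcript_id}\t{a.site_interval[0]}\t"
                f"{a.site_interval[1]}\t{a.score:g}\t{bin_score(a.score)}\t{diagram}\n"
            )
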