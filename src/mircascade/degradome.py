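"""Degradome (PARE) T-plots, cleavage-site location, and category calls.

Degradome sequencing captures the 5' ends of uncapped transcript
fragments; a genuine miRNA-guided cleavage leaves a pile-up of tags at the
position opposite miRNA position 10. Candidate target sites found by the
alignment search are therefore validated by asking how the tag abundance
at the predicted cleavage position ranks against the rest of the
transcript:

* category 0 — the unique maximum of the transcript, with more than 1 read
* category 1 — tied for the maximum, more than 1 read
* category 2 — above the median of occupied positions but below the maximum
* category 3 — at or below the median, more than 1 read
* category 4 — exactly one read at the cleavage position

The median is computed over positions with non-zero abundance only.
Tag abundances are reported as transcripts per billion (TPB).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_io import DomainError, SequenceRecord, tpb_normalize
from .targets import (
    BULGE_MIRNA,
    BULGE_TARGET,
    TargetAlignment,
    bin_score,
    find_target_sites,
)

#: default alignment-score thresholds for degradome validation
MAX_SCORE_KNOWN = 4.5     # conserved and less-conserved miRNAs
MAX_SCORE_NOVEL = 5.0     # novel and candidate miRNAs

#: miRNA position opposite the scissile phosphate
CLEAVAGE_POSITION = 10


class AmbiguousCleavageError(DomainError):
    """miRNA position 10 falls in a bulge column; no unique cleavage site."""


@dataclass
class DegradomeTag:
    """One degradome 5'-tag: transcript, 1-based position of the tag 5' end, count."""

    transcript_id: str
    position: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise DomainError("tag count must be >= 1")
        if self.position < 1:
            raise DomainError("tag position must be >= 1")


@dataclass
class TPlot:
    """Per-position degradome tag abundance along one transcript."""

    transcript_id: str
    abundance: np.ndarray
    total_tags: int

    def tpb(self, position: int) -> float:
        return tpb_normalize(float(self.abundance[position - 1]), self.total_tags)


@dataclass
class CleavageCall:
    """A validated target site with its degradome category."""

    alignment: TargetAlignment
    cleavage_pos: int
    category: int
    tag_count: int
    tag_tpb: float


def build_tplot(tags: Sequence[DegradomeTag], transcript: SequenceRecord,
                total_tags: int) -> TPlot:
    """Accumulate tag counts per transcript position into a T-plot."""
    n = len(transcript.seq)
    abundance = np.zeros(n, dtype=np.int64)
    for tag in tags:
        if tag.transcript_id != transcript.id:
            continue
        if not 1 <= tag.position <= n:
            raise DomainError(
                f"tag position {tag.position} outside transcript "
                f"{transcript.id} (length {n})"
            )
        abundance[tag.position - 1] += tag.count
    return TPlot(transcript_id=transcript.id, abundance=abundance,
                 total_tags=total_tags)


def predicted_cleavage_site(aln: TargetAlignment,
                            cleavage_position: int = CLEAVAGE_POSITION) -> int:
    """Transcript coordinate paired with miRNA position 10.

    This is the 5' end of the 3' cleavage fragment. The alignment columns
    are walked from the site 3' end; bulge columns shift the coordinate,
    and a bulge at position 10 itself raises :class:`AmbiguousCleavageError`.
    """
    t = aln.site_interval[1]  # 3'-most site coordinate, pairs miRNA pos 1
    for state, mp in zip(aln.states, aln.mirna_positions):
        if state == BULGE_MIRNA:
            if mp == cleavage_position:
                raise AmbiguousCleavageError(
                    f"miRNA position {cleavage_position} is a bulge column"
                )
            continue  # consumes no site nucleotide
        if mp == cleavage_position:
            return t
        t -= 1
    raise DomainError(f"alignment does not cover miRNA position {cleavage_position}")


def categorize(tplot: TPlot, position: int) -> int | None:
    """Degradome category (0-4) of a position, or None when it has no tags.

    Computed over positions with non-zero abundance: 4 when exactly one
    read; 0 unique maximum; 1 tied maximum; 2 strictly between median and
    maximum; 3 at or below the median.
    """
    n = len(tplot.abundance)
    if not 1 <= position <= n:
        raise DomainError(f"position {position} outside transcript (length {n})")
    x = int(tplot.abundance[position - 1])
    if x == 0:
        return None
    if x == 1:
        return 4
    occupied = tplot.abundance[tplot.abundance > 0]
    mx = int(occupied.max())
    med = float(np.median(occupied))
    if x == mx:
        return 0 if int((occupied == mx).sum()) == 1 else 1
    if x > med:
        return 2
    return 3


def validate_target(mirna: str, transcript: SequenceRecord, tplot: TPlot,
                    max_score: float = MAX_SCORE_KNOWN,
                    max_bulges: int = 1,
                    neighbor_window: int = 0) -> list[CleavageCall]:
    """Predict sites, locate cleavage positions, and call categories.

    Sites scoring above ``max_score`` are excluded by the search; sites
    whose cleavage position carries no tag yield no call. With
    ``neighbor_window`` = 1, a tag-free exact position falls back to the
    best tagged position within +/-1 nt (off-by-one tag ends); disabled by
    default. Alignment variants predicting the same cleavage position
    collapse to the best-scoring one. Calls are sorted by category then
    descending tag abundance.
    """
    calls: list[CleavageCall] = []
    for aln in find_target_sites(mirna, transcript, max_score=max_score,
                                 max_bulges=max_bulges):
        try:
            pos = predicted_cleavage_site(aln)
        except AmbiguousCleavageError:
            continue
        if tplot.abundance[pos - 1] == 0 and neighbor_window:
            lo = max(1, pos - neighbor_window)
            hi = min(len(tplot.abundance), pos + neighbor_window)
            cand = max(range(lo, hi + 1), key=lambda p: tplot.abundance[p - 1])
            if tplot.abundance[cand - 1] > 0:
                pos = cand
        cat = categorize(tplot, pos)
        if cat is None:
            continue
        calls.append(CleavageCall(
            alignment=aln, cleavage_pos=pos, category=cat,
            tag_count=int(tplot.abundance[pos - 1]),
            tag_tpb=tplot.tpb(pos),
        ))
    by_pos: dict[int, CleavageCall] = {}
    for c in calls:
        prev = by_pos.get(c.cleavage_pos)
        if prev is None or c.alignment.score < prev.alignment.score:
            by_pos[c.cleavage_pos] = c
    out = list(by_pos.values())
    out.sort(key=lambda c: (c.category, -c.tag_tpb))
    return out


# ---------------------------------------------------------------------------
# Tag table I/O and call report
# ---------------------------------------------------------------------------

def read_degradome_table(path: str | Path) -> list[DegradomeTag]:
    """Read a ``transcript_id<TAB>position<TAB>count`` tag table."""
    df = pd.read_csv(path, sep="\t")
    return [
        DegradomeTag(str(r["transcript_id"]), int(r["position"]), int(r["count"]))
        for _, r in df.iterrows()
    ]


def write_degradome_table(tags: Sequence[DegradomeTag], path: str | Path) -> None:
    pd.DataFrame(
        [{"transcript_id": t.transcript_id, "position": t.position, "count": t.count}
         for t in tags]
    ).to_csv(path, sep="\t", index=False)


def write_call_report(calls: Iterable[tuple[str, str, CleavageCall]], path,
                      header_comment: str = "") -> None:
    """Call report TSV: miRNA, target, AS, TPB, category, annotation columns."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("mirna\ttarget\tAS\tcleavage_pos\tTPB\tcategory\tbin\n")
        for mirna, target, call in calls:
            fh.write(
                f"{mirna}\t{target}\t{call.alignment.score:g}\t{call.cleavage_pos}\t"
                f"{call.tag_tpb:.2f}\t{call.category}\t{bin_score(call.alignment.score)}\n"
            )
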