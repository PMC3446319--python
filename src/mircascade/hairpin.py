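"""Hairpin precursor evaluation and novel-miRNA annotation.

Candidate miRNA precursors are screened against the community criteria for
plant miRNA annotation: the mature small RNA must be 20-22 nt, sit on one
arm of a stem-loop, form a duplex with its star strand carrying at most
four mismatches and at most one central (asymmetric) bulge, and the
mature/star pair must account for more than 75% of the small-RNA reads
mapping to the precursor locus. Candidates whose star strand is actually
observed in the sequenced libraries are classified ``novel``; compliant
candidates without a sequenced star are classified ``candidate``.

Structures may be supplied externally as dot-bracket strings, or computed
with the built-in baseline folder (:func:`fold_baseline`), a Nussinov-style
maximum base-pairing dynamic program over Watson-Crick and GU pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_io import (
    DomainError,
    GenomeLocus,
    ParseError,
    SmallRNARead,
    dna,
)

#: base pairs accepted by the baseline folder, DNA space, incl. GU wobble
PAIRABLE = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                      ("G", "T"), ("T", "G")})

DUPLEX_MAX_MISMATCHES = 4
DUPLEX_MAX_BULGES = 1
DUPLEX_READ_FRACTION = 0.75
MATURE_LENGTH_RANGE = (20, 22)
STAR_OVERHANG = 2


class LoopSpanningError(DomainError):
    """The mature interval crosses the terminal loop of the hairpin."""


@dataclass
class SecondaryStructure:
    """A sequence with its nested dot-bracket secondary structure."""

    seq: str
    db: str
    #: 0-based partner index per position, -1 where unpaired
    pairs: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.db):
            raise DomainError("sequence and structure lengths differ")
        stack: list[int] = []
        pairs = [-1] * len(self.db)
        for i, c in enumerate(self.db):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise DomainError(f"unbalanced ')' at position {i + 1}")
                j = stack.pop()
                pairs[i], pairs[j] = j, i
            elif c != ".":
                raise DomainError(f"invalid structure character {c!r}")
        if stack:
            raise DomainError(f"unbalanced '(' at position {stack[-1] + 1}")
        self.pairs = pairs

    def partner(self, pos: int) -> int | None:
        """1-based partner of a 1-based position, or None when unpaired."""
        p = self.pairs[pos - 1]
        return None if p < 0 else p + 1


@dataclass
class DuplexEvaluation:
    """Mismatch/bulge bookkeeping for a miRNA/miRNA* duplex."""

    mismatches: int
    bulges: int
    bulge_sizes: list[int]
    passes: bool


@dataclass
class PrecursorCandidate:
    """One evaluated precursor locus with its classification and reason code."""

    name: str
    locus: GenomeLocus
    structure: SecondaryStructure | None
    mature: tuple[int, int]
    mature_seq: str
    star: tuple[int, int] | None = None
    star_seq: str | None = None
    duplex: DuplexEvaluation | None = None
    duplex_fraction: float | None = None
    classification: str = "rejected"
    reason: str = ""
    structure_source: str = "baseline"


# ---------------------------------------------------------------------------
# Baseline folder
# ---------------------------------------------------------------------------

def _pairable(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


def fold_baseline(seq: str, min_loop: int = 3) -> SecondaryStructure:
    """Maximum base-pairing nested structure (Nussinov dynamic program).

    Watson-Crick plus GU pairs; hairpin loops of at least ``min_loop``
    unpaired nucleotides. The traceback is deterministic: at each interval
    the 5' position is paired whenever pairing it achieves the optimum,
    with the smallest achieving partner index chosen.
    """
    s = dna(seq)
    n = len(s)
    if n < 2 * min_loop:
        raise DomainError(f"sequence too short to fold ({n} nt)")
    if any(c not in "ACGTN" for c in s):
        bad = next(c for c in s if c not in "ACGTN")
        raise DomainError(f"non-nucleotide character {bad!r}")

    # N[i][j] = max pairs in s[i..j]
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if _pairable(s[i], s[k]):
                    inner = N[i + 1][k - 1] if k - 1 > i else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + inner + right)
            N[i][j] = best

    db = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = N[i][j]
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _pairable(s[i], s[k]):
                inner = N[i + 1][k - 1] if k - 1 > i else 0
                right = N[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + right == target:
                    db[i], db[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return SecondaryStructure(seq=seq, db="".join(db))


# ---------------------------------------------------------------------------
# Star inference and duplex evaluation
# ---------------------------------------------------------------------------

def infer_star(structure: SecondaryStructure,
               mature: tuple[int, int],
               overhang: int = STAR_OVERHANG) -> tuple[int, int]:
    """Infer the miRNA* interval from Dicer duplex geometry.

    The star strand pairs the mature strand leaving ``overhang``-nt 3'
    overhangs on both duplex ends: the star 5' end pairs mature position
    ``end - overhang`` and the star 3' end extends ``overhang`` nt past the
    partner of the mature 5' end. Unpaired mature ends are bridged by
    projecting from the nearest paired position. The result is clipped to
    the precursor bounds.
    """
    s, e = mature
    n = len(structure.seq)
    if not 1 <= s <= e <= n:
        raise DomainError(f"mature interval {mature} out of bounds")
    for pos in range(s, e + 1):
        p = structure.partner(pos)
        if p is not None and s <= p <= e:
            raise LoopSpanningError(
                f"mature interval {mature} spans the terminal loop"
            )

    # star 3' end: project from the nearest paired position at/after s
    q = next((pos for pos in range(s, e + 1) if structure.partner(pos)), None)
    if q is None:
        raise DomainError("mature interval is entirely unpaired")
    end3 = structure.partner(q) + (q - s) + overhang
    # star 5' end: project from the nearest paired position at/before e - overhang
    anchor = e - overhang
    q2 = next((pos for pos in range(anchor, s - 1, -1) if structure.partner(pos)), None)
    start5 = structure.partner(q2) - (anchor - q2)
    lo, hi = sorted((start5, end3))
    return (max(1, lo), min(n, hi))


def _effective_partner(structure: SecondaryStructure, pos: int,
                       window: tuple[int, int]) -> int | None:
    """Partner of ``pos`` if it falls inside ``window``, else None."""
    p = structure.partner(pos)
    if p is not None and window[0] <= p <= window[1]:
        return p
    return None


def evaluate_duplex(structure: SecondaryStructure,
                    mature: tuple[int, int],
                    star: tuple[int, int],
                    overhang: int = STAR_OVERHANG) -> DuplexEvaluation:
    """Count mismatches and asymmetric bulges in the miRNA/miRNA* duplex.

    Walks the two strands antiparallel, excluding the ``overhang``-nt 3'
    overhangs. Opposite unpaired positions count as one mismatch; each
    maximal run of unpaired positions on a single side counts as one bulge.
    The criteria pass when mismatches <= 4 and bulges <= 1.
    """
    n = len(structure.seq)
    for s_, e_ in (mature, star):
        if not 1 <= s_ <= e_ <= n:
            raise DomainError("duplex interval out of bounds")
    if not (mature[1] < star[0] or star[1] < mature[0]):
        raise DomainError("mature and star intervals overlap")

    # pairing (non-overhang) region of each strand: all but its 2-nt 3' tail
    m_lo, m_hi = mature[0], mature[1] - overhang
    s_lo, s_hi = star[0], star[1] - overhang
    m_win, s_win = (s_lo, s_hi), (m_lo, m_hi)

    mismatches = 0
    bulge_sizes: list[int] = []
    run_side: str | None = None
    run_len = 0

    def close_run() -> None:
        nonlocal run_side, run_len
        if run_side is not None and run_len > 0:
            bulge_sizes.append(run_len)
        run_side, run_len = None, 0

    i, j = m_lo, s_hi  # mature 5'->3' against star 3'->5'
    while i <= m_hi and j >= s_lo:
        pi = _effective_partner(structure, i, m_win)
        pj = _effective_partner(structure, j, s_win)
        if pi == j:
            close_run()
            i, j = i + 1, j - 1
        elif pi is None and pj is None:
            close_run()
            mismatches += 1
            i, j = i + 1, j - 1
        elif pi is None:
            if run_side != "mature":
                close_run()
                run_side = "mature"
            run_len += 1
            i += 1
        elif pj is None:
            if run_side != "star":
                close_run()
                run_side = "star"
            run_len += 1
            j -= 1
        else:
            # both paired but not to each other; consume the side whose
            # partner lies behind the other pointer (nested geometry)
            if pi < j:
                if run_side != "star":
                    close_run()
                    run_side = "star"
                run_len += 1
                j -= 1
            else:
                if run_side != "mature":
                    close_run()
                    run_side = "mature"
                run_len += 1
                i += 1
    close_run()
    # asymmetric leftovers inside the duplex bounds count as one bulge
    left_m = m_hi - i + 1
    left_s = j - s_lo + 1
    if left_m > 0:
        bulge_sizes.append(left_m)
    if left_s > 0:
        bulge_sizes.append(left_s)

    bulges = len(bulge_sizes)
    passes = mismatches <= DUPLEX_MAX_MISMATCHES and bulges <= DUPLEX_MAX_BULGES
    return DuplexEvaluation(mismatches=mismatches, bulges=bulges,
                            bulge_sizes=bulge_sizes, passes=passes)


# ---------------------------------------------------------------------------
# Read-distribution rule
# ---------------------------------------------------------------------------

def duplex_read_fraction(locus_reads: Sequence[tuple[SmallRNARead, int]],
                         mature: tuple[int, int],
                         star: tuple[int, int] | None,
                         shift: int = 2) -> tuple[float, bool]:
    """Fraction of locus reads attributable to the mature/star duplex.

    ``locus_reads`` are (read, 1-based start on the precursor) pairs. A read
    is attributed to an arm when its start lies within ``shift`` nt of that
    arm's start and its span stays within the arm (expanded by ``shift``).
    Passing requires the fraction to exceed 0.75 strictly.
    """
    if not locus_reads:
        raise DomainError("no reads at locus")
    arms = [mature] + ([star] if star else [])
    num = 0
    den = 0
    for read, start in locus_reads:
        cnt = read.total_count
        den += cnt
        end = start + len(read.seq) - 1
        for a_lo, a_hi in arms:
            if abs(start - a_lo) <= shift and start >= a_lo - shift and end <= a_hi + shift:
                num += cnt
                break
    frac = num / den
    return frac, frac > DUPLEX_READ_FRACTION


# ---------------------------------------------------------------------------
# Homology exclusion and the annotation pipeline
# ---------------------------------------------------------------------------

def matches_known(mature: str, known: Iterable[str], max_mismatch: int = 2) -> bool:
    """Ungapped bounded-mismatch match of a mature sequence to known miRNAs.

    The shorter sequence slides over the longer; a hit anywhere within
    ``max_mismatch`` mismatches counts as homologous.
    """
    q = dna(mature)
    for ref in known:
        r = dna(ref)
        a, b = (q, r) if len(q) <= len(r) else (r, q)
        for off in range(len(b) - len(a) + 1):
            mm = sum(1 for i in range(len(a)) if a[i] != b[off + i])
            if mm <= max_mismatch:
                return True
    return False


@dataclass
class HairpinLocus:
    """Input bundle for one candidate precursor locus."""

    name: str
    locus: GenomeLocus
    precursor: str
    mature: tuple[int, int]
    locus_reads: list[tuple[SmallRNARead, int]]
    structure: SecondaryStructure | None = None


def annotate_candidates(loci: Sequence[HairpinLocus],
                        known_mirnas: Sequence[str] = (),
                        max_known_mismatch: int = 2,
                        min_fraction_shift: int = 2) -> list[PrecursorCandidate]:
    """Run the full precursor screen and classify each locus.

    Order of filters: (1) homology to known miRNAs (<=2 mismatches) drops
    the locus as a known-family homolog; (2) mature length 20-22 nt;
    (3) stem-loop/duplex criteria; (4) strict >75% duplex read fraction;
    (5) classification ``novel`` when any locus read equals the inferred
    star sequence exactly, else ``candidate``. Rejected loci are retained
    with a reason code.
    """
    out: list[PrecursorCandidate] = []
    for hp in loci:
        s, e = hp.mature
        mature_seq = hp.precursor[s - 1:e]
        cand = PrecursorCandidate(
            name=hp.name, locus=hp.locus, structure=hp.structure,
            mature=hp.mature, mature_seq=mature_seq,
            structure_source="external" if hp.structure else "baseline",
        )
        if known_mirnas and matches_known(mature_seq, known_mirnas, max_known_mismatch):
            cand.classification, cand.reason = "rejected", "known_homolog"
            out.append(cand)
            continue
        if not MATURE_LENGTH_RANGE[0] <= len(mature_seq) <= MATURE_LENGTH_RANGE[1]:
            cand.classification, cand.reason = "rejected", "mature_length"
            out.append(cand)
            continue
        structure = hp.structure or fold_baseline(hp.precursor)
        cand.structure = structure
        try:
            star = infer_star(structure, hp.mature)
        except LoopSpanningError:
            cand.classification, cand.reason = "rejected", "loop_spanning_mature"
            out.append(cand)
            continue
        except DomainError:
            cand.classification, cand.reason = "rejected", "no_duplex"
            out.append(cand)
            continue
        cand.star = star
        cand.star_seq = hp.precursor[star[0] - 1:star[1]]
        try:
            duplex = evaluate_duplex(structure, hp.mature, star)
        except DomainError:
            # degenerate geometry (e.g. star overlapping mature on a
            # poorly folding locus) fails the duplex criteria outright
            cand.classification, cand.reason = "rejected", "no_duplex"
            out.append(cand)
            continue
        cand.duplex = duplex
        if not duplex.passes:
            cand.classification, cand.reason = "rejected", "duplex_criteria"
            out.append(cand)
            continue
        if not hp.locus_reads:
            cand.classification, cand.reason = "rejected", "no_reads"
            out.append(cand)
            continue
        frac, ok = duplex_read_fraction(hp.locus_reads, hp.mature, star,
                                        shift=min_fraction_shift)
        cand.duplex_fraction = frac
        if not ok:
            cand.classification, cand.reason = "rejected", "duplex_fraction"
            out.append(cand)
            continue
        star_dna = dna(cand.star_seq)
        has_star_read = any(dna(r.seq) == star_dna for r, _ in hp.locus_reads)
        cand.classification = "novel" if has_star_read else "candidate"
        cand.reason = "star_read_observed" if has_star_read else "no_star_read"
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Dot-bracket file I/O (FASTA-like: header, sequence line, structure line)
# ---------------------------------------------------------------------------

def read_structures(path: str | Path) -> dict[str, SecondaryStructure]:
    structures: dict[str, SecondaryStructure] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise ParseError(f"{path}: expected '>' header on line {i + 1}")
        if i + 2 >= len(lines):
            raise ParseError(f"{path}: truncated record at line {i + 1}")
        name = line[1:].split()[0]
        structures[name] = SecondaryStructure(seq=lines[i + 1].strip(),
                                              db=lines[i + 2].strip())
        i += 3
    return structures


def write_structures(structures: dict[str, SecondaryStructure], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, st in structures.items():
            fh.write(f">{name}\n{st.seq}\n{st.db}\n")
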