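"""Consensus, information content, and signature scanning of aligned blocks.

Used for the conserved miRNA co-target region of MYB genes: the consensus
of an aligned nucleotide or peptide block is the most frequent residue per
column, conservation is expressed as bits of information content
(log2(alphabet) minus the column's Shannon entropy, no small-sample
correction), and MYB family members are collected by bounded-mismatch
scanning with the conserved co-target signature peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from typing import Mapping, Sequence

from .sequence_io import GAP, DomainError, SequenceRecord

ALPHABET_SIZES = {"DNA": 4, "RNA": 4, "protein": 20}

#: gap-majority columns are masked in logo output
GAP_MASK_FRACTION = 0.5


@dataclass
class AlignedBlock:
    """Equal-length aligned rows over a declared alphabet."""

    sequences: list[str]
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise DomainError("aligned block is empty")
        n = len(self.sequences[0])
        if any(len(s) != n for s in self.sequences):
            raise DomainError("aligned rows have unequal lengths")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    def column(self, pos: int) -> list[str]:
        """Residues of a 1-based column."""
        return [s[pos - 1] for s in self.sequences]


@dataclass
class LogoColumn:
    position: int
    frequencies: dict[str, float]
    bits: float
    masked: bool = False
    tie: bool = False


def column_frequencies(column: Sequence[str]) -> dict[str, float]:
    """Relative frequencies over non-gap residues of one column."""
    residues = [c for c in column if c != GAP]
    if not residues:
        return {}
    counts = Counter(residues)
    total = sum(counts.values())
    return {r: c / total for r, c in sorted(counts.items())}


def consensus(block: AlignedBlock) -> tuple[str, list[bool]]:
    """Most-frequent-residue consensus with per-column tie flags.

    Ties are broken alphabetically; all-gap columns yield 'N' (nucleotide)
    or 'X' (protein) and are flagged.
    """
    unknown = "X" if block.alphabet == "protein" else "N"
    out = []
    ties = []
    for pos in range(1, block.width + 1):
        freqs = column_frequencies(block.column(pos))
        if not freqs:
            out.append(unknown)
            ties.append(True)
            continue
        top = max(freqs.values())
        winners = sorted(r for r, f in freqs.items() if f == top)
        out.append(winners[0])
        ties.append(len(winners) > 1)
    return "".join(out), ties


def information_content(frequencies: Mapping[str, float],
                        alphabet_size: int) -> float:
    """Column conservation in bits: log2(alphabet) - Shannon entropy."""
    if not frequencies:
        raise DomainError("empty column")
    total = sum(frequencies.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise DomainError(f"frequencies sum to {total}, expected 1")
    entropy = -sum(f * math.log2(f) for f in frequencies.values() if f > 0)
    return math.log2(alphabet_size) - entropy


def logo_columns(block: AlignedBlock) -> list[LogoColumn]:
    """Per-column frequencies and bit values; gap-majority columns masked."""
    size = ALPHABET_SIZES.get(block.alphabet, 4)
    cols = []
    for pos in range(1, block.width + 1):
        column = block.column(pos)
        gap_frac = column.count(GAP) / len(column)
        freqs = column_frequencies(column)
        bits = information_content(freqs, size) if freqs else 0.0
        top = max(freqs.values(), default=0.0)
        tie = sum(1 for f in freqs.values() if f == top) > 1
        cols.append(LogoColumn(position=pos, frequencies=freqs, bits=bits,
                               masked=gap_frac > GAP_MASK_FRACTION, tie=tie))
    return cols


@dataclass
class SignatureHit:
    protein_id: str
    start: int  # 1-based
    end: int
    mismatches: int
    span: str


def signature_scan(proteins: Sequence[SequenceRecord], signature: str,
                   max_mismatches: int = 6) -> list[SignatureHit]:
    """Bounded-mismatch sliding-window scan for a signature peptide.

    Every protein's best span (fewest mismatches, 5'-most on ties) within
    ``max_mismatches`` of the signature is reported; proteins with no
    qualifying span are omitted.
    """
    if not signature:
        raise DomainError("signature is empty")
    sig = signature.upper()
    k = len(sig)
    hits = []
    for prot in proteins:
        seq = prot.seq.upper()
        best: SignatureHit | None = None
        for off in range(len(seq) - k + 1):
            mm = sum(1 for i in range(k) if seq[off + i] != sig[i])
            if mm <= max_mismatches and (best is None or mm < best.mismatches):
                best = SignatureHit(protein_id=prot.id, start=off + 1,
                                    end=off + k, mismatches=mm,
                                    span=seq[off:off + k])
                if mm == 0:
                    break
        if best is not None:
            hits.append(best)
    return hits


def cotarget_span(len_site_a: int, spacer: int, len_site_b: int) -> int:
    """Total nucleotide span of two adjacent target sites and their spacer."""
    if min(len_site_a, spacer, len_site_b) < 0:
        raise DomainError("lengths must be non-negative")
    return len_site_a + spacer + len_site_b


def write_logo_table(columns: Sequence[LogoColumn], path,
                     header_comment: str = "") -> None:
    """Logo table TSV: position, residue frequencies, bits, masked flag."""
    residues = sorted({r for col in columns for r in col.frequencies})
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("position\t" + "\t".join(residues) + "\tbits\tmasked\n")
        for col in columns:
            freqs = "\t".join(f"{col.frequencies.get(r, 0.0):.4f}" for r in residues)
            fh.write(f"{col.position}\t{freqs}\t{col.bits:.4f}\t{int(col.masked)}\n")
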