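"""Sequence and small-RNA read I/O, normalization, and family grouping.

This module holds the data model shared by the whole pipeline: plain
sequence records (transcripts, precursors, proteins), distinct small-RNA
reads with per-library counts, sequencing libraries with their
genome-matched totals, and miRNA families grouped by bounded mismatch.

Normalization conventions follow standard small-RNA practice: sRNA
abundances are expressed as reads per million (RPM) of the reads that
perfectly match the reference in each library, and degradome tag counts
as transcripts per billion (TPB) of the total tag count.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: gap character accepted in aligned blocks
GAP = "-"


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


class DomainError(ValueError):
    """Raised when an operation's numeric or structural precondition fails."""


def dna(seq: str) -> str:
    """Map a nucleotide string to upper-case DNA form (U -> T).

    All sequence comparison in the package happens in DNA space; output
    preserves whatever alphabet the caller stored.
    """
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space."""
    return str(Seq(dna(seq)).reverse_complement())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named sequence (transcript, precursor, or protein)."""

    id: str
    seq: str
    description: str = ""
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if not self.seq:
            raise DomainError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SmallRNARead:
    """A distinct small-RNA sequence with per-library raw counts.

    ``rpm`` is populated by :func:`normalize_reads`; before normalization it
    is an empty mapping.
    """

    seq: str
    counts: dict[str, int] = field(default_factory=dict)
    rpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 18 <= len(self.seq) <= 30:
            raise DomainError(
                f"read length {len(self.seq)} outside 18-30 nt: {self.seq}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise DomainError(f"negative count for read {self.seq}")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def total_rpm(self) -> float:
        return sum(self.rpm.values())


@dataclass
class Library:
    """A sequencing library and its total of perfectly reference-matched reads."""

    name: str
    total_matched: int

    def __post_init__(self) -> None:
        if self.total_matched <= 0:
            raise DomainError(
                f"library {self.name!r}: total_matched must be positive"
            )


@dataclass
class GenomeLocus:
    """A 1-based inclusive interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise DomainError(f"invalid locus {self.contig}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise DomainError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class MiRNAFamily:
    """A group of mature sequences within the mismatch radius of each other."""

    members: list[SmallRNARead]
    representative: SmallRNARead


# ---------------------------------------------------------------------------
# FASTA and table I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "DNA") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty FASTA file (line 1)")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        raise ParseError(f"{path}: expected '>' header on line 1, got {first[:40]!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has no sequence")
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=str(rec.seq).upper(),
                description=rec.description[len(rec.id):].strip(),
                alphabet=alphabet,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA (wrapped at ``width`` columns)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_read_table(path: str | Path) -> list[SmallRNARead]:
    """Read a tab-delimited read table: ``sequence<TAB>lib1<TAB>lib2...``."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sequence":
        raise ParseError(f"{path}: first column must be 'sequence' (line 1)")
    libs = list(df.columns[1:])
    reads = []
    for _, row in df.iterrows():
        counts = {lib: int(row[lib]) for lib in libs}
        reads.append(SmallRNARead(seq=str(row["sequence"]), counts=counts))
    return reads


def write_read_table(reads: Sequence[SmallRNARead], path: str | Path) -> None:
    libs = sorted({lib for r in reads for lib in r.counts})
    rows = [{"sequence": r.seq, **{lib: r.counts.get(lib, 0) for lib in libs}} for r in reads]
    pd.DataFrame(rows, columns=["sequence", *libs]).to_csv(path, sep="\t", index=False)


def read_library_sizes(path: str | Path) -> list[Library]:
    """Read a ``library<TAB>total_matched`` file."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["library", "total_matched"]:
        raise ParseError(f"{path}: expected header 'library\\ttotal_matched' (line 1)")
    return [Library(str(r["library"]), int(r["total_matched"])) for _, r in df.iterrows()]


def write_library_sizes(libraries: Sequence[Library], path: str | Path) -> None:
    pd.DataFrame(
        [{"library": l.name, "total_matched": l.total_matched} for l in libraries]
    ).to_csv(path, sep="\t", index=False)


def write_gff3(loci: Sequence[tuple[str, GenomeLocus]], path: str | Path,
               source: str = "mircascade", feature: str = "miRNA_primary_transcript") -> None:
    """Emit named loci as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, loc in loci:
            fh.write(
                f"{loc.contig}\t{source}\t{feature}\t{loc.start}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\tID={name}\n"
            )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def rpm_normalize(count: float, library: Library) -> float:
    """Reads per million genome-matched reads: count / total_matched * 1e6."""
    if library.total_matched <= 0:
        raise DomainError("total_matched must be positive")
    if count < 0:
        raise DomainError("count must be non-negative")
    return count / library.total_matched * 1e6


def tpb_normalize(count: float, total_tags: int) -> float:
    """Degradome transcripts per billion: count / total_tags * 1e9."""
    if total_tags <= 0:
        raise DomainError("total_tags must be positive")
    if count < 0:
        raise DomainError("count must be non-negative")
    return count / total_tags * 1e9


def aggregate_total_rpm(per_library_rpm: Iterable[float]) -> float:
    """Sum per-library RPM values into a total abundance."""
    values = list(per_library_rpm)
    if any(v < 0 for v in values):
        raise DomainError("RPM values must be non-negative")
    return float(sum(values))


def normalize_reads(reads: Sequence[SmallRNARead], libraries: Sequence[Library]) -> None:
    """Populate ``rpm`` on every read, in place, against each library's total."""
    by_name = {l.name: l for l in libraries}
    for read in reads:
        read.rpm = {
            lib: rpm_normalize(cnt, by_name[lib])
            for lib, cnt in read.counts.items()
            if lib in by_name
        }


# ---------------------------------------------------------------------------
# Family grouping
# ---------------------------------------------------------------------------

def hamming_5p(a: str, b: str) -> int:
    """Mismatch count over the 5'-aligned common prefix, in DNA space."""
    a, b = dna(a), dna(b)
    n = min(len(a), len(b))
    return sum(1 for i in range(n) if a[i] != b[i])


def within_family_radius(a: str, b: str, max_mismatch: int = 2,
                         max_length_diff: int = 2) -> bool:
    if abs(len(a) - len(b)) > max_length_diff:
        return False
    return hamming_5p(a, b) <= max_mismatch


def group_families(matures: Sequence[SmallRNARead], max_mismatch: int = 2) -> list[MiRNAFamily]:
    """Group mature miRNAs into families by single-linkage bounded mismatch.

    Two sequences are linked when their 5'-aligned Hamming distance is at
    most ``max_mismatch`` and their lengths differ by at most 2 nt. The
    returned family list is deterministic: families sorted by representative
    abundance (descending) then representative sequence; the representative
    is the most abundant member (ties broken lexicographically).
    """
    n = len(matures)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if within_family_radius(matures[i].seq, matures[j].seq, max_mismatch):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[SmallRNARead]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(matures[i])

    def abundance(r: SmallRNARead) -> float:
        return r.total_rpm if r.rpm else float(r.total_count)

    families = []
    for members in groups.values():
        rep = min(members, key=lambda r: (-abundance(r), r.seq))
        members_sorted = sorted(members, key=lambda r: (-abundance(r), r.seq))
        families.append(MiRNAFamily(members=members_sorted, representative=rep))
    families.sort(key=lambda f: (-abundance(f.representative), f.representative.seq))
    return families


# ---------------------------------------------------------------------------
# Bundled reference table (printed annotation table from the source study)
# ---------------------------------------------------------------------------

def load_apple_specific_table() -> pd.DataFrame:
    """Load the bundled table of apple-specific miRNA annotations.

    Columns: name, mirna_seq, contig, length, strand, position, star_seq
    (the literal string ``No star found`` where no star strand was
    sequenced), per-tissue normalized reads (leaf/root/flower/fruit), total.
    """
    ref = importlib.resources.files("mircascade.data") / "table1_apple_specific.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
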