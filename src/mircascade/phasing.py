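"""21-nt phasing-register analysis anchored at miRNA cleavage sites.

After a 22-nt miRNA (or one of a few special 21-nt triggers) cleaves a
transcript, RDR6/DCL4 convert the 3' fragment into phased 21-nt siRNA
duplexes. Register 1 begins at the first nucleotide of the 3' cleavage
fragment (cleavage position + 1); every 21 nt downstream opens the next
register. A locus is phased when reads concentrate in cycle offset 0.

Antisense reads are mapped into the sense register frame by adding the
2-nt 3' overhang of RDR6/DCL4 duplexes before taking the modulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .sequence_io import DomainError, SequenceRecord, SmallRNARead, dna
from .targets import (
    BULGE_MIRNA,
    MISMATCH,
    TargetAlignment,
    find_target_sites,
)

PHASE = 21
#: default analysis window: registers 1..12
DEFAULT_CYCLES = 12
#: antisense reads sit 2 nt offset from the sense register frame
ANTISENSE_OFFSET = 2
#: default phased-fraction threshold for calling a locus phased
PHASED_FRACTION_THRESHOLD = 0.5


@dataclass
class RegisterProfile:
    """Occupancy of the 21 cycle offsets downstream of a cleavage anchor."""

    cleavage_pos: int
    phase: int
    offsets: list[int]
    registers: dict[int, int]
    total: int
    phased_fraction: float | None

    @property
    def defined(self) -> bool:
        return self.phased_fraction is not None


@dataclass
class PhasedLocusCall:
    locus: tuple[int, int]
    phased_fraction: float
    n_species: int
    passes: bool


@dataclass
class Tas3Architecture:
    """Dual trigger-site architecture of a TAS3-like transcript."""

    site5: TargetAlignment
    site3: TargetAlignment
    site5_pos10_mismatch: bool
    inter_site_region: tuple[int, int]
    n_tasiarf: int = 0


def assign_register(read_start: int, cleavage_pos: int,
                    phase: int = PHASE) -> tuple[int, int | None]:
    """Cycle offset (0..phase-1) and register index of a sense read start.

    Register k starts at ``cleavage_pos + 1 + phase*(k-1)``; the register
    index is defined only for in-phase reads (offset 0).
    """
    if read_start <= cleavage_pos:
        raise DomainError(
            f"read start {read_start} is upstream of cleavage at {cleavage_pos}"
        )
    delta = read_start - cleavage_pos - 1
    offset = delta % phase
    register = 1 + delta // phase if offset == 0 else None
    return offset, register


def register_profile(reads: Sequence[tuple[SmallRNARead, int, str]],
                     cleavage_pos: int,
                     window: tuple[int, int] | None = None,
                     phase: int = PHASE,
                     n_cycles: int = DEFAULT_CYCLES,
                     include_antisense: bool = True) -> RegisterProfile:
    """Occupancy profile of reads downstream of a cleavage site.

    ``reads`` are (read, 1-based transcript start, strand) triples; strand
    is '+' or '-'. The window defaults to ``phase * n_cycles`` nt starting
    at cleavage_pos + 1. The phased fraction is the count share at cycle
    offset 0; it is None (flagged undefined) when no read falls in the
    window.
    """
    if window is None:
        window = (cleavage_pos + 1, cleavage_pos + phase * n_cycles)
    if window[0] <= cleavage_pos:
        raise DomainError("window must lie downstream of the cleavage site")
    offsets = [0] * phase
    registers: dict[int, int] = {}
    total = 0
    for read, start, strand in reads:
        if strand == "-":
            if not include_antisense:
                continue
            # map the antisense 5' end into the sense frame: the duplex
            # partner of a sense species starting at s starts (on the
            # antisense strand, in transcript coordinates) at s + len - 1
            # minus the 2-nt overhang; undo that shift before the modulus
            start = start - len(read.seq) + 1 + ANTISENSE_OFFSET
        if not window[0] <= start <= window[1]:
            continue
        cnt = read.total_count
        delta = start - cleavage_pos - 1
        off = delta % phase
        offsets[off] += cnt
        total += cnt
        if off == 0:
            k = 1 + delta // phase
            registers[k] = registers.get(k, 0) + cnt
    frac = offsets[0] / total if total > 0 else None
    return RegisterProfile(cleavage_pos=cleavage_pos, phase=phase,
                           offsets=offsets, registers=registers,
                           total=total, phased_fraction=frac)


def call_phased_locus(profile: RegisterProfile,
                      species: Sequence[str] = (),
                      threshold: float = PHASED_FRACTION_THRESHOLD) -> PhasedLocusCall:
    """Threshold the phased fraction into a locus-level call."""
    if not profile.defined:
        raise DomainError("no reads in window: phased fraction undefined")
    lo = profile.cleavage_pos + 1
    hi = profile.cleavage_pos + profile.phase * max(profile.registers, default=1)
    return PhasedLocusCall(
        locus=(lo, hi),
        phased_fraction=profile.phased_fraction,
        n_species=len(set(map(dna, species))),
        passes=profile.phased_fraction >= threshold,
    )


def extract_phased_species(transcript: SequenceRecord, cleavage_pos: int,
                           n_cycles: int, phase: int = PHASE) -> list[str]:
    """In-register 21-nt species from the 3' cleavage fragment.

    Cycle k is the substring starting at ``cleavage_pos + 1 + phase*(k-1)``.
    Duplicated cycles (repeat sequence) are removed preserving first
    occurrence, so the result counts sequence-distinct species.
    """
    needed = cleavage_pos + phase * n_cycles
    if needed > len(transcript.seq):
        feasible = (len(transcript.seq) - cleavage_pos) // phase
        raise DomainError(
            f"transcript {transcript.id} too short for {n_cycles} cycles; "
            f"last full cycle is {feasible}"
        )
    species: list[str] = []
    seen: set[str] = set()
    for k in range(n_cycles):
        start = cleavage_pos + phase * k  # 0-based index of cycle k+1
        sub = transcript.seq[start:start + phase]
        key = dna(sub)
        if key not in seen:
            seen.add(key)
            species.append(sub)
    return species


def detect_tas3_architecture(transcript: SequenceRecord, mir390: str,
                             max_score: float = 7.0,
                             max_bulges: int = 1) -> Tas3Architecture | None:
    """Recognize the dual miR390-site architecture of TAS3-like transcripts.

    Returns the 5'-most/3'-most site pair when at least two sites score at
    or under ``max_score``, flagging whether the 5' site carries a mismatch
    opposite miRNA position 10 (TAS3-1-like, non-cleavable 5' site) or not
    (TAS3-2-like). None when fewer than two sites exist.
    """
    sites = find_target_sites(mir390, transcript, max_score=max_score,
                              max_bulges=max_bulges)
    # overlapping alignment variants describe one physical site: cluster
    # them and keep each cluster's best-scoring alignment
    clusters: list[list[TargetAlignment]] = []
    for aln in sorted(sites, key=lambda a: a.site_interval[0]):
        if clusters and aln.site_interval[0] <= clusters[-1][-1].site_interval[1]:
            clusters[-1].append(aln)
        else:
            clusters.append([aln])
    reps = [min(c, key=lambda a: (a.score, a.site_interval[0])) for c in clusters]
    if len(reps) < 2:
        return None
    site5, site3 = reps[0], reps[-1]
    if site5.site_interval[1] >= site3.site_interval[0]:
        return None
    mismatch10 = any(
        mp == 10 and state in (MISMATCH, BULGE_MIRNA)
        for state, mp in zip(site5.states, site5.mirna_positions)
    )
    inter = (site5.site_interval[1] + 1, site3.site_interval[0] - 1)
    return Tas3Architecture(site5=site5, site3=site3,
                            site5_pos10_mismatch=mismatch10,
                            inter_site_region=inter)


def write_phasing_report(rows, path, n_registers: int = DEFAULT_CYCLES,
                         header_comment: str = "") -> None:
    """Phasing report TSV: one row per (transcript, cleavage anchor)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        reg_cols = "\t".join(f"register_{k}" for k in range(1, n_registers + 1))
        fh.write(
            "transcript\tcleavage_pos\ttotal_reads\tphased_fraction\t"
            f"n_species\t{reg_cols}\n"
        )
        for transcript_id, profile, n_species in rows:
            frac = (f"{profile.phased_fraction:.4f}"
                    if profile.defined else "NA")
            regs = "\t".join(
                str(profile.registers.get(k, 0)) for k in range(1, n_registers + 1)
            )
            fh.write(
                f"{transcript_id}\t{profile.cleavage_pos}\t{profile.total}\t"
                f"{frac}\t{n_species}\t{regs}\n"
            )
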