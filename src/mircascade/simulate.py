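"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates a four-tissue plant small-RNA study: skewed
tissue-biased read abundances over planted hairpin precursors (with
miRNA/miRNA* duplexes and controlled duplex defects), TAS3-like loci with
dual trigger sites, a MYB-like gene family sharing a conserved co-target
block (21-nt site + 12-nt spacer + 22-nt site = 55 nt) ahead of divergent
3' regions, degradome tags concentrated at true cleavage positions over a
uniform background, and planted secondary-target transcripts for the
siRNA cascade. Every random choice flows from one integer-seeded
generator, so a seed reproduces a byte-identical bundle.

The manifest records all planted truth (coordinates, sequences, species,
topology) and is sufficient to compute the expected output of every
pipeline stage (:func:`expected_outputs`).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hairpin import SecondaryStructure, write_structures
from .sequence_io import (
    DomainError,
    Library,
    SequenceRecord,
    SmallRNARead,
    dna,
    revcomp,
    write_fasta,
    write_library_sizes,
    write_read_table,
)
from .degradome import DegradomeTag, write_degradome_table

BASES = "ACGT"
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
#: substitutions that neither pair nor wobble with the given mature base
_NONPAIRING = {"A": "A", "T": "C", "G": "G", "C": "C"}

TISSUES = ("leaf", "root", "flower", "fruit")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study design.

    Defaults mirror the emulated study: four tissue libraries, hairpins
    half with and half without sequenced star strands, strongly
    duplex-concentrated hairpin reads, 21-nt phasing with a high in-phase
    signal fraction, and degradome tags dominated by the cleavage signal.
    """

    seed: int = 0
    tissues: tuple[str, ...] = TISSUES
    library_total_reads: int = 30_000

    # hairpin loci
    n_hairpins: int = 8
    n_hairpins_with_star: int = 4
    n_decoys: int = 8
    mature_length_range: tuple[int, int] = (20, 22)
    arm_pad: int = 8
    loop_length: int = 9
    planted_mismatches: int = 2
    planted_bulges: int = 0
    duplex_fraction: float = 0.9

    # TAS-like loci
    tas_phase: int = 21
    tas_cycles: int = 12
    tas_signal_fraction: float = 0.9

    # MYB-like family
    myb_family_size: int = 10
    myb_conserved_length: int = 99
    myb_conserved_mutation_rate: float = 0.02
    myb_divergent_cycles: int = 12

    # read model
    locus_abundance_mu: float = 6.0   # log-scale mean of per-locus weight
    locus_abundance_sigma: float = 1.0
    tissue_dirichlet_alpha: float = 0.5

    # degradome model
    degradome_tags_per_transcript: int = 200
    degradome_signal_fraction: float = 0.9
    degradome_background_positions: int = 30

    # cascade
    n_secondary_targets: int = 3
    n_decoy_targets: int = 4
    secondary_target_length: int = 240

    def validate(self) -> None:
        problems = []
        for name in ("duplex_fraction", "tas_signal_fraction",
                     "degradome_signal_fraction", "myb_conserved_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} outside [0, 1]")
        if self.n_hairpins_with_star > self.n_hairpins:
            problems.append("n_hairpins_with_star exceeds n_hairpins")
        if self.loop_length < 3:
            problems.append("loop_length must be >= 3")
        if self.planted_mismatches > 4:
            problems.append("planted_mismatches exceed the duplex criterion (4)")
        if self.planted_bulges > 1:
            problems.append("planted_bulges exceed the duplex criterion (1)")
        if problems:
            raise DomainError("infeasible config: " + "; ".join(problems))


@dataclass
class FixtureBundle:
    """In-memory fixture: sequences, reads, tags, structures, manifest."""

    config: SimulationConfig
    triggers: dict[str, str]
    transcriptome: list[SequenceRecord]
    precursors: list[SequenceRecord]
    structures: dict[str, SecondaryStructure]
    reads: list[SmallRNARead]
    libraries: list[Library]
    degradome_tags: list[DegradomeTag]
    manifest: dict


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _checksum(*parts: str) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Hairpin construction
# ---------------------------------------------------------------------------

def build_hairpin(rng: np.random.Generator, cfg: SimulationConfig,
                  name: str) -> dict:
    """One planted precursor: exact inverted repeat with controlled defects.

    Returns a manifest entry with precursor sequence, dot-bracket
    structure, mature and star intervals (1-based), and sequences. Defects
    (symmetric mismatches, star-side bulges) are planted away from the
    duplex anchor positions so the Dicer-overhang geometry stays exact.
    """
    lo, hi = cfg.mature_length_range
    m_len = int(rng.integers(lo, hi + 1))
    mature = _random_seq(rng, m_len)
    pad_a = _random_seq(rng, cfg.arm_pad)
    pad_b = _random_seq(rng, cfg.arm_pad)
    loop = _random_seq(rng, cfg.loop_length)
    arm5 = pad_a + mature + pad_b
    n5 = len(arm5)

    # 3' arm as mutable list, perfect reverse complement of the 5' arm;
    # pairing: arm5 index i (0-based) <-> arm3 index n5-1-i
    arm3 = [_COMP[c] for c in reversed(arm5)]
    paired5 = [True] * n5

    m_start0 = len(pad_a)             # 0-based mature start within arm5
    m_end0 = m_start0 + m_len - 1
    # interior positions eligible for defects: keep the duplex anchors
    # (mature start, mature end-2) and the 3' overhang region intact
    eligible = list(range(m_start0 + 2, m_end0 - 3))
    rng.shuffle(eligible)
    mm_pos = sorted(eligible[:cfg.planted_mismatches])
    for i in mm_pos:
        arm3[n5 - 1 - i] = _NONPAIRING[arm5[i]]
        paired5[i] = False

    bulge_after: list[int] = []
    if cfg.planted_bulges:
        pool = [i for i in eligible[cfg.planted_mismatches:] if i not in mm_pos]
        bulge_after = sorted(pool[:cfg.planted_bulges])

    precursor_5 = arm5 + loop
    # assemble the 3' arm, inserting unpaired bulge nucleotides
    arm3_seq = []
    pair_of_5 = {}  # 0-based arm5 index -> 0-based precursor index on arm3
    offset = len(precursor_5)
    k = 0
    for j in range(n5):
        i5 = n5 - 1 - j  # arm5 index this arm3 position complements
        arm3_seq.append(arm3[j])
        if paired5[i5]:
            pair_of_5[i5] = offset + k
        k += 1
        if i5 - 1 in bulge_after and i5 - 1 >= 0:
            arm3_seq.append(BASES[int(rng.integers(0, 4))])
            k += 1
    precursor = precursor_5 + "".join(arm3_seq)

    db = ["."] * len(precursor)
    for i5, i3 in pair_of_5.items():
        db[i5], db[i3] = "(", ")"
    structure = SecondaryStructure(seq=precursor, db="".join(db))

    mature_iv = (m_start0 + 1, m_end0 + 1)
    # star interval per Dicer geometry: partner(mature_end - 2) .. partner(mature_start) + 2
    star_start = pair_of_5[m_end0 - 2] + 1
    star_end = pair_of_5[m_start0] + 1 + 2
    star_iv = (star_start, star_end)
    return {
        "name": name,
        "precursor": precursor,
        "structure": structure.db,
        "mature": list(mature_iv),
        "mature_seq": mature,
        "star": list(star_iv),
        "star_seq": precursor[star_start - 1:star_end],
        "mismatches_planted": len(mm_pos),
        "bulges_planted": len(bulge_after),
    }


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig,
                     out_dir: str | Path | None = None) -> FixtureBundle:
    """Generate the full fixture bundle; optionally write it to ``out_dir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    triggers = {
        "miR390-like": _random_seq(rng, 21),
        "miR828-like": _random_seq(rng, 22),
        "miR858-like": _random_seq(rng, 21),
    }

    # -- hairpin and decoy loci ------------------------------------------------
    hairpins = []
    for h in range(cfg.n_hairpins):
        entry = build_hairpin(rng, cfg, f"hp{h + 1:02d}")
        entry["star_reads_planted"] = h < cfg.n_hairpins_with_star
        entry["expected_class"] = ("novel" if entry["star_reads_planted"]
                                   else "candidate")
        hairpins.append(entry)

    decoys = []
    for d in range(cfg.n_decoys):
        template = hairpins[d % len(hairpins)]
        seq = list(template["precursor"])
        rng.shuffle(seq)
        decoys.append({
            "name": f"decoy{d + 1:02d}",
            "precursor": "".join(seq),
            "mature": list(template["mature"]),
        })

    # -- TAS-like loci ---------------------------------------------------------
    phase = cfg.tas_phase
    tas_loci = []
    for tname, ttype, n_arf in (("TAS3-1-like", "TAS3-1", 2),
                                ("TAS3-2-like", "TAS3-2", 1),
                                ("TAS4-like", "TAS4", 1)):
        trig = triggers["miR390-like"] if ttype.startswith("TAS3") else triggers["miR828-like"]
        site = revcomp(trig)
        L = len(site)
        pad5 = _random_seq(rng, 30)
        inter = _random_seq(rng, phase * cfg.tas_cycles)
        site5 = site
        if ttype == "TAS3-1":
            # plant a mismatch opposite miRNA position 10 in the 5' site
            idx = L - 10  # 0-based site index paired with miRNA position 10
            site5 = site[:idx] + _NONPAIRING[dna(trig)[9]] + site[idx + 1:]
        pad3 = _random_seq(rng, 30)
        if ttype == "TAS4":
            seq = pad5 + site + inter + pad3
            site5_iv = None
            site3_iv = (len(pad5) + 1, len(pad5) + L)
            anchor_site_end = site3_iv[1]
        else:
            seq = pad5 + site5 + inter + site + pad3
            site5_iv = (len(pad5) + 1, len(pad5) + L)
            site3_iv = (len(pad5) + L + len(inter) + 1, len(pad5) + L + len(inter) + L)
            anchor_site_end = site5_iv[1]
        cleavage_pos = anchor_site_end - 9
        # plant tasiARF-like species at fixed registers inside the phased region
        arfs = []
        for a in range(n_arf):
            reg = 3 + a
            start0 = cleavage_pos + phase * (reg - 1)  # 0-based substring start
            arfs.append({"register": reg, "seq": seq[start0:start0 + phase]})
        tas_loci.append({
            "name": tname, "type": ttype, "seq": seq,
            "site5": list(site5_iv) if site5_iv else None,
            "site3": list(site3_iv),
            "pos10_mismatch": ttype == "TAS3-1",
            "cleavage_pos": cleavage_pos,
            "tasiarf": arfs,
            "signal_fraction": cfg.tas_signal_fraction,
        })

    # -- MYB-like family -------------------------------------------------------
    conserved = _random_seq(rng, cfg.myb_conserved_length)
    site858 = revcomp(triggers["miR858-like"])
    spacer = _random_seq(rng, 12)
    site828 = revcomp(triggers["miR828-like"])
    cotarget = site858 + spacer + site828  # 21 + 12 + 22 = 55 nt
    mybs = []
    for m in range(cfg.myb_family_size):
        cons = list(conserved)
        n_mut = rng.binomial(len(cons), cfg.myb_conserved_mutation_rate)
        for i in rng.choice(len(cons), size=n_mut, replace=False):
            cons[i] = BASES[int(rng.integers(0, 4))]
        divergent = _random_seq(rng, cfg.tas_phase * cfg.myb_divergent_cycles)
        seq = "".join(cons) + cotarget + divergent
        site828_start = cfg.myb_conserved_length + len(site858) + len(spacer) + 1
        site828_end = site828_start + len(site828) - 1
        cleavage_pos = site828_end - 9
        species = []
        for k in range(cfg.myb_divergent_cycles):
            start0 = cleavage_pos + cfg.tas_phase * k
            sub = seq[start0:start0 + cfg.tas_phase]
            if len(sub) == cfg.tas_phase:
                species.append(sub)
        mybs.append({
            "name": f"MYB{m + 1:02d}", "seq": seq,
            "site858": [cfg.myb_conserved_length + 1,
                        cfg.myb_conserved_length + len(site858)],
            "site828": [site828_start, site828_end],
            "cleavage_pos": cleavage_pos,
            "species": species,
            "signal_fraction": cfg.tas_signal_fraction,
        })

    # -- secondary-target and decoy-target transcripts -------------------------
    all_species = [s for m in mybs for s in m["species"]]
    picks = rng.choice(len(all_species), size=cfg.n_secondary_targets, replace=False)
    secondary_targets = []
    for t, pi in enumerate(sorted(int(x) for x in picks)):
        sp = all_species[pi]
        pad5 = _random_seq(rng, (cfg.secondary_target_length - phase) // 2)
        pad3 = _random_seq(rng, cfg.secondary_target_length - phase - len(pad5))
        seq = pad5 + revcomp(sp) + pad3
        site_iv = (len(pad5) + 1, len(pad5) + phase)
        secondary_targets.append({
            "name": f"TGT{t + 1:02d}", "seq": seq,
            "species": sp, "site": list(site_iv),
            "cleavage_pos": site_iv[1] - 9,
        })
    decoy_targets = [{"name": f"DTGT{d + 1:02d}",
                      "seq": _random_seq(rng, cfg.secondary_target_length)}
                     for d in range(cfg.n_decoy_targets)]

    # -- transcriptome and precursor records ----------------------------------
    transcriptome = (
        [SequenceRecord(t["name"], t["seq"], description="TAS-like locus")
         for t in tas_loci]
        + [SequenceRecord(m["name"], m["seq"], description="MYB-like transcript")
           for m in mybs]
        + [SequenceRecord(t["name"], t["seq"], description="planted secondary target")
           for t in secondary_targets]
        + [SequenceRecord(d["name"], d["seq"], description="decoy target")
           for d in decoy_targets]
    )
    precursors = (
        [SequenceRecord(h["name"], h["precursor"], description="planted hairpin")
         for h in hairpins]
        + [SequenceRecord(d["name"], d["precursor"], description="shuffled decoy locus")
           for d in decoys]
    )
    structures = {h["name"]: SecondaryStructure(h["precursor"], h["structure"])
                  for h in hairpins}

    # -- read model: weighted species pool, multinomial per library ------------
    # each locus gets a log-normal weight and a Dirichlet tissue profile;
    # within-locus shares implement the duplex / phasing signal fractions
    pool: list[tuple[str, np.ndarray]] = []   # (read seq, per-tissue weight)
    n_t = len(cfg.tissues)

    def add(seq: str, locus_w: float, share: float, tissue_w: np.ndarray) -> None:
        if 18 <= len(seq) <= 30:
            pool.append((seq, locus_w * share * tissue_w))

    def locus_weight() -> float:
        return float(rng.lognormal(cfg.locus_abundance_mu, cfg.locus_abundance_sigma))

    def tissue_weights() -> np.ndarray:
        return rng.dirichlet([cfg.tissue_dirichlet_alpha] * n_t)

    for h in hairpins:
        w, tw = locus_weight(), tissue_weights()
        s, e = h["mature"]
        if h["star_reads_planted"]:
            add(h["mature_seq"], w, cfg.duplex_fraction * 0.72, tw)
            add(h["star_seq"], w, cfg.duplex_fraction * 0.28, tw)
        else:
            add(h["mature_seq"], w, cfg.duplex_fraction, tw)
        # background: loop-region reads, off-duplex
        loop_lo = e + 1
        bg = h["precursor"][loop_lo + 2: loop_lo + 2 + 22]
        add(bg, w, 1.0 - cfg.duplex_fraction, tw)

    for d in decoys:
        w, tw = locus_weight(), tissue_weights()
        s, e = d["mature"]
        add(d["precursor"][s - 1:e], w, 0.85, tw)
        add(d["precursor"][e + 10:e + 31], w, 0.15, tw)

    def add_phased(seq: str, cleavage_pos: int, p: float,
                   w: float, tw: np.ndarray, n_cycles: int) -> None:
        starts = [cleavage_pos + phase * k for k in range(n_cycles)]
        starts = [s0 for s0 in starts if s0 + phase <= len(seq)]
        for s0 in starts:
            add(seq[s0:s0 + phase], w, p / len(starts), tw)
        # off-phase background, uniform over the same window
        n_bg = max(4, n_cycles)
        lo, hi = cleavage_pos + 1, max(cleavage_pos + 2, len(seq) - phase)
        offs = rng.integers(lo, hi, size=n_bg)
        offs = [int(o) for o in offs if (o - cleavage_pos - 1) % phase != 0]
        for o in offs:
            add(seq[o - 1:o - 1 + phase], w, (1.0 - p) / max(1, len(offs)), tw)

    for t in tas_loci:
        w, tw = locus_weight(), tissue_weights()
        add_phased(t["seq"], t["cleavage_pos"], t["signal_fraction"], w, tw,
                   cfg.tas_cycles)
    for m in mybs:
        w, tw = locus_weight(), tissue_weights()
        add_phased(m["seq"], m["cleavage_pos"], m["signal_fraction"], w, tw,
                   cfg.myb_divergent_cycles)

    # collapse identical sequences, then draw exact per-library totals
    agg: dict[str, np.ndarray] = {}
    for seq, wvec in pool:
        key = dna(seq)
        agg[key] = agg.get(key, np.zeros(n_t)) + wvec
    seqs = sorted(agg)
    weights = np.array([agg[s] for s in seqs])  # (n_reads, n_tissues)
    reads: list[SmallRNARead] = []
    counts_matrix = np.zeros_like(weights, dtype=np.int64)
    for j, tissue in enumerate(cfg.tissues):
        p = weights[:, j]
        p = p / p.sum()
        counts_matrix[:, j] = rng.multinomial(cfg.library_total_reads, p)
    for i, seq in enumerate(seqs):
        counts = {t: int(counts_matrix[i, j]) for j, t in enumerate(cfg.tissues)}
        if sum(counts.values()) > 0:
            reads.append(SmallRNARead(seq=seq, counts=counts))
    libraries = [Library(t, cfg.library_total_reads) for t in cfg.tissues]

    # -- degradome tags --------------------------------------------------------
    tags: list[DegradomeTag] = []
    cleaved = ([(t["name"], t["seq"], t["cleavage_pos"]) for t in tas_loci]
               + [(m["name"], m["seq"], m["cleavage_pos"]) for m in mybs]
               + [(t["name"], t["seq"], t["cleavage_pos"]) for t in secondary_targets])
    for name, seq, cpos in cleaved:
        n_tags = cfg.degradome_tags_per_transcript
        k_bg = min(cfg.degradome_background_positions, len(seq) - 1)
        positions = [cpos] + [int(p) for p in
                              rng.choice([p for p in range(1, len(seq) + 1) if p != cpos],
                                         size=k_bg, replace=False)]
        probs = np.array([cfg.degradome_signal_fraction]
                         + [(1 - cfg.degradome_signal_fraction) / k_bg] * k_bg)
        draw = rng.multinomial(n_tags, probs / probs.sum())
        for p, c in zip(positions, draw):
            if c > 0:
                tags.append(DegradomeTag(name, p, int(c)))
    total_tags = sum(t.count for t in tags)

    manifest = {
        "seed": cfg.seed,
        "triggers": triggers,
        "hairpins": hairpins,
        "decoys": [d["name"] for d in decoys],
        "tas_loci": [{k: v for k, v in t.items() if k != "seq"} for t in tas_loci],
        "myb_family": [{k: v for k, v in m.items() if k != "seq"} for m in mybs],
        "secondary_targets": [{k: v for k, v in t.items() if k != "seq"}
                              for t in secondary_targets],
        "decoy_targets": [d["name"] for d in decoy_targets],
        "degradome_total_tags": total_tags,
        "libraries": {l.name: l.total_matched for l in libraries},
        "checksum": _checksum(*(r.seq for r in transcriptome),
                              *(r.seq for r in precursors)),
    }

    bundle = FixtureBundle(config=cfg, triggers=triggers,
                           transcriptome=transcriptome,
                           precursors=precursors, structures=structures,
                           reads=reads, libraries=libraries,
                           degradome_tags=tags, manifest=manifest)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.transcriptome, out / "transcriptome.fasta")
    write_fasta(bundle.precursors, out / "precursors.fasta")
    write_fasta(
        [SequenceRecord(name, seq, description="trigger miRNA")
         for name, seq in bundle.triggers.items()],
        out / "triggers.fasta",
    )
    write_structures(bundle.structures, out / "structures.db.txt")
    write_read_table(bundle.reads, out / "reads.tsv")
    write_library_sizes(bundle.libraries, out / "libraries.tsv")
    write_degradome_table(bundle.degradome_tags, out / "degradome.tsv")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(bundle.manifest, fh, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(bundle.config), fh, sort_keys=True)


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def expected_outputs(manifest: dict, bundle: FixtureBundle | None = None) -> dict:
    """Deterministic per-stage expectations from planted truth.

    When the bundle is supplied its content checksum is verified against
    the manifest (mismatch raises a checksum error).
    """
    if bundle is not None:
        got = _checksum(*(r.seq for r in bundle.transcriptome),
                        *(r.seq for r in bundle.precursors))
        if got != manifest["checksum"]:
            raise DomainError("manifest/bundle checksum mismatch")
    expected_class = {h["name"]: h["expected_class"] for h in manifest["hairpins"]}
    cleavage = {t["name"]: t["cleavage_pos"] for t in manifest["tas_loci"]}
    cleavage.update({m["name"]: m["cleavage_pos"] for m in manifest["myb_family"]})
    species = sorted({dna(s) for m in manifest["myb_family"] for s in m["species"]})
    edges = sorted(
        (f"siR:{dna(t['species'])}", t["name"])
        for t in manifest["secondary_targets"]
    )
    return {
        "hairpin_classifications": expected_class,
        "decoy_names": list(manifest["decoys"]),
        "cleavage_positions": cleavage,
        "phased_fraction": {t["name"]: t["signal_fraction"]
                            for t in manifest["tas_loci"]},
        "secondary_species": species,
        "secondary_edges": edges,
        "tas3_pos10": {t["name"]: t["pos10_mismatch"]
                       for t in manifest["tas_loci"] if t["site5"] is not None},
    }
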