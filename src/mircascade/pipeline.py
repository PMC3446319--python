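"""End-to-end orchestration: reads -> hairpins -> targets -> degradome ->
phasing -> cascade, with reproducible per-stage reports.

Every output table carries a header comment with the package version, a
hash of the effective configuration, and the seed, so two runs with the
same inputs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path


from . import __version__
from .cascade import (
    DEFAULT_MAX_CATEGORY,
    SECONDARY_MAX_SCORE,
    assemble_network,
    cascade_edges,
    derive_secondary_species,
    write_edge_list,
    write_graphml,
)
from .degradome import (
    MAX_SCORE_KNOWN,
    build_tplot,
    read_degradome_table,
    validate_target,
    write_call_report,
)
from .hairpin import (
    HairpinLocus,
    annotate_candidates,
    read_structures,
)
from .phasing import DEFAULT_CYCLES, register_profile, write_phasing_report
from .sequence_io import (
    GenomeLocus,
    SmallRNARead,
    dna,
    normalize_reads,
    read_fasta,
    read_library_sizes,
    read_read_table,
    revcomp,
)
from .targets import find_target_sites, write_site_report

log = logging.getLogger("mircascade")


@dataclass
class PipelineConfig:
    """Thresholds of the analysis, all overridable from the CLI."""

    max_score_known: float = MAX_SCORE_KNOWN      # degradome, known miRNAs
    max_score_prediction: float = 5.0             # target prediction rule
    cascade_max_score: float = SECONDARY_MAX_SCORE
    cascade_max_category: int = DEFAULT_MAX_CATEGORY
    phase: int = 21
    n_cycles: int = DEFAULT_CYCLES
    duplex_fraction_shift: int = 2
    cascade_source_prefixes: tuple[str, ...] = ("MYB",)
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineRun:
    config: PipelineConfig
    outputs: dict[str, Path] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    exit_status: int = 0


def map_reads(reads, sequence: str):
    """All exact occurrences of each read (both strands) on a sequence.

    Returns (read, start, strand) triples; for '-' strand reads ``start``
    is the transcript coordinate of the read's 5' end (the highest
    coordinate of its span).
    """
    seq = dna(sequence)
    hits = []
    for read in reads:
        q = dna(read.seq)
        for query, strand in ((q, "+"), (revcomp(q), "-")):
            off = seq.find(query)
            while off >= 0:
                if strand == "+":
                    hits.append((read, off + 1, "+"))
                else:
                    hits.append((read, off + len(q), "-"))
                off = seq.find(query, off + 1)
    return hits


def run_pipeline(bundle_dir: str | Path, out_dir: str | Path,
                 config: PipelineConfig | None = None) -> PipelineRun:
    """Execute all stages on a fixture-bundle directory.

    Expects transcriptome.fasta, precursors.fasta, reads.tsv,
    libraries.tsv, degradome.tsv, triggers.fasta and optionally
    structures.db.txt and known.fasta in ``bundle_dir``. Each stage's
    report is written before the next begins; a stage failure aborts with
    the failing stage named and partial outputs retained.
    """
    cfg = config or PipelineConfig()
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(config=cfg)
    header = f"mircascade {__version__} config={cfg.digest()} seed={cfg.seed}"
    stage = "setup"

    def finish_stage(name: str, t0: float, n_records: int) -> None:
        run.log.append({"stage": name, "seconds": round(time.time() - t0, 3),
                        "records": n_records})
        log.info("stage %s: %d records", name, n_records)

    try:
        # ---- stage 1: sequence_io ------------------------------------------
        stage = "sequence_io"
        t0 = time.time()
        transcriptome = read_fasta(bundle / "transcriptome.fasta")
        precursors = read_fasta(bundle / "precursors.fasta")
        triggers = {r.id: r.seq for r in read_fasta(bundle / "triggers.fasta")}
        reads = read_read_table(bundle / "reads.tsv")
        libraries = read_library_sizes(bundle / "libraries.tsv")
        normalize_reads(reads, libraries)
        known = []
        if (bundle / "known.fasta").exists():
            known = [r.seq for r in read_fasta(bundle / "known.fasta")]
        structures = {}
        if (bundle / "structures.db.txt").exists():
            structures = read_structures(bundle / "structures.db.txt")
        finish_stage(stage, t0, len(reads))

        # ---- stage 2: hairpin annotation -----------------------------------
        stage = "hairpin_annotation"
        t0 = time.time()
        loci = []
        for prec in precursors:
            locus_reads = [(r, s) for r, s, strand in map_reads(reads, prec.seq)
                           if strand == "+"]
            # mature interval: the most abundant read at the locus
            if not locus_reads:
                continue
            top, top_start = max(locus_reads, key=lambda rs: rs[0].total_count)
            mature = (top_start, top_start + len(top.seq) - 1)
            loci.append(HairpinLocus(
                name=prec.id,
                locus=GenomeLocus(prec.id, 1, len(prec.seq)),
                precursor=prec.seq, mature=mature, locus_reads=locus_reads,
                structure=structures.get(prec.id),
            ))
        candidates = annotate_candidates(loci, known_mirnas=known,
                                         min_fraction_shift=cfg.duplex_fraction_shift)
        path = out / "candidates.tsv"
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            fh.write("locus\tmature_seq\tstar_seq\tmismatches\tbulges\t"
                     "duplex_fraction\tclassification\treason\n")
            for c in candidates:
                mm = c.duplex.mismatches if c.duplex else "NA"
                bl = c.duplex.bulges if c.duplex else "NA"
                frac = f"{c.duplex_fraction:.4f}" if c.duplex_fraction is not None else "NA"
                fh.write(f"{c.name}\t{c.mature_seq}\t{c.star_seq or 'NA'}\t"
                         f"{mm}\t{bl}\t{frac}\t{c.classification}\t{c.reason}\n")
        run.outputs["candidates"] = path
        finish_stage(stage, t0, len(candidates))

        # ---- stage 3: target scoring ---------------------------------------
        stage = "target_scoring"
        t0 = time.time()
        all_sites = []
        for name, seq in triggers.items():
            for transcript in transcriptome:
                for aln in find_target_sites(seq, transcript,
                                             max_score=cfg.max_score_prediction):
                    all_sites.append((name, aln))
        path = out / "sites.tsv"
        write_site_report([a for _, a in all_sites], path, header_comment=header)
        run.outputs["sites"] = path
        finish_stage(stage, t0, len(all_sites))

        # ---- stage 4: degradome validation ---------------------------------
        stage = "degradome"
        t0 = time.time()
        tags = read_degradome_table(bundle / "degradome.tsv")
        total_tags = sum(t.count for t in tags)
        tmap = {t.id: t for t in transcriptome}
        tplots = {tid: build_tplot([g for g in tags if g.transcript_id == tid],
                                   tmap[tid], total_tags)
                  for tid in sorted({g.transcript_id for g in tags})
                  if tid in tmap}
        calls = []   # (mirna_name, transcript_id, CleavageCall)
        for name, seq in triggers.items():
            for tid, tplot in tplots.items():
                for call in validate_target(seq, tmap[tid], tplot,
                                            max_score=cfg.max_score_known):
                    calls.append((name, tid, call))
        path = out / "degradome_calls.tsv"
        write_call_report(calls, path, header_comment=header)
        run.outputs["degradome_calls"] = path
        finish_stage(stage, t0, len(calls))

        # ---- stage 5: phasing ----------------------------------------------
        stage = "phasing"
        t0 = time.time()
        phasing_rows = []
        profiles = {}
        for name, tid, call in calls:
            mapped = map_reads(reads, tmap[tid].seq)
            mapped = [(r, s, st) for r, s, st in mapped if s > call.cleavage_pos]
            profile = register_profile(mapped, call.cleavage_pos,
                                       phase=cfg.phase, n_cycles=cfg.n_cycles)
            n_species = len({dna(r.seq) for r, s, st in mapped
                             if st == "+" and (s - call.cleavage_pos - 1) % cfg.phase == 0
                             and len(r.seq) == cfg.phase})
            profiles[(name, tid)] = profile
            phasing_rows.append((tid, profile, n_species))
        path = out / "phasing.tsv"
        write_phasing_report(phasing_rows, path, n_registers=cfg.n_cycles,
                             header_comment=header)
        run.outputs["phasing"] = path
        finish_stage(stage, t0, len(phasing_rows))

        # ---- stage 6: cascade ----------------------------------------------
        stage = "cascade_network"
        t0 = time.time()
        coding_calls = [
            (tid, call) for name, tid, call in calls
            if any(tid.startswith(p) for p in cfg.cascade_source_prefixes)
        ]
        species = derive_secondary_species(coding_calls, tmap,
                                           n_cycles=cfg.n_cycles,
                                           max_category=cfg.cascade_max_category)
        edges = cascade_edges(species, transcriptome,
                              max_score=cfg.cascade_max_score, tplots=tplots)
        primary = [(name, tid, call) for name, tid, call in calls
                   if call.category <= cfg.cascade_max_category
                   and any(tid.startswith(p) for p in cfg.cascade_source_prefixes)]
        network = assemble_network(
            {name: seq for name, seq in triggers.items()},
            primary, species, edges,
        )
        path = out / "cascade_edges.tsv"
        write_edge_list(network, path, header_comment=header)
        run.outputs["cascade_edges"] = path
        write_graphml(network, out / "cascade.graphml")
        run.outputs["cascade_graphml"] = out / "cascade.graphml"
        finish_stage(stage, t0, len(edges))

        # ---- summary -------------------------------------------------------
        by_class: dict[str, int] = {}
        for c in candidates:
            by_class[c.classification] = by_class.get(c.classification, 0) + 1
        by_cat: dict[str, int] = {}
        for _, _, call in calls:
            by_cat[str(call.category)] = by_cat.get(str(call.category), 0) + 1
        run.summary = {
            "version": __version__,
            "config": cfg.__dict__ | {"digest": cfg.digest()},
            "n_reads": len(reads),
            "classifications": by_class,
            "n_sites": len(all_sites),
            "degradome_categories": by_cat,
            "n_secondary_species": len(species),
            "n_cascade_edges": len(edges),
            "layers": network.layer_counts,
            # timings stay in run.log; the written summary is reproducible
            "stages": [{"stage": s["stage"], "records": s["records"]}
                       for s in run.log],
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(run.summary, fh, indent=2, default=str, sort_keys=True)
        run.outputs["summary"] = out / "summary.json"
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        run.exit_status = 1
        run.summary = {"failed_stage": stage, "error": str(exc)}
        log.error("pipeline aborted in stage %s: %s", stage, exc)
    return run
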