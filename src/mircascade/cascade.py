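"""Assembly of the miRNA -> transcript -> siRNA -> target cascade network.

A trigger miRNA cleaves coding transcripts (validated by degradome
category); the 3' fragments spawn phased 21-nt siRNA species; those
species are searched against the transcriptome at a stringent alignment
score and, where degradome evidence exists, their edges are upgraded to
degradome-validated. The result is a layered, acyclic regulatory network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .degradome import CleavageCall, TPlot, categorize, predicted_cleavage_site
from .phasing import DEFAULT_CYCLES, extract_phased_species
from .sequence_io import DomainError, SequenceRecord, dna
from .targets import find_target_sites

#: layers of the cascade, in topological order
LAYERS = ("trigger-miRNA", "primary-target", "secondary-siRNA", "secondary-target")

#: degradome categories admitted as validated primary cleavages
DEFAULT_MAX_CATEGORY = 3

#: stringent threshold for secondary-siRNA target search
SECONDARY_MAX_SCORE = 4.5


@dataclass
class SecondarySpecies:
    """A derived siRNA species with every (transcript, register) source."""

    seq: str
    sources: list[tuple[str, int]]


@dataclass
class RegulatoryEdge:
    source: str
    target: str
    score: float
    evidence: str  # "predicted" | "degradome-validated"
    category: int | None = None

    def __post_init__(self) -> None:
        if self.evidence == "degradome-validated" and self.category is None:
            raise DomainError("degradome-validated edge must carry a category")


@dataclass
class CascadeNetwork:
    graph: nx.DiGraph
    edges: list[RegulatoryEdge]

    @property
    def layer_counts(self) -> dict[str, int]:
        counts = {layer: 0 for layer in LAYERS}
        for _, data in self.graph.nodes(data=True):
            counts[data["layer"]] += 1
        return counts


def derive_secondary_species(calls: Sequence[tuple[str, CleavageCall]],
                             transcripts: Mapping[str, SequenceRecord],
                             n_cycles: int = DEFAULT_CYCLES,
                             max_category: int = DEFAULT_MAX_CATEGORY,
                             ) -> list[SecondarySpecies]:
    """Phased species from validated cleavages, deduplicated globally.

    ``calls`` are (transcript_id, call) pairs; calls above ``max_category``
    are skipped. Cycles running past a transcript end are truncated to the
    last full cycle (never padded). Identical species from different
    transcripts merge into one entry with all source annotations retained.
    """
    pooled: dict[str, SecondarySpecies] = {}
    for transcript_id, call in calls:
        if call.category > max_category:
            continue
        transcript = transcripts[transcript_id]
        feasible = (len(transcript.seq) - call.cleavage_pos) // 21
        cycles = min(n_cycles, feasible)
        if cycles < 1:
            continue
        species = extract_phased_species(transcript, call.cleavage_pos, cycles)
        for k, seq in enumerate(species, start=1):
            key = dna(seq)
            entry = pooled.setdefault(key, SecondarySpecies(seq=seq, sources=[]))
            entry.sources.append((transcript_id, k))
    return list(pooled.values())


def cascade_edges(species: Sequence[SecondarySpecies],
                  transcriptome: Sequence[SequenceRecord],
                  max_score: float = SECONDARY_MAX_SCORE,
                  tplots: Mapping[str, TPlot] | None = None,
                  max_bulges: int = 1) -> list[RegulatoryEdge]:
    """Target search for every secondary species against the transcriptome.

    Self-edges (a species hitting its own source transcript at its own
    locus) are excluded; alignment variants of the same (species, target)
    pair collapse to the best-scoring edge. When a T-plot is available for
    the target and the predicted cleavage position carries tags, the edge
    is upgraded to degradome-validated with its category.
    """
    best: dict[tuple[str, str], RegulatoryEdge] = {}
    for sp in species:
        source_ids = {t for t, _ in sp.sources}
        for transcript in transcriptome:
            for aln in find_target_sites(sp.seq, transcript, max_score=max_score,
                                         max_bulges=max_bulges):
                if transcript.id in source_ids:
                    # a phased species aligns perfectly to its own locus
                    site = dna(transcript.seq[aln.site_interval[0] - 1:
                                              aln.site_interval[1]])
                    from .sequence_io import revcomp
                    if dna(revcomp(sp.seq)) == site or dna(sp.seq) == site:
                        continue
                evidence, category = "predicted", None
                if tplots and transcript.id in tplots:
                    try:
                        pos = predicted_cleavage_site(aln)
                        cat = categorize(tplots[transcript.id], pos)
                    except DomainError:
                        cat = None
                    if cat is not None:
                        evidence, category = "degradome-validated", cat
                edge = RegulatoryEdge(
                    source=f"siR:{dna(sp.seq)}", target=transcript.id,
                    score=aln.score, evidence=evidence, category=category,
                )
                key = (edge.source, edge.target)
                if key not in best or edge.score < best[key].score:
                    best[key] = edge
    edges = sorted(best.values(), key=lambda e: (e.source, e.target, e.score))
    return edges


def assemble_network(trigger_mirnas: Mapping[str, str],
                     primary_calls: Sequence[tuple[str, str, CleavageCall]],
                     species: Sequence[SecondarySpecies],
                     secondary_edges: Sequence[RegulatoryEdge]) -> CascadeNetwork:
    """Build the layered cascade graph.

    ``trigger_mirnas`` maps miRNA name -> sequence; ``primary_calls`` are
    (mirna_name, transcript_id, call) triples. Every secondary edge's
    source species must be derivable from a primary call (orphans raise a
    consistency error). The graph is acyclic across layers by construction.
    """
    g = nx.DiGraph()
    edges: list[RegulatoryEdge] = []
    primary_targets = set()
    for name in trigger_mirnas:
        g.add_node(name, layer="trigger-miRNA")
    for mirna_name, transcript_id, call in primary_calls:
        g.add_node(transcript_id, layer="primary-target")
        primary_targets.add(transcript_id)
        edge = RegulatoryEdge(source=mirna_name, target=transcript_id,
                              score=call.alignment.score,
                              evidence="degradome-validated",
                              category=call.category)
        edges.append(edge)
        g.add_edge(mirna_name, transcript_id, **edge.__dict__)

    species_ids = {}
    for sp in species:
        node = f"siR:{dna(sp.seq)}"
        for transcript_id, _ in sp.sources:
            if transcript_id not in primary_targets:
                raise DomainError(
                    f"orphan secondary species {node}: source {transcript_id} "
                    "is not a validated primary target"
                )
        g.add_node(node, layer="secondary-siRNA")
        species_ids[node] = sp
        for transcript_id, register in sp.sources:
            g.add_edge(transcript_id, node, evidence="biogenesis",
                       register=register)

    for edge in secondary_edges:
        if edge.source not in species_ids:
            raise DomainError(f"orphan secondary edge source {edge.source}")
        if edge.target not in g or g.nodes[edge.target]["layer"] != "primary-target":
            g.add_node(edge.target, layer="secondary-target")
        g.add_edge(edge.source, edge.target, **edge.__dict__)
        edges.append(edge)

    return CascadeNetwork(graph=g, edges=edges)


def write_edge_list(network: CascadeNetwork, path, header_comment: str = "") -> None:
    """Edge list TSV: source, source_layer, target, score, evidence, category."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("source\tsource_layer\ttarget\tscore\tevidence\tcategory\n")
        for u, v, data in network.graph.edges(data=True):
            layer = network.graph.nodes[u]["layer"]
            score = data.get("score", "")
            score = f"{score:g}" if score != "" else ""
            cat = data.get("category")
            fh.write(
                f"{u}\t{layer}\t{v}\t{score}\t{data.get('evidence', '')}\t"
                f"{cat if cat is not None else 'NA'}\n"
            )


def write_graphml(network: CascadeNetwork, path) -> None:
    g = network.graph.copy()
    for _, _, data in g.edges(data=True):
        for k, v in list(data.items()):
            if v is None:
                data[k] = "NA"
    nx.write_graphml(g, path)
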