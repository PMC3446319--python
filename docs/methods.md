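# Methods

This note documents the models and procedures implemented in
`mircascade`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## Normalization and family grouping

Small-RNA abundances are reads per million (RPM) computed against each
library's total of perfectly reference-matched reads — not the raw
library total — so a fully matched library's RPM values sum to 10^6.
Degradome tags are transcripts per billion (TPB) of the library's total
tag count. Both are linear in the raw count for a fixed denominator.

Mature miRNAs are grouped into families by single-linkage clustering
under Hamming distance over their 5'-aligned sequences, with at most 2
mismatches and at most 2 nt length difference. Anchoring the comparison
at the 5' end reflects the positional constraint of mature miRNA 5' ends
(AGO loading and targeting both key on it); single linkage matches the
transitive sense in which miRNA "families" are named. All comparison is
done in DNA space (U→T); records keep their original alphabet.
Multi-mapping reads are counted fully at every locus they match.

## Hairpin screen

A precursor candidate passes five filters, in order: (1) matures within
2 mismatches of a known miRNA are set aside as homologs of known
families (ungapped sliding-window comparison, equivalent to a gapped
aligner at this mismatch radius for 20–22-nt queries and exactly
testable); (2) mature length 20–22 nt; (3) stem-loop/duplex criteria;
(4) the strict > 75 % duplex read-fraction rule; (5) candidates with a
sequenced star read are *novel*, the rest *candidate*. Rejected loci are
retained with machine-readable reason codes.

The star interval follows Dicer geometry: the star 5' end pairs mature
position `end − 2` and each duplex end carries a 2-nt 3' overhang;
unpaired anchor positions are bridged by projecting from the nearest
paired position. The duplex walk between mature and star (overhangs
excluded) counts opposite unpaired positions as mismatches and each
maximal single-sided unpaired run as one bulge; the criteria are ≤ 4
mismatches and ≤ 1 bulge. "Central bulge" is read as any asymmetric run
strictly inside the duplex, with no size cap — the annotation criteria
count bulges, not their lengths. The read-fraction rule tolerates ±2 nt
of start-position wobble around the mature and star starts, because
sequencing end-heterogeneity (isomiRs) is universal; the tolerance is a
parameter.

Structures may be supplied as dot-bracket files (the normal route when a
thermodynamic folder is available) or computed by the built-in baseline
folder, a Nussinov maximum-base-pairing dynamic program over
Watson–Crick and G:U pairs with a minimum hairpin loop of 3 nt and a
deterministic traceback (the 5' position pairs whenever pairing achieves
the optimum, smallest partner first). Maximum pairing is not a
free-energy model; it keeps the package self-contained and is exact and
oracle-testable. The pipeline records which structure source was used.

## Target search and scoring

The alignment score is the classic plant-miRNA penalty: mismatches and
single-nucleotide bulges or gaps cost 1, G:U wobbles 0.5, and penalties
at miRNA positions 2–13 are doubled. The doubling window follows the
scoring formula rather than the narrower "seed" narrative (positions
2–12) sometimes used descriptively; the window is exposed as a
parameter. G:U is evaluated on the DNA-mapped pair set {G:T, T:G} with
the strands read antiparallel. A bulge_target column (extra transcript
nucleotide) inherits the doubling decision of the adjacent 5'-ward miRNA
position.

The search is a small dynamic program anchored at each candidate site 3'
end (the nucleotide pairing miRNA position 1), allowing up to
`max_bulges` (default 1, per the single-nucleotide penalty definition)
non-terminal bulge columns on either strand, and pruning any partial
alignment already above the score ceiling. Overlapping sites with
identical score deduplicate to the 5'-most; output is ordered by
(score, position). The search is verified against exhaustive
window-by-window enumeration on hundreds of random instances.

Score bins follow the established convention: ≤ 5 cleavage-favorable,
5 < AS ≤ 7 less cleavage-favorable, > 7 cleavage-unfavorable.

## Degradome validation

Cleavage is assigned to the transcript position paired with miRNA
position 10 — the 5' end of the 3' cleavage fragment under slicer
geometry — located by walking the alignment columns so bulges shift the
coordinate correctly; a bulge at position 10 itself is an ambiguous
cleavage and yields no call. Categories are computed over positions with
non-zero abundance: 0 unique maximum (> 1 read), 1 tied maximum, 2
strictly between the median and maximum, 3 at or below the median, 4
exactly one read. The median over occupied positions only is the
established degradome-category convention and is consistent with the
definitions of categories 0 and 2 as "most abundant" and "above median,
below maximum"; categories 1, 3 and 4 are fixed accordingly. Categories
0–3 are invariant under rescaling all abundances; category 4 is
raw-count-defined. Default validation thresholds are AS ≤ 4.5 for known
miRNAs and ≤ 5 for novel/candidate miRNAs; alignment variants predicting
the same cleavage position collapse to the best-scoring one. An optional
±1-nt fallback window (off-by-one tag ends) is available but disabled by
default.

## Phasing

Register 1 begins at the first nucleotide of the 3' cleavage fragment
(`cleavage_pos + 1`); cycle offsets are `(start − cleavage_pos − 1) mod
21` and the phased fraction is the count share at offset 0. The analysis
window defaults to 21 × 12 nt (registers 1–12). Antisense reads, when
included, are mapped into the sense frame by undoing the canonical 2-nt
3' overhang of RDR6/DCL4 duplexes; whether antisense reads were included
is recorded in output metadata. No log-odds phasing statistic is
computed by default — the phased fraction with a configurable threshold
(default 0.5) is the primary statistic, which keeps the call criterion
transparent; an enrichment p-value would be a labelled extension.

TAS3-like architecture detection clusters overlapping alignment variants
of the trigger miRNA into physical sites, requires two non-overlapping
sites, and flags whether the 5' site carries a mismatch opposite miRNA
position 10 (the non-cleavable 5' site of the long TAS3 subtype) or not
(the short subtype).

## Cascade network

Validated cleavage calls (degradome category ≤ 3 by default) on coding
transcripts seed phased-species extraction over 12 cycles; species are
deduplicated globally by sequence with all (transcript, register)
sources retained, and species truncated at transcript ends are dropped,
never padded. Each species is searched against the transcriptome at a
stringent AS ≤ 4.5; self-hits at the species' own locus are excluded,
and edges gain degradome validation (with a category) when a T-plot
covers the predicted cleavage position. The assembled network is layered
trigger-miRNA → primary-target → secondary-siRNA → secondary-target and
acyclic across layers by construction; orphan species (not traceable to
a validated primary cleavage) are a consistency error.

## Conservation utilities

Consensus is the most frequent non-gap residue per column, ties broken
alphabetically and flagged. Conservation per column is
`log2(alphabet) − H` bits with no small-sample correction (the choice is
recorded in output metadata). Columns with > 50 % gaps are masked in
logo output. MYB family members are collected by bounded-mismatch
scanning with the 18-residue co-target signature peptide (default 6
mismatches); a deterministic, database-free stand-in for a permissive
similarity search, with the bound exposed as a parameter.

## Synthetic data generator

The generator emulates a four-tissue plant small-RNA study: per-locus
abundances are log-normal (μ = 6, σ = 1 on the log scale) with
Dirichlet(0.5) tissue weights to produce the strong tissue bias typical
of miRNA expression; per-library read totals are drawn as one
multinomial per library over the weighted species pool, so column totals
match the configured library size exactly. Hairpins are exact inverted
repeats with planted duplex defects (defaults: 2 mismatches, 0 bulges,
planted away from the duplex anchors so the overhang geometry stays
exact); half the hairpins receive star reads (novel), half do not
(candidate); decoys are per-locus shuffles of real precursors. The
mature/star duplex carries 90 % of each hairpin locus's reads, safely
above the 75 % rule; phased loci place 90 % of their reads in-phase over
registers 1–12; degradome tags put 90 % of 200 tags per transcript at
the true cleavage position over a uniform 30-position background, the
simplest defensible background model. The MYB-like family (10 members)
shares a conserved block containing the 21-nt + 12-nt + 22-nt co-target
geometry ahead of member-specific divergent regions sized for exactly 12
phased cycles, giving 120 sequence-distinct species; three species get
planted perfect-complement target transcripts and four random decoy
transcripts provide the score separation for the cascade test. Trigger
sequences are generated per seed rather than copied from any database;
the manifest records every planted coordinate, sequence and edge, and a
content checksum ties a manifest to its bundle.

What the generator does **not** emulate: sequencing errors and quality
scores, adapter artifacts, multi-locus repeat families, RNA secondary
structure of non-hairpin loci, realistic transcriptome composition, or
thermodynamically folded precursors. Passing the suite therefore shows
the algorithms are correct on data satisfying the model's assumptions —
planted truth is recovered exactly and decoys rejected — not that the
thresholds are optimal for any particular real library. For the TAS
fixtures the register frame is anchored at the 5' trigger site for both
TAS3 subtypes so that all registers fall inside the inter-site region;
this is a fixture simplification (in the long subtype the 3' site sets
the phase in vivo) and is recorded in the manifest.

## Numerical and design choices

* All scores are non-negative half-integers; comparisons are exact, no
  floating tolerances are needed in scoring.
* Deterministic orderings everywhere: families by representative
  abundance then sequence; sites by (score, position); calls by
  (category, −TPB); edges lexicographically. Reruns are bit-identical
  and every output table carries the package version, a config hash and
  the seed in a header comment.
* Degenerate inputs are values, not crashes: an empty phasing window is
  "undefined, flagged", a tag-free position is "no call", a locus whose
  inferred star degenerates is rejected with a reason code. Malformed
  files raise parse errors naming the file and line, and the pipeline
  aborts naming the failing stage while retaining partial outputs.
* Problem sizes in the shipped tests and acceptance script (8 + 8
  hairpin/decoy loci, 3 TAS-like loci, 10 MYB members, 30 000 reads per
  library, 200 random search-oracle instances, 1 000 random T-plots, 50
  phasing replicates per signal level) were chosen so the whole suite
  exercises every stage at comfortable desk scale.

## Known limitations

* The baseline folder maximizes pairing, not free energy; externally
  computed dot-bracket structures should be preferred for real data.
* Read-to-locus assignment is exact substring matching — sufficient for
  synthetic scale, not a genome-scale mapper.
* The hairpin screen takes the most abundant locus read as the mature
  candidate; loci whose true mature is not the top read would need the
  mature supplied explicitly.
* No translational-repression prediction, target-site accessibility or
  energy modelling; no genome-wide de-novo PHAS scan without a cleavage
  anchor; no GO enrichment of network targets.
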