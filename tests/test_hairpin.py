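import numpy as np
import pytest

from oracles import max_pairs_bruteforce

from mircascade.hairpin import (
    HairpinLocus,
    LoopSpanningError,
    SecondaryStructure,
    annotate_candidates,
    duplex_read_fraction,
    evaluate_duplex,
    fold_baseline,
    infer_star,
    matches_known,
)
from mircascade.sequence_io import DomainError, GenomeLocus, SmallRNARead
from mircascade.simulate import SimulationConfig, build_hairpin


def perfect_hairpin(mature="ACGTACGTACGTACGTACGTA", pad=5, loop=9):
    """An exact inverted-repeat precursor with the mature on the 5' arm."""
    cfg = SimulationConfig(planted_mismatches=0, planted_bulges=0,
                           arm_pad=pad, loop_length=loop)
    rng = np.random.default_rng(11)
    return build_hairpin(rng, cfg, "hp")


class TestFoldBaseline:
    def test_simple_stem(self):
        assert fold_baseline("GGGAAAACCC").db == "(((....)))"

    def test_no_complementarity_leaves_all_unpaired(self):
        assert fold_baseline("AAAAAAAA").db == "........"

    def test_non_nucleotide_rejected(self):
        with pytest.raises(DomainError):
            fold_baseline("ACGTQACGTA")

    def test_matches_exhaustive_enumeration_on_short_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(8, 15))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            st = fold_baseline(seq)
            assert st.db.count("(") == max_pairs_bruteforce(seq)

    def test_output_is_balanced_and_nested(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            SecondaryStructure(seq, fold_baseline(seq).db)  # validates


class TestStructureValidation:
    @pytest.mark.parametrize("db", ["(()", "())", "(.x)"])
    def test_invalid_dotbracket_rejected(self, db):
        with pytest.raises(DomainError):
            SecondaryStructure("A" * len(db), db)


class TestInferStar:
    def test_recovers_planted_star_interval(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            hp = build_hairpin(rng, SimulationConfig(planted_mismatches=2), "h")
            st = SecondaryStructure(hp["precursor"], hp["structure"])
            star = infer_star(st, tuple(hp["mature"]))
            assert list(star) == hp["star"]

    def test_perfect_duplex_star_has_two_nt_offset(self):
        hp = perfect_hairpin()
        st = SecondaryStructure(hp["precursor"], hp["structure"])
        s, e = hp["mature"]
        star = infer_star(st, (s, e))
        # star 5' end pairs mature position e-2, star 3' end overhangs by 2
        assert st.partner(e - 2) == star[0]
        assert st.partner(s) + 2 == star[1]

    def test_loop_spanning_mature_rejected(self):
        hp = perfect_hairpin()
        st = SecondaryStructure(hp["precursor"], hp["structure"])
        n5 = len(hp["precursor"]) // 2
        with pytest.raises(LoopSpanningError):
            infer_star(st, (n5 - 10, n5 + 10))


class TestEvaluateDuplex:
    def test_fully_paired_duplex_passes_clean(self):
        hp = perfect_hairpin()
        st = SecondaryStructure(hp["precursor"], hp["structure"])
        ev = evaluate_duplex(st, tuple(hp["mature"]), tuple(hp["star"]))
        assert (ev.mismatches, ev.bulges, ev.passes) == (0, 0, True)

    @pytest.mark.parametrize("n_mm,expect_pass", [(2, True), (4, True)])
    def test_planted_mismatches_counted(self, n_mm, expect_pass):
        rng = np.random.default_rng(5)
        hp = build_hairpin(rng, SimulationConfig(planted_mismatches=n_mm), "h")
        st = SecondaryStructure(hp["precursor"], hp["structure"])
        ev = evaluate_duplex(st, tuple(hp["mature"]), tuple(hp["star"]))
        assert ev.mismatches == n_mm
        assert ev.passes is expect_pass

    def test_five_mismatches_fail(self):
        # mature of 22 nt gives enough defect-eligible interior positions
        rng = np.random.default_rng(6)
        cfg = SimulationConfig(planted_mismatches=4, mature_length_range=(22, 22))
        hp = build_hairpin(rng, cfg, "h")
        st = SecondaryStructure(hp["precursor"], hp["structure"])
        # knock out one more pair symmetrically -> 5th mismatch
        pos = next(p for p in range(hp["mature"][0] + 2, hp["mature"][1] - 3)
                   if st.partner(p))
        db = list(st.db)
        db[pos - 1] = "."
        db[st.partner(pos) - 1] = "."
        ev = evaluate_duplex(SecondaryStructure(st.seq, "".join(db)),
                             tuple(hp["mature"]), tuple(hp["star"]))
        assert ev.mismatches == 5
        assert not ev.passes

    def test_single_planted_bulge_passes_two_fail(self):
        rng = np.random.default_rng(7)
        hp = build_hairpin(rng, SimulationConfig(planted_mismatches=0,
                                                 planted_bulges=1), "h")
        st = SecondaryStructure(hp["precursor"], hp["structure"])
        ev = evaluate_duplex(st, tuple(hp["mature"]), tuple(hp["star"]))
        assert ev.bulges == 1 and ev.passes
        # breaking one more pair asymmetrically adds runs on both sides
        pos = next(p for p in range(hp["mature"][0] + 2, hp["mature"][1] - 3)
                   if st.partner(p))
        db = list(st.db)
        db[pos - 1] = "."
        db[st.partner(pos) - 1] = "."
        ev2 = evaluate_duplex(SecondaryStructure(st.seq, "".join(db)),
                              tuple(hp["mature"]), tuple(hp["star"]))
        assert ev2.bulges + ev2.mismatches > ev.bulges

    def test_symmetric_in_mature_and_star(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            hp = build_hairpin(rng, SimulationConfig(planted_mismatches=2,
                                                     planted_bulges=1), "h")
            st = SecondaryStructure(hp["precursor"], hp["structure"])
            a = evaluate_duplex(st, tuple(hp["mature"]), tuple(hp["star"]))
            b = evaluate_duplex(st, tuple(hp["star"]), tuple(hp["mature"]))
            assert (a.mismatches, a.bulges) == (b.mismatches, b.bulges)


class TestDuplexReadFraction:
    def _read(self, seq, n):
        return SmallRNARead(seq, {"leaf": n})

    def test_strict_three_quarters_rule(self):
        mature, star = (10, 30), (40, 60)
        dup = self._read("A" * 21, 75)
        bg = self._read("C" * 21, 25)
        frac, ok = duplex_read_fraction([(dup, 10), (bg, 33)], mature, star)
        assert frac == 0.75 and not ok  # "more than 75%" is strict
        frac, ok = duplex_read_fraction(
            [(self._read("A" * 21, 80), 10), (self._read("C" * 21, 20), 33)],
            mature, star)
        assert frac == 0.80 and ok

    def test_all_reads_on_mature(self):
        frac, ok = duplex_read_fraction([(self._read("A" * 21, 5), 10)],
                                        (10, 30), (40, 60))
        assert frac == 1.0 and ok

    def test_empty_locus_rejected(self):
        with pytest.raises(DomainError):
            duplex_read_fraction([], (10, 30), (40, 60))


class TestAnnotation:
    def test_known_homolog_excluded_at_two_mismatches(self):
        known = ["ACAGGGAAGAGGTAGAGCATG"]
        near = "ACAGGGAAGAGGTAGAGCAAA"   # 2 mismatches
        far = "ACAGGGAAGAGGTAGAGTTTT"    # 4 mismatches
        assert matches_known(near, known)
        assert not matches_known(far, known)

    def test_planted_hairpins_classified_by_star_reads(self, default_bundle):
        bundle, _ = default_bundle
        from mircascade.pipeline import map_reads
        results = {}
        for h in bundle.manifest["hairpins"]:
            prec = next(p for p in bundle.precursors if p.id == h["name"])
            locus_reads = [(r, s) for r, s, strand
                           in map_reads(bundle.reads, prec.seq) if strand == "+"]
            locus = HairpinLocus(
                name=h["name"], locus=GenomeLocus(h["name"], 1, len(prec.seq)),
                precursor=prec.seq, mature=tuple(h["mature"]),
                locus_reads=locus_reads,
                structure=bundle.structures[h["name"]],
            )
            cand = annotate_candidates([locus])[0]
            results[h["name"]] = cand.classification
        expected = {h["name"]: h["expected_class"]
                    for h in bundle.manifest["hairpins"]}
        assert results == expected
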