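import numpy as np
import pytest

from mircascade.phasing import (
    assign_register,
    call_phased_locus,
    detect_tas3_architecture,
    extract_phased_species,
    register_profile,
)
from mircascade.sequence_io import DomainError, SequenceRecord, SmallRNARead


def read(seq="A" * 21, n=1):
    return SmallRNARead(seq, {"leaf": n})


class TestAssignRegister:
    @pytest.mark.parametrize("start,offset,register", [
        (101, 0, 1),    # first nucleotide of the 3' fragment
        (122, 0, 2),
        (332, 0, 12),   # 101 + 21 * 11
        (105, 4, None),
    ])
    def test_cycle_arithmetic(self, start, offset, register):
        assert assign_register(start, cleavage_pos=100) == (offset, register)

    def test_upstream_read_rejected(self):
        with pytest.raises(DomainError):
            assign_register(100, cleavage_pos=100)

    def test_shifting_one_phase_increments_register(self):
        for start in (101, 122, 143):
            _, r1 = assign_register(start, 100)
            _, r2 = assign_register(start + 21, 100)
            assert r2 == r1 + 1


class TestRegisterProfile:
    def test_all_in_phase_reads_give_unit_fraction(self):
        reads = [(read(), 101 + 21 * k, "+") for k in range(5)]
        prof = register_profile(reads, cleavage_pos=100)
        assert prof.phased_fraction == 1.0
        assert prof.registers == {k + 1: 1 for k in range(5)}

    def test_uniform_background_near_one_in_twentyone(self):
        rng = np.random.default_rng(37)
        n = 10_000
        starts = rng.integers(101, 101 + 21 * 12, size=n)
        reads = [(read(n=1), int(s), "+") for s in starts]
        prof = register_profile(reads, cleavage_pos=100)
        p = 1 / 21
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(prof.phased_fraction - p) < 3 * sigma

    def test_empty_window_flagged_undefined(self):
        prof = register_profile([], cleavage_pos=100)
        assert not prof.defined
        with pytest.raises(DomainError):
            call_phased_locus(prof)

    def test_translation_invariance(self):
        rng = np.random.default_rng(41)
        starts = [int(s) for s in rng.integers(101, 300, size=200)]
        a = register_profile([(read(), s, "+") for s in starts], 100)
        b = register_profile([(read(), s + 57, "+") for s in starts], 157)
        assert a.offsets == b.offsets

    def test_antisense_reads_fold_into_sense_frame(self):
        # the antisense partner of a sense species starting at s has its
        # 5' end at s + 20 - 2 (2-nt duplex overhang)
        s = 101 + 21 * 2
        sense = [(read(), s, "+")]
        anti = [(read(), s + 20 - 2, "-")]
        pa = register_profile(sense, 100)
        pb = register_profile(anti, 100)
        assert pa.offsets == pb.offsets

    def test_signal_fraction_recovered_within_binomial_error(self):
        rng = np.random.default_rng(43)
        for p in (0.3, 0.6, 0.9):
            hits = 0
            reps = 30
            n = 2_000
            for _ in range(reps):
                in_phase = rng.binomial(n, p)
                starts = [101 + 21 * int(k) for k in rng.integers(0, 12, in_phase)]
                bg = 0
                while bg < n - in_phase:
                    s = int(rng.integers(101, 101 + 21 * 12))
                    if (s - 101) % 21 != 0:
                        starts.append(s)
                        bg += 1
                prof = register_profile([(read(), s, "+") for s in starts], 100)
                sigma = np.sqrt(p * (1 - p) / n)
                hits += abs(prof.phased_fraction - p) < 3 * sigma
            assert hits >= 0.9 * reps


class TestExtractSpecies:
    def test_species_start_in_register(self):
        seq = "".join("ACGT"[i % 4] * 1 for i in range(200))
        t = SequenceRecord("t", "A" * 200)
        t = SequenceRecord("t", seq)
        species = extract_phased_species(t, cleavage_pos=10, n_cycles=3)
        assert species == [seq[10:31], seq[31:52], seq[52:73]]

    def test_repeat_cycles_deduplicated(self):
        t = SequenceRecord("t", "C" * 10 + "ACGTACGTACGTACGTACGTA" * 2 + "C" * 10)
        species = extract_phased_species(t, cleavage_pos=10, n_cycles=2)
        assert len(species) == 1

    def test_overrun_names_last_full_cycle(self):
        t = SequenceRecord("t", "A" * 60)
        with pytest.raises(DomainError, match="last full cycle is 2"):
            extract_phased_species(t, cleavage_pos=10, n_cycles=5)


class TestTas3Architecture:
    def test_planted_dual_site_architectures(self, default_bundle):
        bundle, _ = default_bundle
        mir390 = bundle.triggers["miR390-like"]
        tmap = {t.id: t for t in bundle.transcriptome}
        for entry in bundle.manifest["tas_loci"]:
            if entry["site5"] is None:
                continue
            arch = detect_tas3_architecture(tmap[entry["name"]], mir390,
                                            max_score=7.0)
            assert arch is not None, entry["name"]
            assert arch.site5_pos10_mismatch == entry["pos10_mismatch"]
            assert list(arch.site5.site_interval) == entry["site5"]
            assert list(arch.site3.site_interval) == entry["site3"]

    def test_single_site_returns_none(self, default_bundle):
        bundle, _ = default_bundle
        mir390 = bundle.triggers["miR390-like"]
        from mircascade.sequence_io import revcomp
        t = SequenceRecord("one", "C" * 40 + revcomp(mir390) + "C" * 40)
        assert detect_tas3_architecture(t, mir390, max_score=3.0) is None
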