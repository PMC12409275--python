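"""The masking pipeline: sampling, the uniqueness test, lenient and strict sets."""

import numpy as np
import pytest

from conftest import clone_pangenome, make_genome, mutate, random_dna
from panmask import (
    GenomeSequence,
    HammingFilterParams,
    HitIndex,
    IntervalSet,
    PangenomeSet,
    RegionFilterParams,
    SdustParams,
    UniquenessParams,
    compute_mask,
    intersect,
    is_sufficiently_unique,
    lenient_regions,
    strict_regions,
    subtract,
)


class TestSamplePositions:
    def test_stride_plus_forced_final(self):
        from panmask import sample_positions

        assert sample_positions(20, 5, 10) == [0, 10, 15]
        assert sample_positions(151, 151, 10) == [0]
        assert sample_positions(30, 5, 1) == list(range(26))

    def test_too_short_sequence_gives_no_positions(self):
        from panmask import sample_positions

        assert sample_positions(10, 31, 5) == []


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            UniquenessParams(d1=3, d2=3)
        with pytest.raises(ValueError):
            UniquenessParams(c=1.0)
        with pytest.raises(ValueError):
            UniquenessParams(k=10, w=11)
        with pytest.raises(ValueError):
            RegionFilterParams(min_region_len=0)


def _pg_with_extra_copies(rng, n_extra, n_genomes=10, klen=31):
    """Clone panel plus ``n_extra`` lightly mutated copies of one locus,
    spread over distinct haplotypes, appended at their ends."""
    bases = random_dna(rng, 3000)
    q = bases[1000 : 1000 + klen]
    ref = GenomeSequence("ref", "chr1", bases)
    others = []
    for i in range(n_genomes - 1):
        hb = bases
        if i < n_extra:
            hb = hb + random_dna(rng, 40) + mutate(rng, q, 1) + random_dna(rng, 40)
        others.append((GenomeSequence(f"hap{i+1}", "chr1", hb),))
    return PangenomeSet((ref,), tuple(others)), 1000


class TestSufficientUniqueness:
    def test_copy_gain_threshold_arithmetic(self, rng):
        # N=10, c=1.01 -> threshold 10.1: 10 pangenome hits pass, 11 fail
        p = UniquenessParams(k=31, w=5, c=1.01, d1=1, d2=3)
        pg10, pos = _pg_with_extra_copies(rng, 0)
        assert is_sufficiently_unique(pos, pg10.reference[0], pg10, p)
        pg11, pos = _pg_with_extra_copies(rng, 1)
        assert not is_sufficiently_unique(pos, pg11.reference[0], pg11, p)

    def test_reference_duplication_fails_condition_one(self, rng):
        bases = random_dna(rng, 2000)
        dup = bases[500:531]
        ref_bases = bases + random_dna(rng, 50) + dup  # second exact ref copy
        pg = clone_pangenome(ref_bases, 4)
        p = UniquenessParams(k=31, w=5, c=2.0, d1=1, d2=3)
        # high c so condition (ii) cannot be the reason
        assert not is_sufficiently_unique(500, pg.reference[0], pg, p)

    def test_kmer_containing_n_is_never_unique(self, rng):
        bases = random_dna(rng, 500) + "N" + random_dna(rng, 500)
        pg = clone_pangenome(bases, 1)
        p = UniquenessParams(k=31, w=5, c=1.01, d1=1, d2=3)
        assert not is_sufficiently_unique(480, pg.reference[0], pg, p)


class TestComputeMask:
    P = UniquenessParams(k=31, w=5, c=1.01, d1=1, d2=3)

    def test_repeat_free_single_genome_unmasked(self, rng):
        pg = clone_pangenome(random_dna(rng, 2000), 0)
        assert compute_mask(pg, self.P) == IntervalSet()

    def test_tandem_duplication_masks_both_copies(self, rng):
        seg = random_dna(rng, 300)
        bases = random_dna(rng, 700) + seg + seg + random_dna(rng, 700)
        pg = clone_pangenome(bases, 0)
        mask = compute_mask(pg, self.P)
        # every k-mer inside either copy has two reference hits; interiors
        # are fully covered, boundaries depend on sampling phase
        interior = IntervalSet({"chr1": [(715, 1285)]})
        assert intersect(mask, interior).total_length == interior.total_length
        # nothing masked far away from the duplication
        assert intersect(mask, IntervalSet({"chr1": [(0, 600)]})).total_length == 0

    def test_n_run_masked(self, rng):
        bases = random_dna(rng, 800) + "N" * 151 + random_dna(rng, 800)
        pg = clone_pangenome(bases, 0)
        mask = compute_mask(pg, self.P)
        assert intersect(mask, IntervalSet({"chr1": [(800, 951)]})).total_length == 151

    def test_sequence_shorter_than_k_wholly_masked(self):
        pg = clone_pangenome("ACGTACGTAC", 0)
        mask = compute_mask(pg, UniquenessParams(k=31, w=5, c=1.01, d1=1, d2=3))
        assert mask == IntervalSet({"chr1": [(0, 10)]})

    def test_agrees_with_single_kmer_api(self, rng):
        # every sampled k-mer failing the per-k-mer test has its window
        # fully masked
        pg, _ = _pg_with_extra_copies(rng, 1)
        mask = compute_mask(pg, self.P)
        index = HitIndex(pg)
        ref = pg.reference[0]
        failures = 0
        for pos in range(0, 2970, 25):  # a subsample of the w=5 grid
            if not is_sufficiently_unique(pos, ref, pg, self.P, index=index):
                failures += 1
                covered = intersect(
                    mask, IntervalSet({"chr1": [(pos, pos + 31)]})
                ).total_length
                assert covered == 31
        # the planted extra copy makes at least the source k-mers fail
        assert failures >= 1


class TestLenientRegions:
    def test_repeat_free_reference_is_one_interval(self, rng):
        pg = clone_pangenome(random_dna(rng, 2000), 0)
        p = UniquenessParams(k=31, w=5, c=1.01, d1=1, d2=3)
        got = lenient_regions(pg, p, HammingFilterParams(k=31, max_mismatch=3))
        assert got == IntervalSet({"chr1": [(0, 2000)]})

    def test_hamming_rescue_drops_pair_missed_by_edit_conditions(self, rng):
        # with d1=0 the 2-mismatch twin is invisible to condition (i), and
        # d2=1 keeps it outside condition (ii); the exact Hamming filter at
        # 3 mismatches still drops both copies
        q = random_dna(rng, 31)
        twin = mutate(rng, q, 2)
        bases = random_dna(rng, 600) + q + random_dna(rng, 600) + twin + random_dna(rng, 600)
        pg = clone_pangenome(bases, 0)
        p = UniquenessParams(k=31, w=5, c=1.01, d1=0, d2=1)
        mask = compute_mask(pg, p)
        q_start = 600
        assert intersect(mask, IntervalSet({"chr1": [(q_start, q_start + 31)]})).total_length == 0
        lenient = lenient_regions(pg, p, HammingFilterParams(k=31, max_mismatch=3))
        assert intersect(lenient, IntervalSet({"chr1": [(q_start, q_start + 31)]})).total_length == 0

    def test_minimum_length_filter_applied(self, rng):
        pg = clone_pangenome(random_dna(rng, 2000), 0)
        p = UniquenessParams(k=31, w=5, c=1.01, d1=1, d2=3)
        got = lenient_regions(pg, p, f=RegionFilterParams(min_region_len=50))
        for _, ivs in got.items():
            for s, e in ivs:
                assert e - s >= 50


class TestStrictRegions:
    def test_long_homopolymer_subtracted_flanks_kept(self, rng):
        left, right = random_dna(rng, 200), random_dna(rng, 200)
        bases = left + "A" * 30 + right
        ref = [make_genome(bases)]
        lenient = IntervalSet({"chr1": [(0, len(bases))]})
        got = strict_regions(lenient, ref)
        assert intersect(got, IntervalSet({"chr1": [(200, 230)]})).total_length == 0
        assert got.total_length >= 380

    def test_short_lcr_tolerated(self, rng):
        bases = random_dna(rng, 120) + "A" * 15 + random_dna(rng, 120)
        lenient = IntervalSet({"chr1": [(0, len(bases))]})
        got = strict_regions(lenient, [make_genome(bases)])
        assert got == lenient

    def test_empty_lenient_gives_empty_strict(self, rng):
        got = strict_regions(IntervalSet(), [make_genome(random_dna(rng, 500))])
        assert got == IntervalSet()

    def test_always_subset_of_lenient(self, rng):
        bases = random_dna(rng, 800) + "AT" * 30 + random_dna(rng, 800)
        ref = [make_genome(bases)]
        for _ in range(10):
            triples = []
            for _ in range(int(rng.integers(1, 8))):
                s = int(rng.integers(0, 1500))
                triples.append(("chr1", s, s + int(rng.integers(30, 200))))
            lenient = IntervalSet(triples)
            got = strict_regions(lenient, ref)
            assert subtract(got, lenient).total_length == 0
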