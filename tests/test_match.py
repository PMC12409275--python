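"""Approximate hit counting: DP reference route, seeded index, Hamming scan."""

import numpy as np
import pytest

from oracles import edit_distance
from conftest import clone_pangenome, make_genome, mutate, random_dna, revcomp
from panmask import (
    AmbiguousQueryError,
    GenomeSequence,
    HitIndex,
    build_hit_index,
    count_edit_hits_pangenome,
    edit_hits,
    hamming_hits,
    indexed_edit_hits,
)
from panmask import _kernels as K


class TestEditHits:
    def test_planted_query_found_exactly_once(self, rng):
        target_bases = random_dna(rng, 2000)
        q = random_dna(rng, 31)
        target = make_genome(target_bases[:700] + q + target_bases[700:])
        hits = edit_hits(q, target, 0)
        assert len(hits) == 1
        assert hits[0].dist == 0
        assert hits[0].start == 700
        assert hits[0].strand == "+"

    def test_mutated_second_copy_found_at_its_distance(self, rng):
        q = random_dna(rng, 31)
        q2 = mutate(rng, q, 2)
        assert edit_distance(q, q2) == 2
        target = make_genome(random_dna(rng, 400) + q + random_dna(rng, 400) + q2 + random_dna(rng, 400))
        hits = edit_hits(q, target, 3)
        assert sorted(h.dist for h in hits) == [0, 2]

    def test_reverse_complement_hit_on_minus_strand(self, rng):
        q = random_dna(rng, 31)
        target = make_genome(random_dna(rng, 300) + revcomp(q) + random_dna(rng, 300))
        hits = edit_hits(q, target, 0)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].start == 300

    def test_n_query_rejected_distinctly(self, rng):
        target = make_genome(random_dna(rng, 100))
        with pytest.raises(AmbiguousQueryError):
            edit_hits("ACGTN" + "A" * 26, target, 1)

    def test_n_in_target_never_matches(self):
        q = "ACGTACGTACGT"
        target = make_genome("N" * 60)
        assert edit_hits(q, target, 3) == []

    def test_indel_jitter_collapses_to_one_hit(self, rng):
        # a copy with one deletion produces several qualifying alignments
        # around one locus; they must count once
        q = random_dna(rng, 31)
        copy = q[:14] + q[15:]  # one base deleted
        target = make_genome(random_dna(rng, 200) + copy + random_dna(rng, 200))
        hits = edit_hits(q, target, 2)
        assert len(hits) == 1
        assert hits[0].dist == 1

    def test_monotonicity_in_distance(self, rng):
        q = random_dna(rng, 21)
        target = make_genome(random_dna(rng, 1500) + mutate(rng, q, 3) + random_dna(rng, 200))
        counts = [len(edit_hits(q, target, d)) for d in range(6)]
        assert counts == sorted(counts)

    def test_strand_symmetry_of_counts(self, rng):
        target = make_genome(random_dna(rng, 1200))
        for _ in range(5):
            q = random_dna(rng, 21)
            assert len(edit_hits(q, target, 3)) == len(edit_hits(revcomp(q), target, 3))


class TestHamming:
    def test_query_equals_target(self):
        q = "ACGTACGTAC"
        assert hamming_hits(q, make_genome(q), 0) == 1

    def test_tandem_exact_copies(self):
        q = "ACGTACGTAC"
        assert hamming_hits(q, make_genome(q + q), 0) == 2

    def test_bound_violated(self, rng):
        q = random_dna(rng, 20)
        assert hamming_hits(q, make_genome(mutate(rng, q, 4)), 3) == 0

    def test_hamming_starts_subset_of_edit_clusters(self, rng):
        # every ungapped qualifying start implies an edit-distance hit at the
        # same bound
        for _ in range(10):
            q = random_dna(rng, 21)
            t = random_dna(rng, 400) + mutate(rng, q, 2) + random_dna(rng, 100)
            target = make_genome(t)
            hh = hamming_hits(q, target, 2)
            eh = len([h for h in edit_hits(q, target, 2) if h.strand == "+"])
            assert hh == 0 or eh >= 1

    def test_batched_hamming_equals_scan(self, rng):
        bases = random_dna(rng, 3000)
        pg = clone_pangenome(bases, 0)
        index = HitIndex(pg)
        k = 31
        positions = list(range(0, 3000 - k, 37))
        qs = np.stack([K.encode(bases[p : p + k]) for p in positions])
        batched = index.batch_hamming_multi(qs, 3)
        target = make_genome(bases)
        for i, p in enumerate(positions):
            assert batched[i] == hamming_hits(bases[p : p + k], target, 3)


class TestIndex:
    def test_counts_match_brute_force_on_clone_panel(self, rng):
        bases = random_dna(rng, 2000)
        pg = clone_pangenome(bases, 9)
        index = build_hit_index(pg)
        q = bases[500:531]
        per_genome = indexed_edit_hits(index, q, 3)
        assert sum(per_genome.values()) == 10
        assert count_edit_hits_pangenome(q, pg, 3) == 10

    def test_extra_mutated_copy_counted(self, rng):
        bases = random_dna(rng, 2000)
        q = bases[700:731]
        hap = bases + mutate(rng, q, 2)
        ref = GenomeSequence("ref", "chr1", bases)
        from panmask import PangenomeSet

        pg = PangenomeSet((ref,), ((GenomeSequence("hap1", "chr1", hap),),))
        index = build_hit_index(pg)
        assert sum(indexed_edit_hits(index, q, 3).values()) == 3
        assert count_edit_hits_pangenome(q, pg, 3) == 3

    def test_absent_query_counts_zero(self, rng):
        pg = clone_pangenome(random_dna(rng, 2000), 2)
        q = random_dna(rng, 31)
        index = build_hit_index(pg)
        counts = indexed_edit_hits(index, q, 3)
        brute = {
            gid: sum(len(edit_hits(q, gs, 3)) for gs in seqs)
            for gid, seqs in pg.genome_items()
        }
        assert counts == brute

    def test_empty_genome_set_counts_zero(self, rng):
        index = HitIndex([])
        q = K.encode(random_dna(rng, 31))[None, :]
        assert index.batch_cluster_counts(q, 3).tolist() == [0]

    def test_k_configuration_enforced(self, rng):
        pg = clone_pangenome(random_dna(rng, 500), 0)
        index = build_hit_index(pg, k=31)
        with pytest.raises(ValueError, match="configuration"):
            indexed_edit_hits(index, random_dna(rng, 21), 1)


class TestEngineAgreement:
    def test_bitparallel_profile_equals_naive(self, rng):
        """The Myers scan kernels are exact: same per-end profile as the DP."""
        from panmask.simulate import _peq4, _peq_packed

        out_s = np.empty(1 << 14, np.int64)
        out_e = np.empty(1 << 14, np.int64)
        out_d = np.empty(1 << 14, np.int64)
        for _ in range(60):
            k = int(rng.integers(8, 32))
            n = int(rng.integers(k, 600))
            d = int(rng.integers(0, min(8, k)))
            t = rng.integers(0, 5, n).astype(np.int8)
            q = rng.integers(0, 4, k).astype(np.int8)
            if n > k and rng.random() < 0.7:
                s = int(rng.integers(0, n - k))
                t[s : s + k] = q
            ref_e, ref_d = K.naive_profile(q, t, d)
            keep = ref_e > 0  # the word kernels do not emit the empty prefix
            m4 = K.myers4_profile(t, _peq4([q, q, q, q], k), k, d, out_s, out_e, out_d)
            sel = out_s[:m4] == 0
            assert np.array_equal(ref_e[keep], out_e[:m4][sel])
            assert np.array_equal(ref_d[keep], out_d[:m4][sel])
            mp = K.myers_packed2(
                t, _peq_packed(q, q, k), _peq_packed(q, q, k), k, d, out_s, out_e, out_d
            )
            sel = out_s[:mp] == 0
            assert np.array_equal(ref_e[keep], out_e[:mp][sel])
            assert np.array_equal(ref_d[keep], out_d[:mp][sel])
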