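"""Coverage, density and genotype-ignored FDR/FNR metrics."""

import pytest

from conftest import make_genome, random_dna
from panmask import (
    ConsistencyError,
    GenomeSequence,
    IntervalSet,
    VariantRecord,
    compare_callsets,
    coverage_of_intervals,
    coverage_of_variants,
    relative_density,
    variant_density,
)


REGIONS = IntervalSet({"chr1": [(0, 50), (100, 200)]})


class TestCoverage:
    def test_whole_genome_regions_cover_everything(self):
        targets = IntervalSet({"chr1": [(10, 60)]})
        whole = IntervalSet({"chr1": [(0, 1000)]})
        assert coverage_of_intervals(whole, targets) == 1.0

    def test_partial_coverage(self):
        regions = IntervalSet({"chr1": [(0, 88)]})
        targets = IntervalSet({"chr1": [(0, 100)]})
        assert coverage_of_intervals(regions, targets) == pytest.approx(0.88)

    def test_disjoint_targets_zero(self):
        assert coverage_of_intervals(REGIONS, IntervalSet({"chr1": [(60, 90)]})) == 0.0

    def test_empty_targets_is_explicit_no_target(self):
        assert coverage_of_intervals(REGIONS, IntervalSet()) is None
        assert coverage_of_variants(REGIONS, []) is None

    def test_variant_footprint_rule(self):
        inside = VariantRecord("chr1", 10, "A", ("G",))
        masked_base = VariantRecord("chr1", 60, "A", ("G",))
        straddling = VariantRecord("chr1", 48, "AAAA", ("A",))
        cov = coverage_of_variants(REGIONS, [inside, masked_base, straddling])
        assert cov == pytest.approx(1 / 3)


class TestDensity:
    def test_density_per_bp(self):
        regions = IntervalSet({"chr1": [(0, 1000)]})
        variants = [VariantRecord("chr1", i * 100 + 3, "A", ("G",)) for i in range(5)]
        assert variant_density(regions, variants) == pytest.approx(0.005)

    def test_no_variants_zero_density(self):
        assert variant_density(REGIONS, []) == 0.0

    def test_relative_density_identity(self):
        regions = IntervalSet({"chr1": [(0, 500)]})
        variants = [VariantRecord("chr1", p, "A", ("G",)) for p in (3, 77, 240)]
        assert relative_density(regions, variants, regions) == 1.0

    def test_zero_length_regions_undefined(self):
        with pytest.raises(ValueError):
            variant_density(IntervalSet(), [])


def _ref(rng):
    bases = list(random_dna(rng, 300))
    # pin the bases our records refer to
    for pos, b in [(10, "A"), (50, "C"), (120, "G"), (180, "T"), (240, "A"), (241, "C")]:
        bases[pos] = b
    return [GenomeSequence("ref", "chr1", "".join(bases))]


def _truth():
    return [
        VariantRecord("chr1", 10, "A", ("G",)),
        VariantRecord("chr1", 50, "C", ("T",)),
        VariantRecord("chr1", 120, "G", ("A",)),
        VariantRecord("chr1", 180, "T", ("C",)),
    ]


WHOLE = IntervalSet({"chr1": [(0, 300)]})


class TestCompareCallsets:
    def test_truth_against_itself_is_perfect(self, rng):
        rep = compare_callsets(_truth(), _truth(), WHOLE, _ref(rng))
        assert (rep.fdr, rep.fnr) == (0.0, 0.0)

    def test_three_of_four_recovered(self, rng):
        rep = compare_callsets(_truth()[:3], _truth(), WHOLE, _ref(rng))
        assert rep.fdr == 0.0
        assert rep.fnr == pytest.approx(0.25)

    def test_one_spurious_call(self, rng):
        calls = _truth() + [VariantRecord("chr1", 240, "A", ("G",))]
        rep = compare_callsets(calls, _truth(), WHOLE, _ref(rng))
        assert rep.fdr == pytest.approx(0.2)
        assert rep.fnr == 0.0

    def test_symmetric_swap_of_rates(self, rng):
        calls = _truth()[:3] + [VariantRecord("chr1", 240, "A", ("G",))]
        a = compare_callsets(calls, _truth(), WHOLE, _ref(rng))
        b = compare_callsets(_truth(), calls, WHOLE, _ref(rng))
        assert a.fdr == pytest.approx(b.fnr)
        assert a.fnr == pytest.approx(b.fdr)

    def test_order_invariance(self, rng):
        calls = list(reversed(_truth()[:3]))
        rep = compare_callsets(calls, _truth(), WHOLE, _ref(rng))
        assert (rep.tp, rep.fp, rep.fn) == (3, 0, 1)

    def test_restriction_monotonicity(self, rng):
        calls = _truth() + [VariantRecord("chr1", 240, "A", ("G",))]
        big = compare_callsets(calls, _truth(), WHOLE, _ref(rng))
        small = compare_callsets(
            calls, _truth(), IntervalSet({"chr1": [(0, 100)]}), _ref(rng)
        )
        assert small.tp + small.fp <= big.tp + big.fp

    def test_genotypes_are_irrelevant_multiallelic_match(self, rng):
        truth = [VariantRecord("chr1", 120, "G", ("A",))]
        calls = [VariantRecord("chr1", 120, "G", ("A", "C"))]
        rep = compare_callsets(calls, truth, WHOLE, _ref(rng))
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)

    def test_snp_indel_selection(self, rng):
        ref = _ref(rng)
        seq = ref[0].bases
        truth = _truth() + [VariantRecord("chr1", 240, seq[240:242], (seq[240],))]
        snp = compare_callsets(truth, truth, WHOLE, ref, variant_type="snp")
        indel = compare_callsets(truth, truth, WHOLE, ref, variant_type="indel")
        assert snp.tp == 4
        assert indel.tp == 1

    def test_unnormalized_input_rejected(self, rng):
        ref = _ref(rng)
        seq = ref[0].bases
        denorm = VariantRecord("chr1", 100, seq[100:102], (seq[100] + "G" if seq[101] != "G" else seq[100] + "T",))
        # shares a removable prefix -> not normalized
        with pytest.raises(ConsistencyError):
            compare_callsets([denorm], [], WHOLE, ref)
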