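"""Region-evaluation metrics: coverage, variant density, and FDR/FNR.

Callset accuracy is measured the way easy regions are meant to be used:
restrict calls and truth to variants whose whole reference footprint lies
inside the regions, then match on normalized (sequence, position, REF, ALT)
with genotypes ignored.  Matching is exact-normalized-allele, not
haplotype-aware: clusters of equivalent representations spanning several
records are not reconciled, which is adequate for callsets that avoid such
clusters and is documented as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

from .intervals import IntervalSet, intersect
from .io import ConsistencyError, GenomeSequence, VariantRecord, normalize_variant


@dataclass(frozen=True)
class EvalReport:
    """Match counts and derived rates of a callset against a truth set."""

    tp: int
    fp: int
    fn: int

    @property
    def fdr(self) -> float:
        """False discovery rate FP/(TP+FP); 0 when no calls."""
        return self.fp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def fnr(self) -> float:
        """False negative rate FN/(TP+FN); 0 when no truth."""
        return self.fn / (self.tp + self.fn) if self.tp + self.fn else 0.0


def coverage_of_intervals(regions: IntervalSet, targets: IntervalSet) -> Optional[float]:
    """Fraction of target bases inside ``regions``; None when no targets."""
    denom = targets.total_length
    if denom == 0:
        return None
    return intersect(targets, regions).total_length / denom


def _footprint_inside(v: VariantRecord, regions: IntervalSet) -> bool:
    for s, e in regions.intervals(v.seq_name):
        if s <= v.pos and v.end <= e:
            return True
        if s > v.pos:
            break
    return False


def coverage_of_variants(
    regions: IntervalSet, variants: Sequence[VariantRecord]
) -> Optional[float]:
    """Fraction of variants whose reference footprint lies wholly inside.

    A variant straddling a region boundary is not safely callable and counts
    as uncovered.  None when the variant list is empty.
    """
    if not variants:
        return None
    inside = sum(1 for v in variants if _footprint_inside(v, regions))
    return inside / len(variants)


def variant_density(
    regions: IntervalSet, variants: Sequence[VariantRecord]
) -> float:
    """Variants with footprint inside the regions, per region base."""
    total = regions.total_length
    if total == 0:
        raise ValueError("variant density undefined for zero-length regions")
    inside = sum(1 for v in variants if _footprint_inside(v, regions))
    return inside / total


def relative_density(
    regions: IntervalSet,
    variants: Sequence[VariantRecord],
    confident: IntervalSet,
) -> float:
    """Density in ``regions`` over density in the confident baseline."""
    base = variant_density(confident, variants)
    if base == 0:
        raise ValueError("relative density undefined: zero confident density")
    return variant_density(regions, variants) / base


# -- callset comparison ----------------------------------------------------

AlleleKey = Tuple[str, int, str, str]


def _decompose(
    variants: Iterable[VariantRecord],
    ref: Sequence[GenomeSequence],
    variant_type: Optional[str],
) -> List[Tuple[VariantRecord, List[AlleleKey]]]:
    """Split multi-allelic records into normalized per-allele keys.

    Raises :class:`ConsistencyError` when an input record is not already
    normalized (left-aligned, trimmed) for every allele it carries.
    """
    by_name = {gs.seq_name: gs for gs in ref}
    out: List[Tuple[VariantRecord, List[AlleleKey]]] = []
    for v in variants:
        if v.seq_name not in by_name:
            raise ConsistencyError(f"variant on unknown sequence {v.seq_name!r}")
        keys: List[AlleleKey] = []
        for alt in v.alts:
            single = VariantRecord(v.seq_name, v.pos, v.ref, (alt,))
            norm = normalize_variant(single, by_name[v.seq_name])
            if (norm.pos, norm.ref, norm.alts) != (v.pos, v.ref, (alt,)) and len(v.alts) == 1:
                raise ConsistencyError(
                    f"record {v.seq_name}:{v.pos} {v.ref}>{alt} is not normalized; "
                    "run normalize_variant on the callset first"
                )
            if variant_type == "snp" and not (len(norm.ref) == 1 == len(norm.alts[0])):
                continue
            if variant_type == "indel" and len(norm.ref) == 1 == len(norm.alts[0]):
                continue
            keys.append((norm.seq_name, norm.pos, norm.ref, norm.alts[0]))
        out.append((v, keys))
    return out


def compare_callsets(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    regions: IntervalSet,
    ref: Sequence[GenomeSequence],
    variant_type: Optional[str] = None,
) -> EvalReport:
    """Genotype-ignored accuracy of ``calls`` against ``truth`` in regions.

    Both sets are restricted to variants whose footprint lies inside the
    regions.  A call matches when any normalized (seq, pos, REF, ALT) pairing
    agrees with the truth.  ``variant_type`` selects "snp" or "indel"
    evaluation; None evaluates every variant.
    """
    if variant_type not in (None, "snp", "indel"):
        raise ValueError("variant_type must be None, 'snp' or 'indel'")
    calls_in = [v for v in calls if _footprint_inside(v, regions)]
    truth_in = [v for v in truth if _footprint_inside(v, regions)]
    dec_calls = _decompose(calls_in, ref, variant_type)
    dec_truth = _decompose(truth_in, ref, variant_type)
    truth_keys: Set[AlleleKey] = {k for _, ks in dec_truth for k in ks}
    call_keys: Set[AlleleKey] = {k for _, ks in dec_calls for k in ks}
    tp = fn = 0
    for _, ks in dec_truth:
        if not ks:
            continue
        if any(k in call_keys for k in ks):
            tp += 1
        else:
            fn += 1
    fp = 0
    for _, ks in dec_calls:
        if not ks:
            continue
        if not any(k in truth_keys for k in ks):
            fp += 1
    return EvalReport(tp=tp, fp=fp, fn=fn)
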