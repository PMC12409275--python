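"""The panmask pipeline: sufficient-uniqueness masking of a pangenome.

Suppose there are N genomes including the reference.  A reference k-mer is
*sufficiently unique* when

(i)  it has exactly 1 hit within edit distance d1 in the reference genome
     (the hit being its own locus), and
(ii) it has fewer than c*N hits within edit distance d2 across all N
     genomes, with d2 > d1 and c > 1 the tolerance for copy-number gains.

Condition (i) guards against mismapping within the reference; condition (ii)
catches loci that are unique in the reference but carry extra paralogous
copies in non-reference samples, whose private differences would otherwise
surface as false variants.  The known blind spot: a segment deleted in some
genomes but duplicated in others can keep its total hit count below c*N and
stay unmasked.

One k-mer is sampled per w bases; every insufficiently unique k-mer masks
``[i, i+k)``.  The complement of the mask, minus an exact ungapped Hamming
rescue filter on the reference and a minimum-length filter, gives the
*lenient* easy regions; subtracting long SDUST low-complexity tracts gives
the *strict* set.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .intervals import IntervalSet, complement, length_filter, subtract, union
from .io import GenomeSequence
from .match import HammingFilterParams, HitIndex
from .sdust import SdustParams, sdust_mask


@dataclass(frozen=True)
class PangenomeSet:
    """The N genomes (reference first) the uniqueness test runs over."""

    reference: Tuple[GenomeSequence, ...]
    others: Tuple[Tuple[GenomeSequence, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", tuple(self.reference))
        object.__setattr__(self, "others", tuple(tuple(g) for g in self.others))
        if not self.reference:
            raise ValueError("reference genome has no sequences")
        ids = [g[0].genome_id for g in (self.reference, *self.others) if g]
        if len(set(ids)) != len(ids):
            raise ValueError("genome_ids must be unique")

    @property
    def N(self) -> int:
        """Total genome count, reference included."""
        return 1 + len(self.others)

    @property
    def reference_id(self) -> str:
        return self.reference[0].genome_id

    def genome_items(self) -> Iterator[Tuple[str, List[GenomeSequence]]]:
        yield self.reference[0].genome_id, list(self.reference)
        for g in self.others:
            yield g[0].genome_id, list(g)

    def reference_lengths(self) -> Dict[str, int]:
        return {gs.seq_name: gs.length for gs in self.reference}


@dataclass(frozen=True)
class UniquenessParams:
    """Tunables of the sufficient-uniqueness test.

    ``k``: k-mer length (151 matches common short-read lengths);
    ``w``: sampling stride; ``c``: copy-gain tolerance (> 1);
    ``d1``: reference-uniqueness edit bound; ``d2``: pangenome edit bound
    (d2 > d1).
    """

    k: int = 151
    w: int = 10
    c: float = 1.01
    d1: int = 3
    d2: int = 7

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not 1 <= self.w <= self.k:
            raise ValueError("require 1 <= w <= k")
        if not self.c > 1:
            raise ValueError("c must exceed 1 (copy-gain tolerance)")
        if not (self.d2 > self.d1 >= 0):
            raise ValueError("require d2 > d1 >= 0")


@dataclass(frozen=True)
class RegionFilterParams:
    """Easy-region post-filters: minimum length and longest tolerated LCR."""

    min_region_len: int = 50
    max_lcr_len: int = 18

    def __post_init__(self) -> None:
        if self.min_region_len < 1 or self.max_lcr_len < 0:
            raise ValueError("require min_region_len >= 1 and max_lcr_len >= 0")


def sample_positions(seq_len: int, k: int, w: int) -> List[int]:
    """Sampled k-mer start positions: stride ``w`` plus a forced final k-mer.

    The final position ``seq_len - k`` is always included so sequence tails
    are assessed rather than easy by default.  A sequence shorter than ``k``
    yields no positions (it is masked entirely by convention).
    """
    if seq_len < k:
        return []
    last = seq_len - k
    pos = list(range(0, last + 1, w))
    if pos[-1] != last:
        pos.append(last)
    return pos


def _copy_gain_threshold(c: float, n: int) -> Fraction:
    # exact rational c*N so the strict "< c*N" comparison never suffers
    # float round-off; a count equal to the boundary masks
    return Fraction(str(c)) * n


def _query_matrix(codes: np.ndarray, positions: Sequence[int], k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Stack sampled k-mers into a code matrix; flag those containing N."""
    pos = np.asarray(positions, dtype=np.int64)
    idx = pos[:, None] + np.arange(k)[None, :]
    qs = codes[idx]
    has_n = (qs >= 4).any(axis=1)
    return qs.astype(np.int8), has_n


def is_sufficiently_unique(
    kmer_pos: int,
    ref_seq: GenomeSequence,
    genomes: PangenomeSet,
    p: UniquenessParams,
    index: HitIndex | None = None,
) -> bool:
    """Apply both uniqueness conditions to one reference k-mer.

    k-mers containing N are never sufficiently unique (assembly gaps must
    not look easy).
    """
    if kmer_pos + p.k > ref_seq.length:
        raise ValueError("k-mer exceeds reference sequence")
    kmer = ref_seq.bases[kmer_pos : kmer_pos + p.k]
    if "N" in kmer:
        return False
    if index is None:
        index = HitIndex(genomes)
    q = K.encode(kmer)[None, :]
    ref_hits = int(index.batch_cluster_counts(q, p.d1, genome_ids=[genomes.reference_id])[0])
    if ref_hits != 1:
        return False
    pan_hits = int(index.batch_cluster_counts(q, p.d2)[0])
    return pan_hits < _copy_gain_threshold(p.c, genomes.N)


def compute_mask(
    genomes: PangenomeSet,
    p: UniquenessParams,
    index: HitIndex | None = None,
) -> IntervalSet:
    """Mask ``[i, i+k)`` for every sampled, insufficiently unique k-mer.

    Reference sequences shorter than ``k`` are masked entirely
    (unassessable is not easy).
    """
    if index is None:
        index = HitIndex(genomes)
    thresh = _copy_gain_threshold(p.c, genomes.N)
    triples: List[Tuple[str, int, int]] = []
    for ref_seq in genomes.reference:
        name = ref_seq.seq_name
        if ref_seq.length < p.k:
            triples.append((name, 0, ref_seq.length))
            continue
        positions = sample_positions(ref_seq.length, p.k, p.w)
        codes = K.encode(ref_seq.bases)
        qs, has_n = _query_matrix(codes, positions, p.k)
        clean = np.nonzero(~has_n)[0]
        bad = np.zeros(len(positions), dtype=bool)
        bad[has_n] = True
        if clean.size:
            sub = np.ascontiguousarray(qs[clean])
            ref_counts = index.batch_cluster_counts(
                sub, p.d1, genome_ids=[genomes.reference_id]
            )
            pan_counts = index.batch_cluster_counts(sub, p.d2)
            fail = (ref_counts != 1) | np.array(
                [not (int(c) < thresh) for c in pan_counts]
            )
            bad[clean[fail]] = True
        for i in np.nonzero(bad)[0].tolist():
            s = positions[i]
            triples.append((name, s, s + p.k))
    return IntervalSet(triples)


def hamming_drop_intervals(
    genomes: PangenomeSet,
    p: UniquenessParams,
    h: HammingFilterParams,
    index: HitIndex | None = None,
) -> IntervalSet:
    """``[i, i+k)`` for every sampled k-mer with >= 2 exact Hamming starts.

    The rescue filter mirrors exact mappability tools: ungapped matches
    within ``h.max_mismatch`` on the forward strand of the reference only.
    It saves hits that k-mer sampling or alignment clustering may blur, e.g.
    within long low-complexity runs where edit-distance hits chain into a
    single cluster.
    """
    if index is None:
        index = HitIndex(genomes)
    triples: List[Tuple[str, int, int]] = []
    for ref_seq in genomes.reference:
        if ref_seq.length < p.k:
            continue
        positions = sample_positions(ref_seq.length, p.k, p.w)
        codes = K.encode(ref_seq.bases)
        qs, has_n = _query_matrix(codes, positions, p.k)
        clean = np.nonzero(~has_n)[0]
        if not clean.size:
            continue
        sub = np.ascontiguousarray(qs[clean])
        counts = index.batch_hamming_multi(
            sub, h.max_mismatch, genome_ids=[genomes.reference_id]
        )
        for i in clean[counts >= 2].tolist():
            s = positions[i]
            triples.append((ref_seq.seq_name, s, s + p.k))
    return IntervalSet(triples)


def lenient_regions(
    genomes: PangenomeSet,
    p: UniquenessParams,
    h: HammingFilterParams | None = None,
    f: RegionFilterParams | None = None,
    index: HitIndex | None = None,
) -> IntervalSet:
    """Lenient easy regions: unmasked, Hamming-rescued, length-filtered."""
    if h is None:
        h = HammingFilterParams(k=p.k)
    if f is None:
        f = RegionFilterParams()
    if index is None:
        index = HitIndex(genomes)
    mask = compute_mask(genomes, p, index=index)
    drop = hamming_drop_intervals(genomes, p, h, index=index)
    easy = complement(union(mask, drop), genomes.reference_lengths())
    return length_filter(easy, f.min_region_len)


def strict_regions(
    lenient: IntervalSet,
    ref: Sequence[GenomeSequence],
    s: SdustParams | None = None,
    f: RegionFilterParams | None = None,
) -> IntervalSet:
    """Strict easy regions: lenient minus SDUST LCRs longer than the cap.

    SNP and indel calling errors concentrate in low-complexity regions, so
    tracts longer than ``f.max_lcr_len`` are excluded and the minimum-length
    filter re-applied.  The result is always a subset of the lenient input.
    """
    if s is None:
        s = SdustParams()
    if f is None:
        f = RegionFilterParams()
    long_lcrs: List[Tuple[str, int, int]] = []
    for gs in ref:
        lcrs = sdust_mask(gs, s)
        for st, en in lcrs.intervals(gs.seq_name):
            if en - st > f.max_lcr_len:
                long_lcrs.append((gs.seq_name, st, en))
    out = subtract(lenient, IntervalSet(long_lcrs))
    return length_filter(out, f.min_region_len)
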