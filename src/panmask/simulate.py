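"""Seeded synthetic pangenomes with planted structure and known truth.

The generator emulates the role of a collection of high-quality haplotype
assemblies: each haplotype is the reference plus sampled SNVs and short
indels, optionally carrying planted segmental duplications (present in a
configurable subset of haplotypes, with per-copy divergence), planted
low-complexity tracts in the reference, and the method's documented blind
spot — a segment deleted in some genomes while duplicated in others.  Every
planted feature and every small variant is recorded in a truth ledger, so
each pipeline stage can be checked against ground truth without external
data.  One integer seed drives all randomness; identical seeds give
byte-identical output.

:func:`expected_mask_oracle` recomputes the sufficient-uniqueness mask with
a full dynamic-programming scan over every genome position (bit-parallel,
no seeding, no index), serving as the independent referee for
:func:`panmask.mask.compute_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .intervals import IntervalSet
from .io import GenomeSequence, VariantRecord, normalize_variant
from .mask import PangenomeSet, UniquenessParams, sample_positions

_BASES = "ACGT"


@dataclass(frozen=True)
class Duplication:
    """A planted segmental duplication of a reference segment."""

    src_start: int
    length: int
    n_copies: int = 1
    carrier_haplotype_count: int = 1
    divergence: float = 0.005  # per-base SNV rate of each planted copy


@dataclass(frozen=True)
class LcrTract:
    """A planted low-complexity tract written into the reference."""

    start: int
    motif: str
    repeat_count: int

    @property
    def length(self) -> int:
        return len(self.motif) * self.repeat_count


@dataclass(frozen=True)
class WeaknessCase:
    """Segment deleted in some haplotypes and duplicated (exactly) in others.

    Total hit counts of k-mers in the segment drop by one per deletion
    carrier and rise by one per duplication carrier; when the net count
    stays below c*N the uniqueness test cannot see the duplication — the
    method's stated limitation.
    """

    start: int
    length: int
    deleted_in: int
    duplicated_in: int


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    ref_len: int = 50_000
    n_haplotypes: int = 9  # non-reference genomes; N = n_haplotypes + 1
    snv_rate: float = 0.001
    indel_rate: float = 0.0002
    duplications: Tuple[Duplication, ...] = ()
    lcr_tracts: Tuple[LcrTract, ...] = ()
    weakness: Optional[WeaknessCase] = None
    seq_name: str = "chr1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "duplications", tuple(self.duplications))
        object.__setattr__(self, "lcr_tracts", tuple(self.lcr_tracts))
        for r in (self.snv_rate, self.indel_rate):
            if not 0 <= r <= 0.1:
                raise ValueError("rates must lie in [0, 0.1]")
        spans = []
        for d in self.duplications:
            spans.append((d.src_start, d.src_start + d.length))
        for t in self.lcr_tracts:
            spans.append((t.start, t.start + t.length))
        if self.weakness is not None:
            spans.append((self.weakness.start, self.weakness.start + self.weakness.length))
        for s, e in spans:
            if not (0 <= s < e <= self.ref_len):
                raise ValueError(f"planted feature ({s}, {e}) outside reference bounds")
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted features overlap")


@dataclass(frozen=True)
class Edit:
    """One haplotype edit: replace ``ref[pos:pos+ref_len]`` by ``alt``."""

    pos: int
    ref_len: int
    alt: str
    kind: str  # snv | ins | del | dup_copy | weakness_del | weakness_copy


@dataclass(frozen=True)
class ParalogCopy:
    hap_id: str
    insertion_site: int
    src_start: int
    length: int


@dataclass
class TruthLedger:
    """Everything the generator planted, keyed the way tests need it."""

    ref: GenomeSequence
    edits: Dict[str, List[Edit]]
    variants: Dict[str, List[VariantRecord]]  # normalized small variants
    paralogs: List[ParalogCopy]
    lcr_tracts: List[Tuple[int, int]]
    weakness: Optional[WeaknessCase]

    def all_variants(self) -> List[VariantRecord]:
        """Deduplicated union of all haplotypes' small variants."""
        seen = set()
        out: List[VariantRecord] = []
        for hap in sorted(self.variants):
            for v in self.variants[hap]:
                key = (v.seq_name, v.pos, v.ref, v.alts)
                if key not in seen:
                    seen.add(key)
                    out.append(v)
        out.sort(key=lambda v: v.pos)
        return out

    def features_bed(self) -> IntervalSet:
        triples = [(self.ref.seq_name, s, e) for s, e in self.lcr_tracts]
        for p in self.paralogs:
            triples.append((self.ref.seq_name, p.src_start, p.src_start + p.length))
        if self.weakness is not None:
            triples.append(
                (self.ref.seq_name, self.weakness.start, self.weakness.start + self.weakness.length)
            )
        return IntervalSet(triples)

    def reconstruct(self, hap_id: str) -> str:
        """Apply the ledger's edits to the reference, highest position first."""
        bases = self.ref.bases
        for ed in sorted(self.edits[hap_id], key=lambda e: e.pos, reverse=True):
            bases = bases[: ed.pos] + ed.alt + bases[ed.pos + ed.ref_len :]
        return bases


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes.tolist())


def _feature_exclusion(cfg: SimConfig, margin: int) -> np.ndarray:
    """Boolean mask of reference positions where small variants must not land."""
    excl = np.zeros(cfg.ref_len, dtype=bool)
    spans = [(d.src_start, d.src_start + d.length) for d in cfg.duplications]
    spans += [(t.start, t.start + t.length) for t in cfg.lcr_tracts]
    if cfg.weakness is not None:
        spans.append((cfg.weakness.start, cfg.weakness.start + cfg.weakness.length))
    for s, e in spans:
        excl[max(0, s - margin) : min(cfg.ref_len, e + margin)] = True
    excl[:margin] = True
    excl[cfg.ref_len - margin :] = True
    return excl


def _pick_site(rng: np.random.Generator, free: np.ndarray) -> int:
    open_pos = np.nonzero(free)[0]
    if open_pos.size == 0:
        raise ValueError("no free insertion site left; reduce planted features")
    return int(rng.choice(open_pos))


def _mutate_copy(rng: np.random.Generator, codes: np.ndarray, rate: float) -> Tuple[np.ndarray, int]:
    out = codes.copy()
    hits = np.nonzero(rng.random(out.size) < rate)[0]
    for i in hits.tolist():
        out[i] = (out[i] + int(rng.integers(1, 4))) % 4
    return out, int(hits.size)


def simulate_pangenome(cfg: SimConfig) -> Tuple[PangenomeSet, TruthLedger]:
    """Generate the pangenome and its truth ledger from one seed."""
    rng = np.random.default_rng(cfg.seed)
    ref_codes = _random_seq(rng, cfg.ref_len)
    for t in cfg.lcr_tracts:
        motif = K.encode(t.motif)
        tract = np.tile(motif, t.repeat_count)
        ref_codes[t.start : t.start + tract.size] = tract
    ref_bases = _codes_to_str(ref_codes)
    ref = GenomeSequence("ref", cfg.seq_name, ref_bases)

    hap_ids = [f"hap{i + 1}" for i in range(cfg.n_haplotypes)]
    margin = 16
    excl = _feature_exclusion(cfg, margin)

    # deterministic carrier assignment for the weakness case; random carriers
    # for ordinary duplications
    weak_del: List[str] = []
    weak_dup: List[str] = []
    if cfg.weakness is not None:
        need = cfg.weakness.deleted_in + cfg.weakness.duplicated_in
        if need > cfg.n_haplotypes:
            raise ValueError("weakness case needs more haplotypes than configured")
        weak_del = hap_ids[: cfg.weakness.deleted_in]
        weak_dup = hap_ids[cfg.weakness.deleted_in : need]
    dup_carriers: List[List[str]] = []
    for d in cfg.duplications:
        if d.carrier_haplotype_count > cfg.n_haplotypes:
            raise ValueError("duplication carrier count exceeds haplotype count")
        picked = rng.choice(cfg.n_haplotypes, size=d.carrier_haplotype_count, replace=False)
        dup_carriers.append([hap_ids[i] for i in sorted(picked.tolist())])

    edits: Dict[str, List[Edit]] = {h: [] for h in hap_ids}
    variants: Dict[str, List[VariantRecord]] = {h: [] for h in hap_ids}
    paralogs: List[ParalogCopy] = []
    # insertion sites must not collide across haplotypes' features either
    free = ~excl

    for di, d in enumerate(cfg.duplications):
        src = ref_codes[d.src_start : d.src_start + d.length]
        for hap in dup_carriers[di]:
            for _ in range(d.n_copies):
                site = _pick_site(rng, free)
                free[max(0, site - margin) : site + margin] = False
                copy, _nmut = _mutate_copy(rng, src, d.divergence)
                edits[hap].append(Edit(site, 0, _codes_to_str(copy), "dup_copy"))
                paralogs.append(ParalogCopy(hap, site, d.src_start, d.length))

    if cfg.weakness is not None:
        w = cfg.weakness
        seg = ref_codes[w.start : w.start + w.length]
        for hap in weak_del:
            edits[hap].append(Edit(w.start, w.length, "", "weakness_del"))
        for hap in weak_dup:
            site = _pick_site(rng, free)
            free[max(0, site - margin) : site + margin] = False
            edits[hap].append(Edit(site, 0, _codes_to_str(seg), "weakness_copy"))

    for hap in hap_ids:
        taken = excl.copy()
        for ed in edits[hap]:  # keep smalls clear of this hap's own features
            taken[max(0, ed.pos - margin) : min(cfg.ref_len, ed.pos + ed.ref_len + margin)] = True
        snv_pos = np.nonzero((rng.random(cfg.ref_len) < cfg.snv_rate) & ~taken)[0]
        for p in snv_pos.tolist():
            taken[p] = True
            old = int(ref_codes[p])
            new = (old + int(rng.integers(1, 4))) % 4
            alt = _BASES[new]
            edits[hap].append(Edit(p, 1, alt, "snv"))
            variants[hap].append(
                normalize_variant(
                    VariantRecord(cfg.seq_name, p, _BASES[old], (alt,)), ref
                )
            )
        cand = np.nonzero((rng.random(cfg.ref_len) < cfg.indel_rate) & ~taken)[0]
        for p in cand.tolist():
            if p < 1 or taken[max(0, p - 12) : min(cfg.ref_len, p + 12)].any():
                continue
            taken[max(0, p - 12) : min(cfg.ref_len, p + 12)] = True
            ln = min(int(rng.geometric(0.5)), 10)
            if rng.random() < 0.5:  # insertion before position p
                ins = _codes_to_str(_random_seq(rng, ln))
                edits[hap].append(Edit(p, 0, ins, "ins"))
                rec = VariantRecord(cfg.seq_name, p - 1, ref_bases[p - 1], (ref_bases[p - 1] + ins,))
            else:  # deletion of ref[p:p+ln]
                if p + ln + 1 > cfg.ref_len:
                    continue
                edits[hap].append(Edit(p, ln, "", "del"))
                rec = VariantRecord(
                    cfg.seq_name, p - 1, ref_bases[p - 1 : p + ln], (ref_bases[p - 1],)
                )
            variants[hap].append(normalize_variant(rec, ref))
        edits[hap].sort(key=lambda e: e.pos)
        variants[hap].sort(key=lambda v: v.pos)

    ledger = TruthLedger(
        ref=ref,
        edits=edits,
        variants=variants,
        paralogs=paralogs,
        lcr_tracts=[(t.start, t.start + t.length) for t in cfg.lcr_tracts],
        weakness=cfg.weakness,
    )
    hap_seqs = tuple(
        (GenomeSequence(h, cfg.seq_name, ledger.reconstruct(h)),) for h in hap_ids
    )
    pangenome = PangenomeSet(reference=(ref,), others=hap_seqs)
    return pangenome, ledger


# -- independent mask referee ----------------------------------------------


def _peq4(patterns: Sequence[np.ndarray], k: int) -> np.ndarray:
    peq = np.zeros((4, 5), np.uint64)
    bits = np.uint64(1) << np.arange(k, dtype=np.uint64)
    for si, q in enumerate(patterns):
        for c in range(4):
            peq[si, c] = np.bitwise_or.reduce(bits[q == c]) if (q == c).any() else 0
    return peq


def _peq_packed(qlo: np.ndarray, qhi: np.ndarray, k: int) -> np.ndarray:
    """Match masks for two patterns packed into 32-bit fields of one word."""
    a = np.zeros(5, np.uint64)
    bits = np.uint64(1) << np.arange(k, dtype=np.uint64)
    hbits = bits << np.uint64(32)
    for c in range(4):
        v = np.uint64(0)
        lo = bits[qlo == c]
        hi = hbits[qhi == c]
        if lo.size:
            v |= np.bitwise_or.reduce(lo)
        if hi.size:
            v |= np.bitwise_or.reduce(hi)
        a[c] = v
    return a


def _cluster_count_np(ends: np.ndarray, segs: np.ndarray, half: int) -> int:
    if ends.size == 0:
        return 0
    breaks = (np.diff(segs) != 0) | (np.diff(ends) > half)
    return int(breaks.sum()) + 1


def expected_mask_oracle(
    genomes: PangenomeSet,
    p: UniquenessParams,
    ledger: Optional[TruthLedger] = None,
    max_bases: int = 2_500_000,
) -> IntervalSet:
    """Recompute the mask with a full-scan DP over every genome position.

    No seeding, no shared index with the production path: every sampled
    k-mer is aligned, bit-parallel, against the complete concatenation of
    all genomes on both strands, and the per-end distance profile is
    clustered exactly as the hit definition prescribes.  Intended for small
    instances only; larger inputs are refused with a size hint.  The
    ``ledger`` argument is accepted for interface symmetry and unused.
    """
    del ledger
    total = sum(gs.length for _, seqs in genomes.genome_items() for gs in seqs)
    if total > max_bases:
        raise ValueError(
            f"oracle refuses {total} bases (> {max_bases}); "
            "use a smaller fixture (reference <= 100 kb, a few haplotypes)"
        )
    if p.k > 63:
        return _oracle_naive(genomes, p)
    sep = p.d2 + 8
    seg_codes: List[np.ndarray] = []
    seg_start: List[int] = []
    seg_is_ref: List[bool] = []
    off = 0
    ref_id = genomes.reference_id
    for gid, seqs in genomes.genome_items():
        for gs in seqs:
            codes = K.encode(gs.bases)
            seg_start.append(off)
            seg_is_ref.append(gid == ref_id)
            seg_codes.append(codes)
            seg_codes.append(np.full(sep, 4, np.int8))
            off += codes.size + sep
    text = np.concatenate(seg_codes)
    seg_start_arr = np.asarray(seg_start, np.int64)
    seg_is_ref_arr = np.asarray(seg_is_ref, bool)
    thresh = Fraction(str(p.c)) * genomes.N
    half = p.k // 2

    cap = 1 << 16
    out_s = np.empty(cap, np.int64)
    out_e = np.empty(cap, np.int64)
    out_d = np.empty(cap, np.int64)

    triples: List[Tuple[str, int, int]] = []
    for ref_seq in genomes.reference:
        name = ref_seq.seq_name
        if ref_seq.length < p.k:
            triples.append((name, 0, ref_seq.length))
            continue
        positions = sample_positions(ref_seq.length, p.k, p.w)
        codes = K.encode(ref_seq.bases)
        for bi in range(0, len(positions), 2):
            pair = positions[bi : bi + 2]
            qlist = []
            nflag = []
            for s in pair:
                q = codes[s : s + p.k]
                nflag.append(bool((q >= 4).any()))
                qlist.append(np.where(q >= 4, 0, q).astype(np.int8))
            pats = [qlist[0], K.revcomp_codes(qlist[0])]
            if len(pair) == 2:
                pats += [qlist[1], K.revcomp_codes(qlist[1])]
            else:
                pats += [qlist[0], K.revcomp_codes(qlist[0])]
            packed = p.k <= 31 and p.d2 < p.k
            if packed:
                p0 = _peq_packed(pats[0], pats[1], p.k)
                p1 = _peq_packed(pats[2], pats[3], p.k)
            else:
                peq = _peq4(pats, p.k)
            while True:
                if packed:
                    m = K.myers_packed2(text, p0, p1, p.k, p.d2, out_s, out_e, out_d)
                else:
                    m = K.myers4_profile(text, peq, p.k, p.d2, out_s, out_e, out_d)
                if m >= 0:
                    break
                cap *= 2
                out_s = np.empty(cap, np.int64)
                out_e = np.empty(cap, np.int64)
                out_d = np.empty(cap, np.int64)
            st = out_s[:m]
            ends = out_e[:m]
            dd = out_d[:m]
            for qi, s in enumerate(pair):
                if nflag[qi]:
                    triples.append((name, s, s + p.k))
                    continue
                n_all = 0
                n_ref = 0
                for strand_state in (2 * qi, 2 * qi + 1):
                    sel = st == strand_state
                    e_s = ends[sel]
                    d_s = dd[sel]
                    segs = np.searchsorted(seg_start_arr, e_s, side="right") - 1
                    n_all += _cluster_count_np(e_s, segs, half)
                    rsel = seg_is_ref_arr[segs] & (d_s <= p.d1)
                    n_ref += _cluster_count_np(e_s[rsel], segs[rsel], half)
                if n_ref != 1 or not (n_all < thresh):
                    triples.append((name, s, s + p.k))
    return IntervalSet(triples)


def _oracle_naive(genomes: PangenomeSet, p: UniquenessParams) -> IntervalSet:
    """O(n*k)-per-query fallback referee for k-mers too long for one word."""
    thresh = Fraction(str(p.c)) * genomes.N
    half = p.k // 2
    ref_id = genomes.reference_id
    entries = [
        (gid, K.encode(gs.bases))
        for gid, seqs in genomes.genome_items()
        for gs in seqs
    ]
    triples: List[Tuple[str, int, int]] = []
    for ref_seq in genomes.reference:
        name = ref_seq.seq_name
        if ref_seq.length < p.k:
            triples.append((name, 0, ref_seq.length))
            continue
        codes = K.encode(ref_seq.bases)
        for s in sample_positions(ref_seq.length, p.k, p.w):
            q = codes[s : s + p.k]
            if (q >= 4).any():
                triples.append((name, s, s + p.k))
                continue
            qr = K.revcomp_codes(q)
            n_all = 0
            n_ref = 0
            for gid, tcodes in entries:
                for qs in (q, qr):
                    ends, dists = K.naive_profile(qs, tcodes, p.d2)
                    n_all += int(K.cluster_count(ends, half))
                    if gid == ref_id:
                        keep = ends[dists <= p.d1]
                        n_ref += int(K.cluster_count(keep, half))
            if n_ref != 1 or not (n_all < thresh):
                triples.append((name, s, s + p.k))
    return IntervalSet(triples)
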