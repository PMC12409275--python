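"""Approximate occurrence counting of k-mers under bounded edit distance.

The sufficient-uniqueness test needs, for a reference k-mer, the number of
*hit clusters* it has in each genome: end-to-end alignments of the whole
k-mer (mismatches and indels, never clipped) within an edit bound, on either
strand, with nearby qualifying alignments collapsed so one locus counts once
regardless of indel jitter.

Two routes compute the same quantity:

* :func:`edit_hits` / :func:`count_edit_hits_pangenome` — the plain
  semi-global DP over every target position.  Slow, simple, the referee.
* :class:`HitIndex` — exact pigeonhole seeding: the query is split into
  ``d+1`` pieces, any alignment with at most ``d`` edits contains one piece
  unedited, so exact seed lookups localise every hit; candidates are then
  verified with the DP on small windows.  Identical counts, desk-scale fast.

Unlike heuristic long-read aligners, the seeded route is exhaustive at the
scales it supports: it can only find every qualifying hit, never miss one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .io import GenomeSequence


class AmbiguousQueryError(ValueError):
    """The query k-mer contains N; callers decide the policy for these."""


@dataclass(frozen=True)
class HammingFilterParams:
    """Ungapped rescue filter configuration (GenMap-style exact Hamming)."""

    k: int = 151
    max_mismatch: int = 3

    def __post_init__(self) -> None:
        if self.k <= 0 or self.max_mismatch < 0:
            raise ValueError("require k > 0 and max_mismatch >= 0")


@dataclass(frozen=True)
class Hit:
    """One clustered approximate occurrence of a k-mer in a target."""

    genome_id: str
    seq_name: str
    strand: str  # '+' or '-'
    start: int  # 0-based target start of the representative alignment
    dist: int  # edit distance of the representative alignment


def _check_query(codes: np.ndarray) -> None:
    if (codes >= 4).any():
        raise AmbiguousQueryError("query k-mer contains N")


def _cluster_events(ends: np.ndarray, dists: np.ndarray, half: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Group qualifying (end, dist) events into clusters by end proximity."""
    if ends.size == 0:
        return []
    order = np.argsort(ends, kind="stable")
    ends = ends[order]
    dists = dists[order]
    # dedupe equal ends keeping min dist
    keep_e: List[int] = []
    keep_d: List[int] = []
    for e, d in zip(ends.tolist(), dists.tolist()):
        if keep_e and e == keep_e[-1]:
            if d < keep_d[-1]:
                keep_d[-1] = d
        else:
            keep_e.append(e)
            keep_d.append(d)
    clusters: List[Tuple[np.ndarray, np.ndarray]] = []
    cur_e: List[int] = [keep_e[0]]
    cur_d: List[int] = [keep_d[0]]
    for e, d in zip(keep_e[1:], keep_d[1:]):
        if e - cur_e[-1] > half:
            clusters.append((np.array(cur_e), np.array(cur_d)))
            cur_e, cur_d = [], []
        cur_e.append(e)
        cur_d.append(d)
    clusters.append((np.array(cur_e), np.array(cur_d)))
    return clusters


def _representative(q: np.ndarray, t: np.ndarray, cluster: Tuple[np.ndarray, np.ndarray], d_max: int) -> Tuple[int, int]:
    """(start, dist) of a cluster: minimal distance, tie broken leftmost."""
    ends, dists = cluster
    best = int(dists.min())
    k = q.shape[0]
    qr = q[::-1].copy()
    best_start = None
    for e in ends[dists == best].tolist():
        a = max(0, e - k - d_max)
        seg = t[a:e][::-1].copy()
        # reversing both strings turns "alignments ending at e" into prefix
        # alignments of the reversed pair; the longest prefix achieving the
        # cluster's distance gives the leftmost start
        row = K.prefix_profile(qr, seg)
        js = np.nonzero(row == best)[0]
        j = int(js.max()) if js.size else k
        start = e - j
        if best_start is None or start < best_start:
            best_start = start
    return int(best_start if best_start is not None else 0), best


def edit_hits(query: str | np.ndarray, target: GenomeSequence, d_max: int) -> List[Hit]:
    """Every hit cluster of ``query`` on both strands of ``target``.

    Plain dynamic programming over all target positions — the reference
    route.  N in the target never matches; a query containing N raises
    :class:`AmbiguousQueryError`.
    """
    q = K.encode(query) if isinstance(query, str) else np.asarray(query, np.int8)
    _check_query(q)
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    t = K.encode(target.bases)
    k = q.shape[0]
    half = k // 2
    hits: List[Hit] = []
    for strand, qs in (("+", q), ("-", K.revcomp_codes(q))):
        ends, dists = K.naive_profile(qs, t, d_max)
        for cluster in _cluster_events(ends, dists, half):
            start, dist = _representative(qs, t, cluster, d_max)
            hits.append(Hit(target.genome_id, target.seq_name, strand, start, dist))
    hits.sort(key=lambda h: (h.strand, h.start))
    return hits


def _genome_items(genomes) -> List[Tuple[str, List[GenomeSequence]]]:
    if hasattr(genomes, "genome_items"):
        return list(genomes.genome_items())
    return [(gid, list(seqs)) for gid, seqs in genomes]


def count_edit_hits_pangenome(query: str | np.ndarray, genomes, d_max: int) -> int:
    """Total hit-cluster count of ``query`` across all genomes (brute force)."""
    total = 0
    for _, seqs in _genome_items(genomes):
        for gs in seqs:
            total += len(edit_hits(query, gs, d_max))
    return total


def hamming_hits(query: str | np.ndarray, target: GenomeSequence, max_mismatch: int) -> int:
    """Ungapped forward-strand starts within a Hamming bound (N mismatches)."""
    q = K.encode(query) if isinstance(query, str) else np.asarray(query, np.int8)
    t = K.encode(target.bases)
    if q.shape[0] > t.shape[0]:
        raise ValueError("query longer than target")
    return int(K.hamming_scan(q, t, max_mismatch))


# -- seeded exact index ----------------------------------------------------

_MIN_SEED = 4  # below this, seed lookups localise nothing; fall back to scan
_MAX_SEED = 31  # 2-bit packing bound for uint64 hashes


class HitIndex:
    """Exact seeded hit counting over a set of genomes.

    Per genome sequence, sorted tables of packed L-mers are built lazily for
    whatever seed lengths the queried ``(k, d)`` combinations require.  For a
    query class where the pigeonhole seed would be shorter than
    ``_MIN_SEED`` bases, the index transparently falls back to the full DP
    scan — counts are identical either way, by contract.
    """

    def __init__(self, genomes, k: int | None = None):
        self._k = k
        self.entries: List[Tuple[str, str, np.ndarray]] = []
        self.genome_ids: List[str] = []
        seen = set()
        for gid, seqs in _genome_items(genomes):
            if gid in seen:
                raise ValueError(f"duplicate genome_id {gid!r}")
            seen.add(gid)
            self.genome_ids.append(gid)
            for gs in seqs:
                self.entries.append((gid, gs.seq_name, K.encode(gs.bases)))
        self._tables: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = {}

    def _table(self, ei: int, L: int) -> Tuple[np.ndarray, np.ndarray]:
        key = (ei, L)
        tab = self._tables.get(key)
        if tab is None:
            codes = self.entries[ei][2]
            h, valid = K.rolling_hash(codes, L)
            pos = np.nonzero(valid)[0]
            h = h[pos]
            order = np.argsort(h, kind="stable")
            tab = (h[order], pos[order].astype(np.int64))
            self._tables[key] = tab
        return tab

    def _check_k(self, k: int) -> None:
        if self._k is not None and k != self._k:
            raise ValueError(f"query length {k} != index k configuration {self._k}")

    @staticmethod
    def _piece_hashes(qs: np.ndarray, off: int, L: int) -> np.ndarray:
        h = np.zeros(qs.shape[0], np.uint64)
        for j in range(L):
            h = (h << np.uint64(2)) | qs[:, off + j].astype(np.uint64)
        return h

    @staticmethod
    def _peq_matrix(qs: np.ndarray) -> np.ndarray:
        """Per-query Myers match masks, shape (Q, 5); column 4 (N) stays 0."""
        Q, k = qs.shape
        peq = np.zeros((Q, 5), np.uint64)
        rows = np.arange(Q)
        for i in range(k):
            np.bitwise_or.at(peq, (rows, qs[:, i].astype(np.int64)), np.uint64(1) << np.uint64(i))
        return peq

    def _seeded_entry_counts(
        self, ei: int, qs: np.ndarray, peq: np.ndarray, d: int, counts: np.ndarray,
        ev_e: np.ndarray, ev_d: np.ndarray,
    ) -> None:
        codes = self.entries[ei][2]
        n = codes.shape[0]
        Q, k = qs.shape
        pieces = d + 1
        base = k // pieces
        L = min(base, _MAX_SEED)
        if n < L:
            return
        H, P = self._table(ei, L)
        all_q: List[np.ndarray] = []
        all_s0: List[np.ndarray] = []
        for pi in range(pieces):
            off = pi * base
            ph = self._piece_hashes(qs, off, L)
            lo = np.searchsorted(H, ph, side="left")
            hi = np.searchsorted(H, ph, side="right")
            occ = hi - lo
            tot = int(occ.sum())
            if tot == 0:
                continue
            qidx = np.repeat(np.arange(Q), occ)
            starts = np.repeat(lo, occ)
            within = np.arange(tot) - np.repeat(np.cumsum(occ) - occ, occ)
            tpos = P[starts + within]
            all_q.append(qidx)
            all_s0.append(tpos - off)
        if not all_q:
            return
        qidx = np.concatenate(all_q)
        s0 = np.concatenate(all_s0)
        # sort by (query, start centre) and dedupe in one pass via packed keys
        span = n + 2 * k + 2
        key = qidx.astype(np.int64) * span + (s0 + k)
        key = np.unique(key)
        qidx = key // span
        s0 = key % span - k
        grp_lo = np.searchsorted(qidx, np.arange(Q), side="left")
        grp_hi = np.searchsorted(qidx, np.arange(Q), side="right")
        K.seeded_cluster_counts(
            codes, qs, peq, grp_lo, grp_hi, s0, k, d, counts, ev_e, ev_d
        )

    def _scan_query_count(self, qf: np.ndarray, qr: np.ndarray, d: int, genome_ids) -> int:
        total = 0
        k = qf.shape[0]
        half = k // 2
        sel = None if genome_ids is None else set(genome_ids)
        for gid, _, codes in self.entries:
            if sel is not None and gid not in sel:
                continue
            for qs in (qf, qr):
                ends, _ = K.naive_profile(qs, codes, d)
                total += int(K.cluster_count(ends, half))
        return total

    def batch_cluster_counts(
        self, queries: np.ndarray, d: int, genome_ids: Iterable[str] | None = None
    ) -> np.ndarray:
        """Total hit-cluster count per query over the selected genomes.

        ``queries`` is an ``(Q, k)`` int8 code matrix without N.
        """
        queries = np.ascontiguousarray(queries, dtype=np.int8)
        Q, k = queries.shape
        self._check_k(k)
        if (queries >= 4).any():
            raise AmbiguousQueryError("query matrix contains N")
        counts = np.zeros(Q, np.int64)
        if Q == 0:
            return counts
        qs_r = np.ascontiguousarray(queries[:, ::-1])
        qs_r = np.where(qs_r < 4, 3 - qs_r, 4).astype(np.int8)
        base = k // (d + 1)
        sel = None if genome_ids is None else set(genome_ids)
        ev_cap = 1 << 15
        ev_e = np.empty(ev_cap, np.int64)
        ev_d = np.empty(ev_cap, np.int64)
        if base >= _MIN_SEED:
            peq_f = self._peq_matrix(queries) if k <= 63 else np.zeros((Q, 5), np.uint64)
            peq_r = self._peq_matrix(qs_r) if k <= 63 else peq_f
            for ei, (gid, _, _) in enumerate(self.entries):
                if sel is not None and gid not in sel:
                    continue
                for qs, peq in ((queries, peq_f), (qs_r, peq_r)):
                    self._seeded_entry_counts(ei, qs, peq, d, counts, ev_e, ev_d)
            redo = np.nonzero(counts < 0)[0]
            for qi in redo.tolist():
                counts[qi] = self._scan_query_count(
                    queries[qi], qs_r[qi], d, genome_ids
                )
        else:
            for qi in range(Q):
                counts[qi] = self._scan_query_count(
                    queries[qi], qs_r[qi], d, genome_ids
                )
        return counts

    def batch_hamming_multi(
        self, queries: np.ndarray, max_mismatch: int, genome_ids: Iterable[str] | None = None
    ) -> np.ndarray:
        """Forward-strand Hamming start counts per query (exact, seeded)."""
        queries = np.ascontiguousarray(queries, dtype=np.int8)
        Q, k = queries.shape
        self._check_k(k)
        counts = np.zeros(Q, np.int64)
        if Q == 0:
            return counts
        pieces = max_mismatch + 1
        base = k // pieces
        L = min(base, _MAX_SEED)
        sel = None if genome_ids is None else set(genome_ids)
        for ei, (gid, _, codes) in enumerate(self.entries):
            if sel is not None and gid not in sel:
                continue
            n = codes.shape[0]
            if base < _MIN_SEED:
                for qi in range(Q):
                    if k <= n:
                        counts[qi] += int(K.hamming_scan(queries[qi], codes, max_mismatch))
                continue
            if n < L:
                continue
            H, P = self._table(ei, L)
            all_q: List[np.ndarray] = []
            all_s: List[np.ndarray] = []
            for pi in range(pieces):
                off = pi * base
                ph = self._piece_hashes(queries, off, L)
                lo = np.searchsorted(H, ph, side="left")
                hi = np.searchsorted(H, ph, side="right")
                occ = hi - lo
                tot = int(occ.sum())
                if tot == 0:
                    continue
                qidx = np.repeat(np.arange(Q), occ)
                starts = np.repeat(lo, occ)
                within = np.arange(tot) - np.repeat(np.cumsum(occ) - occ, occ)
                tpos = P[starts + within]
                all_q.append(qidx)
                all_s.append(tpos - off)
            if not all_q:
                continue
            qidx = np.concatenate(all_q)
            s = np.concatenate(all_s)
            span = n + 2 * k + 2
            key = qidx.astype(np.int64) * span + (s + k)
            key = np.unique(key)
            qidx = key // span
            s = key % span - k
            K.hamming_verify_counts(codes, queries, qidx, s, max_mismatch, counts)
        return counts


def build_hit_index(genomes, k: int | None = None) -> HitIndex:
    """Build the seeded exact index over a genome collection."""
    return HitIndex(genomes, k=k)


def indexed_edit_hits(index: HitIndex, query: str | np.ndarray, d_max: int) -> Dict[str, int]:
    """Per-genome hit-cluster counts via the index; equals the DP route."""
    q = K.encode(query) if isinstance(query, str) else np.asarray(query, np.int8)
    _check_query(q)
    out: Dict[str, int] = {}
    for gid in index.genome_ids:
        out[gid] = int(
            index.batch_cluster_counts(q[None, :], d_max, genome_ids=[gid])[0]
        )
    return out
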