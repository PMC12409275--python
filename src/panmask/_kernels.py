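"""Compiled kernels for approximate matching and low-complexity scoring.

Three independent alignment engines live here:

* ``naive_profile`` — textbook semi-global dynamic programming (query global,
  target infix), O(n*k) per query.  The reference implementation everything
  else is checked against.
* ``myers4_profile`` — Myers bit-parallel computation of the same per-end
  distance profile (k <= 63), four pattern states interleaved per text pass
  so independent dependency chains overlap on a superscalar core.
* ``seeded_cluster_counts`` — pigeonhole-seeded verification: given exact
  seed candidates, run the naive DP only on candidate windows.  Exact by the
  pigeonhole argument (an alignment with <= d edits over a pattern split into
  d+1 pieces contains at least one unedited piece).

All engines treat the base code 4 (``N``) as matching nothing, and all
produce per-end minimal edit distances, so cluster counts agree exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: base codes: A=0 C=1 G=2 T=3 N=4
CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    CODE[ord(_b)] = _i
    CODE[ord(_b.lower())] = _i


def encode(bases: str) -> np.ndarray:
    """2-bit-style integer codes for a DNA string (N and friends -> 4)."""
    return CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)].copy()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = np.where(codes < 4, 3 - codes, 4).astype(np.int8)
    return rc[::-1].copy()


@njit(cache=True)
def naive_profile(q, t, d):
    """Per-end best edit distance of end-to-end alignments of ``q`` in ``t``.

    Returns ``(ends, dists)``: exclusive end offsets ``j`` in ``[0, n]`` whose
    best alignment of the whole query against a target substring ending at
    ``j`` has at most ``d`` edits, with that distance.
    """
    k = q.shape[0]
    n = t.shape[0]
    col = np.empty(k + 1, np.int64)
    new = np.empty(k + 1, np.int64)
    out_e = np.empty(n + 1, np.int64)
    out_d = np.empty(n + 1, np.int64)
    m = 0
    for i in range(k + 1):
        col[i] = i
    if col[k] <= d:
        out_e[m] = 0
        out_d[m] = col[k]
        m += 1
    for j in range(1, n + 1):
        new[0] = 0
        tc = t[j - 1]
        for i in range(1, k + 1):
            qc = q[i - 1]
            if qc == tc and qc < 4:
                v = col[i - 1]
            else:
                v = col[i - 1] + 1
            v2 = new[i - 1] + 1
            if v2 < v:
                v = v2
            v3 = col[i] + 1
            if v3 < v:
                v = v3
            new[i] = v
        for i in range(k + 1):
            col[i] = new[i]
        if col[k] <= d:
            out_e[m] = j
            out_d[m] = col[k]
            m += 1
    return out_e[:m], out_d[:m]


@njit(cache=True)
def prefix_profile(q, t):
    """Edit distance of the whole query against every target *prefix*.

    Returns ``row[j] = dist(q, t[0:j])`` for ``j = 0..n`` (global in both, no
    free ends).  Used to recover alignment starts: reversing both query and a
    target slice ending at ``e`` turns "alignments ending at e" into prefix
    alignments.
    """
    k = q.shape[0]
    n = t.shape[0]
    col = np.empty(k + 1, np.int64)
    new = np.empty(k + 1, np.int64)
    row = np.empty(n + 1, np.int64)
    for i in range(k + 1):
        col[i] = i
    row[0] = col[k]
    for j in range(1, n + 1):
        new[0] = j
        tc = t[j - 1]
        for i in range(1, k + 1):
            qc = q[i - 1]
            if qc == tc and qc < 4:
                v = col[i - 1]
            else:
                v = col[i - 1] + 1
            v2 = new[i - 1] + 1
            if v2 < v:
                v = v2
            v3 = col[i] + 1
            if v3 < v:
                v = v3
            new[i] = v
        for i in range(k + 1):
            col[i] = new[i]
        row[j] = col[k]
    return row


@njit(cache=True)
def hamming_scan(q, t, mm):
    """Count forward-strand starts with Hamming distance <= ``mm``.

    N never matches (either side), so positions overlapping N count as
    mismatches.
    """
    k = q.shape[0]
    n = t.shape[0]
    count = 0
    for s in range(n - k + 1):
        bad = 0
        for i in range(k):
            qc = q[i]
            tc = t[s + i]
            if qc != tc or qc >= 4:
                bad += 1
                if bad > mm:
                    break
        if bad <= mm:
            count += 1
    return count


@njit(cache=True)
def hamming_verify_counts(t, qs, cand_q, cand_pos, mm, counts):
    """Verify deduplicated candidate starts; add qualifying starts per query."""
    k = qs.shape[1]
    n = t.shape[0]
    for c in range(cand_q.shape[0]):
        qi = cand_q[c]
        s = cand_pos[c]
        if s < 0 or s + k > n:
            continue
        bad = 0
        for i in range(k):
            qc = qs[qi, i]
            tc = t[s + i]
            if qc != tc or qc >= 4:
                bad += 1
                if bad > mm:
                    break
        if bad <= mm:
            counts[qi] += 1


@njit(cache=True)
def myers4_profile(t, peq, k, d, out_s, out_e, out_d):
    """Bit-parallel per-end distance profile for four patterns at once.

    ``peq`` has shape (4, 5): per state, the match bitmask of each base code
    (code 4, N, must be all-zero so N matches nothing).  Patterns share one
    pass over ``t``; qualifying (state, end, dist) triples are appended to the
    output arrays.  Returns the number of events, or -1 if the buffers would
    overflow (caller retries with larger buffers).
    """
    n = t.shape[0]
    cap = out_e.shape[0]
    one = np.uint64(1)
    mbit = one << np.uint64(k - 1)
    ones = np.uint64(0xFFFFFFFFFFFFFFFF)
    zero = np.uint64(0)

    pv0 = ones
    mv0 = zero
    s0 = k
    pv1 = ones
    mv1 = zero
    s1 = k
    pv2 = ones
    mv2 = zero
    s2 = k
    pv3 = ones
    mv3 = zero
    s3 = k
    m = 0
    for j in range(n):
        c = t[j]

        eq = peq[0, c]
        xv = eq | mv0
        xh = (((eq & pv0) + pv0) ^ pv0) | eq
        ph = mv0 | ~(xh | pv0)
        mh = pv0 & xh
        if ph & mbit:
            s0 += 1
        elif mh & mbit:
            s0 -= 1
        ph = ph << one
        mh = mh << one
        pv0 = mh | ~(xv | ph)
        mv0 = ph & xv

        eq = peq[1, c]
        xv = eq | mv1
        xh = (((eq & pv1) + pv1) ^ pv1) | eq
        ph = mv1 | ~(xh | pv1)
        mh = pv1 & xh
        if ph & mbit:
            s1 += 1
        elif mh & mbit:
            s1 -= 1
        ph = ph << one
        mh = mh << one
        pv1 = mh | ~(xv | ph)
        mv1 = ph & xv

        eq = peq[2, c]
        xv = eq | mv2
        xh = (((eq & pv2) + pv2) ^ pv2) | eq
        ph = mv2 | ~(xh | pv2)
        mh = pv2 & xh
        if ph & mbit:
            s2 += 1
        elif mh & mbit:
            s2 -= 1
        ph = ph << one
        mh = mh << one
        pv2 = mh | ~(xv | ph)
        mv2 = ph & xv

        eq = peq[3, c]
        xv = eq | mv3
        xh = (((eq & pv3) + pv3) ^ pv3) | eq
        ph = mv3 | ~(xh | pv3)
        mh = pv3 & xh
        if ph & mbit:
            s3 += 1
        elif mh & mbit:
            s3 -= 1
        ph = ph << one
        mh = mh << one
        pv3 = mh | ~(xv | ph)
        mv3 = ph & xv

        if s0 <= d or s1 <= d or s2 <= d or s3 <= d:
            if m + 4 > cap:
                return -1
            if s0 <= d:
                out_s[m] = 0
                out_e[m] = j + 1
                out_d[m] = s0
                m += 1
            if s1 <= d:
                out_s[m] = 1
                out_e[m] = j + 1
                out_d[m] = s1
                m += 1
            if s2 <= d:
                out_s[m] = 2
                out_e[m] = j + 1
                out_d[m] = s2
                m += 1
            if s3 <= d:
                out_s[m] = 3
                out_e[m] = j + 1
                out_d[m] = s3
                m += 1
    return m


_PACK_FM = np.uint64(0x7FFFFFFF7FFFFFFF)  # two 31-bit fields, guards 31/63 clear
_PACK_M2 = np.uint64(0x7FFFFFFE7FFFFFFF)  # post-shift mask, also clears bit 32
_PACK_G = np.uint64(0x8000000080000000)


@njit(cache=True)
def myers_packed2(t, p0, p1, k, d, out_s, out_e, out_d):
    """Four pattern states (k <= 31, d < k) in two packed words.

    Each word carries two patterns in 32-bit fields (bits 0.. and 32..) with
    guard bits at 31/63 absorbing addition carries; post-shift masking stops
    bits crossing fields, so both fields evolve exactly as independent Myers
    states.  Scores are packed 32-bit counters biased so that a field's top
    bit is clear exactly when its score is <= d.  Output as in
    :func:`myers4_profile`.
    """
    n = t.shape[0]
    cap = out_e.shape[0]
    one = np.uint64(1)
    sh = np.uint64(k - 1)
    tops = (one << sh) | (one << np.uint64(32 + k - 1))
    halfword = np.uint64(0xFFFFFFFF)
    topbit32 = np.uint64(0x80000000)
    bias = (one << np.uint64(31)) - np.uint64(d + 1)
    sc_init = (np.uint64(k) + bias) | ((np.uint64(k) + bias) << np.uint64(32))
    fm = _PACK_FM
    m2 = _PACK_M2
    g = _PACK_G
    pv0 = fm
    mv0 = np.uint64(0)
    sc0 = sc_init
    pv1 = fm
    mv1 = np.uint64(0)
    sc1 = sc_init
    m = 0
    for j in range(n):
        c = t[j]

        eq = p0[c]
        xv = eq | mv0
        xh = (((eq & pv0) + pv0) ^ pv0) | eq
        ph = mv0 | ~(xh | pv0)
        mh = pv0 & xh
        sc0 += (ph & tops) >> sh
        sc0 -= (mh & tops) >> sh
        ph = (ph << one) & m2
        mh = (mh << one) & m2
        pv0 = (mh | ~(xv | ph)) & fm
        mv0 = ph & xv

        eq = p1[c]
        xv = eq | mv1
        xh = (((eq & pv1) + pv1) ^ pv1) | eq
        ph = mv1 | ~(xh | pv1)
        mh = pv1 & xh
        sc1 += (ph & tops) >> sh
        sc1 -= (mh & tops) >> sh
        ph = (ph << one) & m2
        mh = (mh << one) & m2
        pv1 = (mh | ~(xv | ph)) & fm
        mv1 = ph & xv

        if (sc0 & g) != g or (sc1 & g) != g:
            if m + 4 > cap:
                return -1
            jj = j + 1
            a = sc0 & halfword
            b = sc0 >> np.uint64(32)
            if a < topbit32:
                out_s[m] = 0
                out_e[m] = jj
                out_d[m] = np.int64(a - bias)
                m += 1
            if b < topbit32:
                out_s[m] = 1
                out_e[m] = jj
                out_d[m] = np.int64(b - bias)
                m += 1
            a = sc1 & halfword
            b = sc1 >> np.uint64(32)
            if a < topbit32:
                out_s[m] = 2
                out_e[m] = jj
                out_d[m] = np.int64(a - bias)
                m += 1
            if b < topbit32:
                out_s[m] = 3
                out_e[m] = jj
                out_d[m] = np.int64(b - bias)
                m += 1
    return m


@njit(cache=True)
def cluster_count(ends, half):
    """Number of hit clusters among sorted qualifying end offsets.

    Consecutive qualifying ends within ``half`` bases chain into one cluster:
    a single locus should count once regardless of indel jitter.
    """
    m = ends.shape[0]
    if m == 0:
        return 0
    n = 1
    for i in range(1, m):
        if ends[i] - ends[i - 1] > half:
            n += 1
    return n


@njit(cache=True)
def myers1_window(t, peq, k, d, sa, sb, ev_e, ev_d, m):
    """Single-state Myers profile over ``t[sa:sb]``; appends global ends.

    Returns the new event count, or -1 on buffer overflow.  Requires
    ``k <= 63`` and ``d < k``.
    """
    cap = ev_e.shape[0]
    one = np.uint64(1)
    sh = np.uint64(k - 1)
    ones = np.uint64(0xFFFFFFFFFFFFFFFF)
    pv = ones
    mv = np.uint64(0)
    s = k
    for j in range(sa, sb):
        c = t[j]
        eq = peq[c]
        xv = eq | mv
        xh = (((eq & pv) + pv) ^ pv) | eq
        ph = mv | ~(xh | pv)
        mh = pv & xh
        if ph & (one << sh):
            s += 1
        elif mh & (one << sh):
            s -= 1
        ph = ph << one
        mh = mh << one
        pv = mh | ~(xv | ph)
        mv = ph & xv
        if s <= d:
            if m >= cap:
                return -1
            ev_e[m] = j + 1
            ev_d[m] = s
            m += 1
    return m


@njit(cache=True)
def seeded_cluster_counts(t, qs, peq, grp_lo, grp_hi, cand_s0, k, d, counts, ev_e, ev_d):
    """Per-query cluster counts from pigeonhole seed candidates.

    ``cand_s0`` holds candidate alignment-start centres, grouped per query by
    ``grp_lo``/``grp_hi`` and sorted ascending within each group.  Candidate
    bands ``[s0-d, s0+d]`` are merged into windows, a per-end DP profile is
    run on each window slice (bit-parallel when the pattern fits one word,
    the naive DP otherwise), qualifying ends are deduplicated, and the
    resulting clusters are added into ``counts``.  A query whose event buffer
    would overflow gets ``counts[qi]`` set to -1 so the caller can fall back
    to a full scan.
    """
    n = t.shape[0]
    half = k // 2
    cap = ev_e.shape[0]
    bitpar = k <= 63 and d < k
    for qi in range(qs.shape[0]):
        a = grp_lo[qi]
        b = grp_hi[qi]
        if a >= b:
            continue
        if counts[qi] < 0:
            continue
        q = qs[qi]
        m = 0
        overflow = False
        wlo = cand_s0[a] - d
        whi = cand_s0[a] + d
        c = a + 1
        while True:
            merge_next = False
            if c < b:
                nlo = cand_s0[c] - d
                if nlo - whi <= k:
                    whi = max(whi, cand_s0[c] + d)
                    merge_next = True
            if merge_next:
                c += 1
                continue
            # flush window [wlo, whi] in start space
            sa = wlo
            if sa < 0:
                sa = 0
            sb = whi + k + d
            if sb > n:
                sb = n
            if sa < sb:
                if bitpar:
                    m2 = myers1_window(t, peq[qi], k, d, sa, sb, ev_e, ev_d, m)
                    if m2 < 0:
                        overflow = True
                    else:
                        m = m2
                else:
                    le, ld = naive_profile(q, t[sa:sb], d)
                    for x in range(le.shape[0]):
                        if m >= cap:
                            overflow = True
                            break
                        ev_e[m] = sa + le[x]
                        ev_d[m] = ld[x]
                        m += 1
            if overflow or c >= b:
                break
            wlo = cand_s0[c] - d
            whi = cand_s0[c] + d
            c += 1
        if overflow:
            counts[qi] = -1
            continue
        if m == 0:
            continue
        # dedupe ends (windows can overlap by up to d), then chain-cluster
        order = np.argsort(ev_e[:m], kind="mergesort")
        nclust = 0
        prev_end = np.int64(-1) - half
        for x in range(m):
            e = ev_e[order[x]]
            if e == prev_end:
                continue
            if e - prev_end > half:
                nclust += 1
            prev_end = e
        counts[qi] += nclust


@njit(cache=True)
def rolling_hash(codes, L):
    """Packed 2-bit hash of every L-mer; ``valid[j]`` false if it contains N.

    L must be <= 31 so the hash fits comfortably in uint64.
    """
    n = codes.shape[0]
    nk = n - L + 1
    if nk <= 0:
        return np.empty(0, np.uint64), np.empty(0, np.bool_)
    h = np.empty(nk, np.uint64)
    valid = np.empty(nk, np.bool_)
    mask = (np.uint64(1) << np.uint64(2 * L)) - np.uint64(1)
    cur = np.uint64(0)
    bad = 0  # count of N within current window
    for j in range(L):
        c = codes[j]
        if c >= 4:
            bad += 1
            c = 0
        cur = ((cur << np.uint64(2)) | np.uint64(c)) & mask
    h[0] = cur
    valid[0] = bad == 0
    for j in range(L, n):
        cin = codes[j]
        cout = codes[j - L]
        if cin >= 4:
            bad += 1
            cin = 0
        if cout >= 4:
            bad -= 1
        cur = ((cur << np.uint64(2)) | np.uint64(cin)) & mask
        h[j - L + 1] = cur
        valid[j - L + 1] = bad == 0
    return h, valid


# -- SDUST -----------------------------------------------------------------


@njit(cache=True)
def sdust_cover(codes, W, T10):
    """Mark bases covered by perfect low-complexity intervals.

    An interval ``[i, e)`` of length ``l`` (4 <= l <= W) scores
    ``sum_t c_t (c_t - 1) / 2 / (l - 3)`` over its ``l - 2`` triplet counts
    ``c_t`` (triplets containing N contribute nothing).  It is *perfect* when
    its score exceeds ``T10 / 10`` and no proper subinterval scores strictly
    higher.  The union of perfect intervals is returned as a boolean cover.
    All score comparisons are exact integer cross-multiplications.
    """
    n = codes.shape[0]
    cover = np.zeros(n, np.bool_)
    if n < 4:
        return cover
    ntri = n - 2
    tri = np.empty(ntri, np.int64)
    tvalid = np.empty(ntri, np.bool_)
    for j in range(ntri):
        a = codes[j]
        b = codes[j + 1]
        c = codes[j + 2]
        if a < 4 and b < 4 and c < 4:
            tri[j] = a * 16 + b * 4 + c
            tvalid[j] = True
        else:
            tri[j] = 0
            tvalid[j] = False

    # maxsub rows indexed by offset off = e - i, off in [0, W]
    below_n = np.zeros(W + 1, np.int64)  # numerators for row i+1
    below_d = np.ones(W + 1, np.int64)
    cur_n = np.zeros(W + 1, np.int64)
    cur_d = np.ones(W + 1, np.int64)
    cnt = np.zeros(64, np.int64)

    for i in range(n - 1, -1, -1):
        for off in range(W + 1):
            cur_n[off] = 0
            cur_d[off] = 1
        # incremental triplet counts over e ascending
        for t in range(64):
            cnt[t] = 0
        pairsum = 0
        emax = i + W
        if emax > n:
            emax = n
        for e in range(i + 3, emax + 1):
            j = e - 3  # triplet starting at e-3 enters interval [i, e)
            if tvalid[j]:
                t = tri[j]
                pairsum += cnt[t]
                cnt[t] += 1
            off = e - i
            l3 = off - 3
            if l3 < 1:
                continue
            # rational score = pairsum / l3
            bn = below_n[off - 1]  # maxsub(i+1, e)
            bd = below_d[off - 1]
            ln_ = cur_n[off - 1]  # maxsub(i, e-1)
            ld_ = cur_d[off - 1]
            # perfect: score > T10/10 and score >= both proper-sub maxima
            if (
                10 * pairsum > T10 * l3
                and pairsum * bd >= bn * l3
                and pairsum * ld_ >= ln_ * l3
            ):
                for p in range(i, e):
                    cover[p] = True
            # cur maxsub(i, e) = max(score, below, left)
            mn = pairsum
            md = l3
            if bn * md > mn * bd:
                mn = bn
                md = bd
            if ln_ * md > mn * ld_:
                mn = ln_
                md = ld_
            cur_n[off] = mn
            cur_d[off] = md
        for off in range(W + 1):
            below_n[off] = cur_n[off]
            below_d[off] = cur_d[off]
    return cover
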