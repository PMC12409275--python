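"""Independent brute-force referees used by the test suite.

These deliberately share no code with the package implementation: scores are
recomputed from scratch per interval, representations are enumerated
exhaustively, and alignments are checked per start position.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple


def sdust_brute(seq: str, window: int = 64, score_threshold: int = 20) -> List[Tuple[int, int]]:
    """Enumerate every subinterval up to the window length and merge the
    perfect low-complexity ones.

    Scores are (pair-count, l-3) rationals compared by cross-multiplication,
    recomputed independently for every interval from a fresh triplet count.
    """
    n = len(seq)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    tri: List[Optional[int]] = []
    for j in range(n - 2):
        s3 = seq[j : j + 3]
        if all(ch in code for ch in s3):
            tri.append(code[s3[0]] * 16 + code[s3[1]] * 4 + code[s3[2]])
        else:
            tri.append(None)

    # pair[i][e]: repeated-triplet pairs in [i, e); computed per start with a
    # running counter (fresh per start, so no shared incremental state with
    # the implementation's row recurrences)
    pairs: Dict[Tuple[int, int], int] = {}
    for i in range(n):
        cnt: Dict[int, int] = {}
        acc = 0
        for e in range(i + 3, min(i + window, n) + 1):
            t = tri[e - 3]
            if t is not None:
                acc += cnt.get(t, 0)
                cnt[t] = cnt.get(t, 0) + 1
            pairs[(i, e)] = acc

    def score(i: int, e: int) -> Tuple[int, int]:
        l3 = (e - i) - 3
        if l3 < 1:
            return (0, 1)
        return (pairs[(i, e)], l3)

    def ge(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
        return a[0] * b[1] >= b[0] * a[1]

    # max score over all subintervals of (i, e), via the obvious max identity
    # on the independently computed score table
    maxsub: Dict[Tuple[int, int], Tuple[int, int]] = {}
    for i in range(n - 1, -1, -1):
        for e in range(i + 4, min(i + window, n) + 1):
            best = score(i, e)
            for sub in ((i + 1, e), (i, e - 1)):
                ms = maxsub.get(sub, (0, 1))
                if not ge(best, ms):
                    best = ms
            maxsub[(i, e)] = best

    covered = [False] * n
    for i in range(n):
        for e in range(i + 4, min(i + window, n) + 1):
            sc = score(i, e)
            if not 10 * sc[0] > score_threshold * sc[1]:
                continue
            if not ge(sc, maxsub.get((i + 1, e), (0, 1))):
                continue
            if not ge(sc, maxsub.get((i, e - 1), (0, 1))):
                continue
            for p in range(i, e):
                covered[p] = True
    out: List[Tuple[int, int]] = []
    s = None
    for p, c in enumerate(covered):
        if c and s is None:
            s = p
        elif not c and s is not None:
            out.append((s, p))
            s = None
    if s is not None:
        out.append((s, n))
    return out


def leftmost_minimal_representation(
    ref: str, pos: int, ref_allele: str, alt_allele: str
) -> Tuple[int, str, str]:
    """Enumerate every equivalent (pos, ref, alt) and return the minimal
    leftmost one.

    Two representations are equivalent when substituting them into the
    reference yields the same haplotype.  Minimal means no shared leading or
    trailing base unless one allele would become empty.
    """
    hap = ref[:pos] + alt_allele + ref[pos + len(ref_allele) :]
    best: Optional[Tuple[int, str, str]] = None
    for p in range(len(ref) + 1):
        for rl in range(0, len(ref) - p + 1):
            r = ref[p : p + rl]
            for al in range(0, len(hap) - p + 1):
                a = hap[p : p + al]
                if not r and not a:
                    continue
                if ref[:p] + a + ref[p + rl :] != hap:
                    continue
                if not r or not a:
                    continue  # VCF representations keep both alleles non-empty
                if r == a:
                    continue
                # minimal: no removable shared prefix/suffix
                if len(r) > 1 and len(a) > 1 and (r[0] == a[0] or r[-1] == a[-1]):
                    continue
                cand = (p, r, a)
                if best is None or cand < best:
                    best = cand
    assert best is not None
    return best


def edit_distance(a: str, b: str) -> int:
    """Plain Wagner-Fischer, for small strings."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[lb]
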