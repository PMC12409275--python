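"""Canonical interval-set algebra on 0-based half-open genomic intervals.

Every stage of the masking pipeline trades in the same currency: per-sequence
sorted, disjoint, half-open intervals (the BED convention).  ``IntervalSet``
canonicalises on construction — intervals are sorted and overlapping or
abutting intervals are merged — so set-algebraic identities hold exactly at
base resolution.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Mapping, Tuple

Interval = Tuple[int, int]


class IntervalSet:
    """Sorted, disjoint, 0-based half-open intervals keyed by sequence name.

    Parameters
    ----------
    intervals
        Mapping of ``seq_name -> iterable of (start, end)`` pairs, or an
        iterable of ``(seq_name, start, end)`` triples.  Input intervals may
        overlap or abut; they are merged into canonical form.  Empty sequences
        (no intervals) are dropped.
    """

    __slots__ = ("_ivs",)

    def __init__(self, intervals: Mapping[str, Iterable[Interval]] | Iterable[Tuple[str, int, int]] | None = None):
        per_seq: Dict[str, List[Interval]] = {}
        if intervals is None:
            pass
        elif isinstance(intervals, Mapping):
            for name, ivs in intervals.items():
                per_seq.setdefault(str(name), []).extend((int(s), int(e)) for s, e in ivs)
        else:
            for name, s, e in intervals:
                per_seq.setdefault(str(name), []).append((int(s), int(e)))
        self._ivs: Dict[str, List[Interval]] = {}
        for name in sorted(per_seq):
            merged = _merge(per_seq[name])
            if merged:
                self._ivs[name] = merged

    # -- accessors ---------------------------------------------------------

    @property
    def seq_names(self) -> List[str]:
        return list(self._ivs)

    def intervals(self, seq_name: str) -> List[Interval]:
        """Intervals of one sequence (empty list if the sequence is absent)."""
        return list(self._ivs.get(seq_name, []))

    def items(self) -> Iterator[Tuple[str, List[Interval]]]:
        for name, ivs in self._ivs.items():
            yield name, list(ivs)

    @property
    def total_length(self) -> int:
        return sum(e - s for ivs in self._ivs.values() for s, e in ivs)

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self._ivs.values())

    def __bool__(self) -> bool:
        return bool(self._ivs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._ivs == other._ivs

    def __hash__(self) -> int:
        return hash(tuple((n, tuple(ivs)) for n, ivs in self._ivs.items()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(f"{n}:{len(v)}iv" for n, v in self._ivs.items())
        return f"IntervalSet({parts or 'empty'}, {self.total_length} bp)"

    def to_dict(self) -> Dict[str, List[Interval]]:
        return {n: list(v) for n, v in self._ivs.items()}


def _merge(ivs: List[Interval]) -> List[Interval]:
    """Sort and merge overlapping/abutting intervals; reject degenerate ones."""
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"degenerate interval ({s}, {e}): start must be < end")
        if s < 0:
            raise ValueError(f"negative interval start {s}")
    out: List[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


# -- set algebra -----------------------------------------------------------


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    d = a.to_dict()
    for name, ivs in b.items():
        d.setdefault(name, []).extend(ivs)
    return IntervalSet(d)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    out: List[Tuple[str, int, int]] = []
    for name, ivs_a in a.items():
        ivs_b = b.intervals(name)
        if not ivs_b:
            continue
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            s = max(ivs_a[i][0], ivs_b[j][0])
            e = min(ivs_a[i][1], ivs_b[j][1])
            if s < e:
                out.append((name, s, e))
            if ivs_a[i][1] < ivs_b[j][1]:
                i += 1
            else:
                j += 1
    return IntervalSet(out)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base positions of ``a`` not in ``b``."""
    out: List[Tuple[str, int, int]] = []
    for name, ivs_a in a.items():
        ivs_b = b.intervals(name)
        j = 0
        for s, e in ivs_a:
            cur = s
            while j < len(ivs_b) and ivs_b[j][1] <= cur:
                j += 1
            jj = j
            while jj < len(ivs_b) and ivs_b[jj][0] < e:
                bs, be = ivs_b[jj]
                if bs > cur:
                    out.append((name, cur, bs))
                cur = max(cur, be)
                if cur >= e:
                    break
                jj += 1
            if cur < e:
                out.append((name, cur, e))
    return IntervalSet(out)


def complement(x: IntervalSet, seq_lengths: Mapping[str, int]) -> IntervalSet:
    """Per-sequence set complement within ``[0, length)``.

    Sequences named in ``seq_lengths`` but absent from ``x`` contribute their
    whole span.  An interval of ``x`` exceeding its sequence length, or on a
    sequence without a declared length, is a consistency error.
    """
    out: List[Tuple[str, int, int]] = []
    for name in x.seq_names:
        if name not in seq_lengths:
            raise ValueError(f"no length given for sequence {name!r}")
    for name, length in seq_lengths.items():
        length = int(length)
        cur = 0
        for s, e in x.intervals(name):
            if e > length:
                raise ValueError(
                    f"interval ({s}, {e}) on {name!r} exceeds sequence length {length}"
                )
            if s > cur:
                out.append((name, cur, s))
            cur = e
        if cur < length:
            out.append((name, cur, length))
    return IntervalSet(out)


def length_filter(x: IntervalSet, min_len: int) -> IntervalSet:
    """Keep intervals with ``end - start >= min_len`` (boundary inclusive)."""
    return IntervalSet(
        (name, s, e) for name, ivs in x.items() for s, e in ivs if e - s >= min_len
    )


def containment_fraction(inner: IntervalSet, outer: IntervalSet) -> float:
    """Fraction of ``inner`` bases that lie inside ``outer``; 0/0 is 1.0."""
    denom = inner.total_length
    if denom == 0:
        return 1.0
    return intersect(inner, outer).total_length / denom
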