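"""Symmetric DUST (SDUST) low-complexity detection.

The score of an interval of length ``l`` is the number of repeated-triplet
pairs, ``sum_t c_t (c_t - 1) / 2`` over its ``l - 2`` overlapping triplets,
divided by ``l - 3``.  Following the SDUST convention the threshold is
scaled by ten: an interval is low-complexity when its score exceeds
``score_threshold / 10``.  The mask is the union of *perfect* intervals —
low-complexity intervals, at most ``window`` bases long, no proper
subinterval of which scores strictly higher — so a reported tract cannot be
narrowed to a denser core.  Triplets containing N carry no score.  All score
comparisons are exact integer arithmetic, so results are deterministic and
shift-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from . import _kernels as K
from .intervals import IntervalSet
from .io import GenomeSequence


@dataclass(frozen=True)
class SdustParams:
    """SDUST configuration: sliding window length and scaled score threshold."""

    window: int = 64
    score_threshold: int = 20

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")


def sdust_mask(seq: GenomeSequence, s: SdustParams | None = None) -> IntervalSet:
    """Low-complexity intervals of one sequence as a canonical IntervalSet."""
    if s is None:
        s = SdustParams()
    codes = K.encode(seq.bases)
    cover = K.sdust_cover(codes, s.window, s.score_threshold)
    return IntervalSet(
        (seq.seq_name, int(st), int(en)) for st, en in _runs(cover)
    )


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (start, end) pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))
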