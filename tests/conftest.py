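"""Shared fixtures: small deterministic genomes and pangenomes."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test-side oracle helpers

from panmask import GenomeSequence, PangenomeSet

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[c] for c in rng.integers(0, 4, n))


def make_genome(bases: str, genome_id: str = "g", seq_name: str = "chr1") -> GenomeSequence:
    return GenomeSequence(genome_id, seq_name, bases)


def clone_pangenome(ref_bases: str, n_others: int, seq_name: str = "chr1") -> PangenomeSet:
    """A pangenome of identical genomes — every reference k-mer has exactly
    one hit per genome."""
    ref = GenomeSequence("ref", seq_name, ref_bases)
    others = tuple(
        (GenomeSequence(f"hap{i+1}", seq_name, ref_bases),) for i in range(n_others)
    )
    return PangenomeSet(reference=(ref,), others=others)


@pytest.fixture()
def rng(request):
    # per-test deterministic stream, independent of execution order
    import zlib

    return np.random.default_rng(zlib.crc32(request.node.name.encode()))


def mutate(rng: np.random.Generator, bases: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct random positions."""
    out = list(bases)
    pos = rng.choice(len(bases), size=n_subs, replace=False)
    for p in pos.tolist():
        old = out[p]
        out[p] = BASES[(BASES.index(old) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def revcomp(bases: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(bases))
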