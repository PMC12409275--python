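"""Reading and writing the standard formats the pipeline touches.

One coordinate convention everywhere: 0-based half-open, the BED convention.
VCF positions are converted on ingest.  Sequences are uppercased and IUPAC
ambiguity codes are mapped to ``N`` so that downstream stages only ever see
the alphabet ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, List, Sequence, Tuple

from Bio import SeqIO

from .intervals import IntervalSet

_VALID = set("ACGTN")
# uppercase, then anything outside ACGT becomes N (IUPAC ambiguity codes,
# gaps from assembly pipelines, stray characters)
_CLEAN = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in map(chr, range(256))}
)


class FormatError(ValueError):
    """A file did not parse as the expected format."""


class ConsistencyError(ValueError):
    """Input records disagree with the reference sequence they refer to."""


def clean_bases(raw: str) -> str:
    """Uppercase and map every non-ACGT character to N."""
    return raw.upper().translate(_CLEAN)


@dataclass(frozen=True)
class GenomeSequence:
    """One named DNA sequence of one genome, over the alphabet ACGTN."""

    genome_id: str
    seq_name: str
    bases: str

    def __post_init__(self) -> None:
        if not set(self.bases) <= _VALID:
            object.__setattr__(self, "bases", clean_bases(self.bases))

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class VariantRecord:
    """Minimal variant: 0-based position of the first REF base, REF, ALTs."""

    seq_name: str
    pos: int
    ref: str
    alts: Tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alts", tuple(self.alts))
        if not self.ref or any(not a for a in self.alts):
            raise ValueError("ref and alt alleles must be non-empty")
        if any(a == self.ref for a in self.alts):
            raise ValueError("every alt must differ from ref")

    @property
    def end(self) -> int:
        """End (exclusive) of the reference footprint ``[pos, pos+len(ref))``."""
        return self.pos + len(self.ref)


# -- FASTA -----------------------------------------------------------------


def _maybe_gzip(path: str | os.PathLike) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | os.PathLike, genome_id: str | None = None) -> List[GenomeSequence]:
    """Read a plain or gzipped FASTA file into ``GenomeSequence`` records.

    The header token before the first whitespace becomes ``seq_name``; the
    genome id defaults to the file stem.
    """
    if genome_id is None:
        name = Path(path).name
        for suf in (".gz", ".fa", ".fasta", ".fna"):
            if name.endswith(suf):
                name = name[: -len(suf)]
        genome_id = name
    out: List[GenomeSequence] = []
    with _maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: FASTA record with empty header")
            if len(rec.seq) == 0:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            out.append(GenomeSequence(genome_id, rec.id, clean_bases(str(rec.seq))))
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for gs in seqs:
            fh.write(f">{gs.seq_name}\n")
            for i in range(0, gs.length, width):
                fh.write(gs.bases[i : i + width] + "\n")


# -- BED -------------------------------------------------------------------


def read_bed(path: str | os.PathLike) -> IntervalSet:
    """Read BED3 into a canonical ``IntervalSet`` (extra columns ignored)."""
    triples: List[Tuple[str, int, int]] = []
    with _maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            triples.append((fields[0], start, end))
    return IntervalSet(triples)


def write_bed(intervals: IntervalSet, path: str | os.PathLike) -> None:
    """Write BED3, sorted by sequence name then start."""
    with open(path, "wt") as fh:
        for name, ivs in intervals.items():
            for s, e in ivs:
                fh.write(f"{name}\t{s}\t{e}\n")


# -- VCF -------------------------------------------------------------------


def read_vcf_minimal(path: str | os.PathLike) -> List[VariantRecord]:
    """Read CHROM/POS/REF/ALT from a VCF; FILTER and genotypes are ignored.

    POS is converted to 0-based.  Records without a concrete ALT allele and
    symbolic/star alleles are skipped.
    """
    import pysam

    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a parseable VCF: {exc}") from exc
    out: List[VariantRecord] = []
    with vf:
        for rec in vf:
            if rec.alts is None:
                continue
            alts = tuple(
                a for a in rec.alts if a and a != "*" and not a.startswith("<")
            )
            alts = tuple(a for a in alts if a != rec.ref)
            if not alts:
                continue
            out.append(VariantRecord(rec.chrom, rec.start, rec.ref, alts))
    return out


def write_vcf_minimal(
    variants: Sequence[VariantRecord],
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write sites-only VCF 4.2 (no genotypes), positions converted to 1-based."""
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.seq_name, v.pos)):
            fh.write(
                f"{v.seq_name}\t{v.pos + 1}\t.\t{v.ref}\t{','.join(v.alts)}\t.\t.\t.\n"
            )


# -- variant normalization -------------------------------------------------


def normalize_variant(v: VariantRecord, ref_seq: GenomeSequence) -> VariantRecord:
    """Left-align and trim a variant against its reference sequence.

    Shared trailing bases are removed (extending left through the reference
    when an allele would empty), then shared leading bases are removed with
    the position advanced.  The operation is idempotent and preserves the
    edited haplotype sequence.
    """
    if v.seq_name != ref_seq.seq_name:
        raise ConsistencyError(
            f"variant on {v.seq_name!r} normalized against {ref_seq.seq_name!r}"
        )
    bases = ref_seq.bases
    if bases[v.pos : v.pos + len(v.ref)] != v.ref:
        raise ConsistencyError(
            f"REF {v.ref!r} at {v.seq_name}:{v.pos} disagrees with reference "
            f"{bases[v.pos : v.pos + len(v.ref)]!r}"
        )
    pos = v.pos
    alleles = [v.ref, *v.alts]
    while True:
        last = {a[-1] for a in alleles}
        if len(last) == 1:
            if all(len(a) > 1 for a in alleles):
                alleles = [a[:-1] for a in alleles]
                continue
            if pos > 0:
                prev = bases[pos - 1]
                alleles = [prev + a[:-1] for a in alleles]
                pos -= 1
                continue
        break
    while all(len(a) > 1 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    return VariantRecord(v.seq_name, pos, alleles[0], tuple(alleles[1:]))


def apply_variant(bases: str, v: VariantRecord, alt_index: int = 0) -> str:
    """Return the haplotype obtained by substituting one ALT for REF."""
    return bases[: v.pos] + v.alts[alt_index] + bases[v.pos + len(v.ref) :]
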