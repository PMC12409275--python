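# panmask

Pangenome-aware **easy regions** for short-read variant calling.

Variant-calling benchmarks report error rates well under 1% — but only
inside curated confident regions. For a sample without such regions, a
genome-wide callset can be an order of magnitude worse. *Easy regions* are
sample-agnostic intervals where generic short-read callers reach high
accuracy, used to filter spurious calls in repeats, segmental duplications
and other hard loci. Reference-only mappability tracks miss a crucial case:
loci unique in the reference but duplicated in other individuals, whose
paralog-specific differences pile up as false variants at the unique
reference copy.

`panmask` derives easy regions from a collection of genome assemblies. With
*N* genomes (reference included), a reference k-mer is **sufficiently
unique** iff

1. it has exactly **1** hit within edit distance *d₁* in the reference
   genome, and
2. it has **< c·N** hits within edit distance *d₂* across all *N* genomes,
   with *d₂ > d₁* and *c > 1* the tolerance for copy-number gains.

One k-mer is sampled every *w* bases; each failing k-mer masks `[i, i+k)`.
The complement — minus an exact ungapped Hamming rescue filter on the
reference (≤ 3 mismatches) and a 50 bp minimum-length filter — is the
**lenient** easy set. Subtracting SDUST low-complexity tracts longer than
18 bp (where indel errors concentrate) gives the **strict** set, always a
subset of the lenient one. Defaults follow read-length-scale practice:
`k=151, w=10, c=1.01, d1=3, d2=7`.

The method's documented blind spot is reproduced, not hidden: a segment
deleted in some genomes but duplicated in others can keep its total hit
count below *c·N* and stay unmasked.

All hit counting here is **exact**: a pigeonhole-seeded index (split the
k-mer into *d+1* pieces; any alignment within *d* edits contains one piece
unedited) localises candidates, which are verified with bit-parallel
dynamic programming. An independent full-scan DP referee recomputes masks
from scratch in the test suite.

## Worked example

Simulate a pangenome with a planted segmental duplication, derive regions,
and evaluate a callset:

```sh
cat > sim.yaml <<EOF
seed: 3
ref_len: 4000
n_haplotypes: 3
snv_rate: 0.001
indel_rate: 0.0002
duplications:
  - {src_start: 1200, length: 300, n_copies: 1, carrier_haplotype_count: 2, divergence: 0.01}
lcr_tracts:
  - {start: 3000, motif: AT, repeat_count: 20}
EOF
panmask simulate --config sim.yaml --out-dir fx/
panmask mask --ref fx/ref.fa --pan fx/hap1.fa,fx/hap2.fa,fx/hap3.fa \
    -k 31 -w 5 -c 1.01 --d1 1 --d2 3 --hamming 3 --min-len 50 -o lenient.bed
panmask strict --ref fx/ref.fa --lenient lenient.bed --max-lcr 18 -o strict.bed
panmask eval accuracy --calls fx/truth.vcf --truth fx/truth.vcf \
    --regions lenient.bed --ref fx/ref.fa
```

The `mask` step logs the masked fraction per sequence, and the resulting
BED shows exactly what was excluded:

```
[mask] chr1: masked 357/4000 bp (8.92%)
$ cat lenient.bed
chr1    0       1195
chr1    1501    2995
chr1    3046    4000
```

The hole at 1195–1501 is the planted 300 bp duplication plus k-mer overlap
flanks: its k-mers occur once in the reference and once more in each of the
two carrier haplotypes, 6 hits ≥ c·N = 4.04, so condition 2 masks them.
The hole at 2995–3046 is the 40 bp AT tract, dropped by the Hamming rescue
filter (a repeat of period 2 matches itself exactly when shifted). The
`eval` step prints `tp 18`, `fdr 0.000000`, `fnr 0.000000`, as a callset
compared against itself must.

The same objects are available as a library:

```python
from panmask import (SimConfig, Duplication, simulate_pangenome,
                     UniquenessParams, lenient_regions)
pg, truth = simulate_pangenome(SimConfig(seed=3, ref_len=4000, n_haplotypes=3))
easy = lenient_regions(pg, UniquenessParams(k=31, w=5, c=1.01, d1=1, d2=3))
```

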