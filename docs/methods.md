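# Methods

## The sufficient-uniqueness model

`panmask` treats short-read mappability as a property of a k-mer against a
*pangenome*: the reference plus the assemblies of other individuals.  With
N genomes (reference included), a reference k-mer is sufficiently unique
when

1. **reference uniqueness** — it has exactly one hit within edit distance
   d₁ in the reference genome (that hit being its own locus).  If the
   second-best reference hit is more than d₁ edits away, reads carrying a
   few errors or variants still map to the right place;
2. **pangenome copy number** — it has fewer than c·N hits within edit
   distance d₂ (d₂ > d₁) across all genomes.  A locus unique in the
   reference but carrying extra paralogous copies in other individuals
   attracts those copies' reads, and paralog-specific differences surface
   as false variants; c > 1 tolerates ordinary copy-number gains (one hit
   per genome plus slack).

One k-mer is sampled every w bases (plus a forced final k-mer so sequence
tails are always assessed); a failing k-mer masks `[i, i+k)`.  The
complement of the mask is post-processed into two tracks:

* **lenient** = complement − Hamming rescue − short fragments.  The rescue
  filter drops the window of any sampled k-mer with ≥ 2 exact ungapped
  matches within 3 mismatches on the reference forward strand.  It mirrors
  exact mappability tools and catches what edit-distance *clustering*
  deliberately blurs: inside a long tandem repeat, shifted self-matches
  chain into a single hit cluster and would otherwise look unique.
  Fragments shorter than 50 bp are removed to reduce fragmentation.
* **strict** = lenient − SDUST low-complexity intervals longer than 18 bp,
  with the 50 bp filter re-applied after subtraction.  Indel errors
  concentrate in low-complexity sequence; the strict track trades a little
  coverage for easier calling.  By construction strict ⊆ lenient.

**Known limitation (by design).** A segment deleted in some genomes and
duplicated in others can keep its total hit count below c·N; condition 2
then never sees the duplication and the segment stays unmasked.  The test
suite asserts this miss rather than hiding it.

### What one "hit" is

Alignment is end-to-end for the k-mer (no clipping) against a target
substring, on both strands; `N` matches nothing.  Because indels jitter
alignment coordinates, qualifying per-end positions within ⌊k/2⌋ bases on
the same strand of the same sequence are collapsed into one hit, reported
at the minimal distance (ties: leftmost start).  One locus therefore counts
once.  The Hamming rescue filter counts raw ungapped starts, deliberately
without clustering.  The `< c·N` comparison is evaluated in exact rational
arithmetic so a count exactly on the boundary always masks.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 151 bp | k-mer length; matches common short-read lengths |
| w | 10 bp | sampling stride; the final k-mer is always added |
| c | 1.01 | copy-gain tolerance in condition 2 (strict `< c·N`) |
| d₁ | 3 edits | reference-uniqueness bound |
| d₂ | 7 edits | pangenome bound, d₂ > d₁ |
| Hamming max | 3 | rescue filter mismatch bound (forward strand, ungapped) |
| min region | 50 bp | minimum emitted easy-region length (inclusive) |
| max LCR | 18 bp | longest low-complexity tract tolerated in strict regions |
| SDUST window / threshold | 64 / 20 | scoring window and ×10-scaled score threshold |

Tests and the acceptance script that run at k=31 scale the edit bounds
proportionally (d₁=1, d₂=3 ≈ the same edits-per-base as 3/151 and 7/151);
sensitivity analyses around c and d₂ only assert directions (larger c can
only grow the easy set; larger d₂ or d₁ can only shrink it).

## Exact approximate matching

Three engines compute per-end distance profiles (for each target position,
the minimal edits of an end-to-end alignment ending there); all agree
exactly and are cross-checked in the tests:

* a textbook O(n·k) semi-global DP — the referee everything else is
  validated against;
* Myers bit-parallel scans: an interleaved four-state kernel (k ≤ 63) and
  a packed two-patterns-per-word kernel (k ≤ 31) whose 32-bit fields are
  isolated by guard bits and post-shift masks.  These power the
  independent full-scan mask referee;
* a pigeonhole-seeded index: the query is split into d+1 disjoint pieces;
  any alignment within d edits contains at least one piece unedited, so
  exact lookups of piece hashes (sorted 2-bit-packed L-mer tables, built
  lazily per seed length) localise every candidate diagonal band.  Merged
  candidate windows are verified with a windowed profile, qualifying ends
  are deduplicated, and clusters are counted.  When the implied seed would
  be shorter than 4 bp (small k with large d) the index falls back to a
  full scan; counts are identical either way.

The production mask uses the seeded index; `expected_mask_oracle`
recomputes masks with the full-scan kernels over the concatenation of all
genomes (separated by N runs longer than d₂, so no alignment bridges two
sequences).  The two routes share no candidate logic, which is what the
mask-equality acceptance test exercises.  Complete-search guarantees here
are strictly stronger than heuristic aligner-based pipelines: a hit can
never be missed at the scales this package supports, so if anything this
masks slightly more than a heuristic search would, never less.

## SDUST formalization

The score of an interval of length l (4 ≤ l ≤ window) is
`Σ_t c_t(c_t−1)/2 / (l−3)` over its l−2 overlapping triplet counts;
triplets containing N contribute nothing.  An interval is low-complexity
when its score exceeds threshold/10, and *perfect* when additionally no
proper subinterval scores strictly higher — a reported tract cannot be
narrowed to a denser core.  The emitted mask is the union of perfect
intervals.  All comparisons are integer cross-multiplications, so results
are deterministic and shift-invariant.  The exact window/threshold pair
behind published strict tracks is not fixed by the method; the defaults
(64, 20) follow the original SDUST description and are exposed on the CLI.

## The synthetic pangenome

`simulate_pangenome` emulates the role of a collection of high-quality
haplotype assemblies.  From one integer seed: a uniform-random ACGT
reference (planted low-complexity tracts overwrite it at declared
positions); each haplotype applies Bernoulli SNVs (default 10⁻³/bp, about
the heterozygosity scale of a human genome against a reference) and short
indels (2×10⁻⁴/bp, geometric lengths p=0.5 capped at 10 bp so planted
variation stays well inside the d₂ regime the method reasons about);
planted segmental duplications insert diverged copies of a reference
segment into configured numbers of carrier haplotypes; the blind-spot case
deletes a segment in some haplotypes while duplicating it exactly once in
others.  Every edit is recorded in a truth ledger (haplotypes are
reconstructable from it exactly; small variants are also emitted as
normalized VCF-style records), and small variants are kept clear of
planted features so hit-count arithmetic on features is exact.

What it does *not* emulate — and hence what green tests do not show about
real data: realistic mutation spectra and recombination, assembly errors
and gaps, GC- or context-dependent error processes, structural variation
beyond tandem/dispersed duplications, and real intergenomic divergence
structure.  The generator validates that planted features stay in bounds
and never overlap.

## Evaluation metrics

Coverage of interval targets is `|targets ∩ regions| / |targets|`; variant
coverage and density use a whole-footprint rule (`[pos, pos+len(ref))`
inside the regions — a variant straddling a hard-region boundary is not
safely callable and counts as uncovered).  Callset accuracy restricts both
sets to in-region footprints and matches normalized (seq, pos, REF, ALT)
allele pairs with genotypes discarded entirely; FDR = FP/(TP+FP),
FNR = FN/(TP+FN), both defined as 0 on empty denominators.  Matching is
exact-normalized-allele, not haplotype-aware: clusters of jointly
equivalent records (e.g. an MNP represented as two SNVs against a complex
ALT) are not reconciled.  The synthetic callsets used in tests avoid such
clusters, where the two notions coincide.  Empty target sets yield an
explicit no-target outcome (`None`), never a silent 0.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; VCF positions convert on
  ingest; only BED3 is emitted.  Interval sets are canonical (sorted,
  disjoint, abutting intervals merged) and all algebra is exact at base
  resolution.
* IUPAC ambiguity codes map to N on ingest; k-mers containing N are never
  sufficiently unique, and N-runs in targets generate no hits — assembly
  gaps must not look easy.
* Sequences shorter than k are wholly masked (unassessable is not easy).
* Whether the published pipeline re-applies the 50 bp filter after LCR
  subtraction, or applies its exact-match rescue to all rather than
  sampled k-mers, is not specified at this level of detail; this
  implementation re-applies the filter (fragmentation is the filter's
  point) and applies the rescue to sampled k-mers (the same grid the mask
  is built on).
* Problem sizes in tests: the mask-referee comparison runs twenty 50–72 kb
  ten-genome fixtures at k=31/w=5; index-vs-DP equivalence runs ~200
  instances at 2–5 kb across k ∈ {21, 31, 151}, d ∈ 0..7; SDUST agreement
  runs 100 random kilobases.  These sizes make the exhaustive referees
  exact yet quick on a single core.

## Limitations

Desk-scale only: no BWT/FM index, no multithreading, genomes are held in
memory (the exact-search guarantee is the point, not throughput).  The
Hamming rescue filter follows mappability-tool convention on the forward
strand; hit clustering resolution is ⌊k/2⌋ — two qualifying loci closer
than that on the same strand count once.  Evaluation is not a vcfeval
replacement on real callsets with complex-region representations.
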