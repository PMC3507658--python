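# Methods

This note documents the model, the algorithmic choices that were genuinely
open, the synthetic-data generator, and the numerical conventions.  All
empirical statements here are recomputed by the test suite or the examples;
nothing is quoted from elsewhere.

## Window model

A window instance consists of the diseased genotype segments `D^R` and the
normal segments `N^R` on a span of `L` sites (codes 0/1/2).  Segments within
one set are kept pairwise distinct (identical genotypes can always be phased
identically, so duplicates add no information); the scanner deduplicates per
status group and maps results back to individuals.  The same segment may
appear in both sets.

The solution is a *center* haplotype plus a haplotype pair per segment with
(1) diseased first-haplotypes equal to the center, (2) no normal haplotype
equal to the center, (3) heuristically few distinct haplotypes.  Outcomes:

* **Type I false** — some position carries both a homozygous-0 and a
  homozygous-1 diseased genotype.  This classification is exact (it depends
  only on a direct scan of the diseased segments); the suite verifies it
  exhaustively for `L ≤ 4`, up to 3 individuals.
* **Type II false** — a center exists but the heuristic cannot phase every
  normal away from it.  This direction is *not* guaranteed complete: the
  solver commits to merges ("use the earliest compatible class") and may
  declare Type II on instances that a different merge order could solve.
  The parsimony-bound test records, rather than asserts, agreement with the
  brute-force feasibility oracle.
* **TRUE** — a fully resolved phasing satisfying (1), (2) and rules C1/C2,
  asserted on every TRUE outcome in a 10,000-case fuzz.

### Determinism conventions

Wherever the procedure says "arbitrarily choose", a fixed rule is used so
that identical inputs give identical outputs:

* the queue of known haplotypes is FIFO; unsolved normals are scanned in
  input order;
* a newly inferred haplotype merges into the earliest-created compatible
  class still queued, else is appended;
* the sharing-pair step takes the lexicographically first feasible pair (by
  input order); if committing that pair's haplotypes produces a propagation
  contradiction, the next pair is tried;
* a propagation contradiction while solving one genotype is treated as
  "this haplotype cannot solve that genotype" (the attempt is rolled back
  and the search continues) rather than abandoning the window.

Two slots of one segment are never merged into the same identity class when
the segment has a heterozygous site (the pair must differ there).

### Wild-card resolution and DH

Positions left undetermined after solving are fixed deterministically:
classes resolve in creation order, center first; each wild card takes the
majority determined allele at that position over all 2n slots, ties to 0.
Two guards apply during resolution:

* a class containing a normal slot that still matches the center everywhere
  determined takes the *opposite* of the center's allele at its first free
  position; if it nevertheless resolves equal to the center, the window is
  Type II false.  Without this guard, majority filling could silently
  violate condition (2).
* heuristic merges can commit the class graph to an odd-parity cycle of
  complement constraints with no consistent assignment at a wild-card
  position; if neither allele can be propagated, the window is declared
  Type II false (the heuristic found no valid phasing).  This is rare and
  only observed on adversarial random instances.

`DH` is the number of distinct fully resolved haplotypes over all slots;
the center is counted through the diseased slots that carry it.  Identity
of partially determined haplotypes is *structural* (same class) or
value-wise on fully determined sequences; equal-looking patterns with wild
cards are not identified, since resolution may legitimately separate them.

The "unsolvable leftovers" step phases each remaining normal greedily,
creating a determined mismatch with the center as early as possible; it
needs either one homozygous mismatch (covers both haplotypes) or two
heterozygous sites with determined center (one per haplotype), else the
window is Type II false.  Wild-card center positions are not counted as
potential mismatches — a deliberate conservatism, since their eventual
value is not controlled by that segment.

## Chromosome scan

Windows of `L = 500` sites (default; the final short window is scanned like
any other so telomeric regions are not lost).  Valid windows merge across
gaps of at most `2L` sites when every tiling window in the gap is Type II
false; the gap measure is the site count between span end and next span
start.  Merged spans are re-solved at ±0.5L, ±0.2L and exact widths,
longest first, keeping the first that solves; a span none of whose
candidates re-validates is dropped with a warning (merging is
order-dependent, so re-validation of the merged span is expected but not
guaranteed).

Extension groups the resolved haplotypes into identity classes of equal
sequences and annexes flanking positions one at a time: a homozygous member
forces the class allele, forced alleles propagate through complements to a
fixpoint, a contradiction stops the direction and excludes the position.
Only conflict checks apply during extension — a normal class may come to
match the center on the annexed run; regions where that happens carry a
flag (`normal_matches_center_in_extension`) rather than being rejected.
An individual whose two haplotypes are identical on the window occupies one
class; a heterozygous flanking site in such an individual is therefore a
conflict (the single class cannot take both alleles), which bounds
extension conservatively.

`DH` for scoring an extended region is recomputed by re-solving the full
extended span; if that fails (extension applies weaker checks), the refined
window's DH is kept and the event logged.  All regions are reported, sorted
by descending score, ties stable.  An optional post-processor
(`bridge_gap = B`, default off) merges reported regions separated by at
most B sites — the manual step of reading an isolated conflicting site
inside an otherwise shared region as a genotyping error; detection itself
never bridges.

Coordinates: user-facing bounds are 1-based inclusive SNP ordinals,
internal spans 0-based half-open, converted by one audited function pair.
After missing-data removal sites are re-indexed 1..S′ by default (the frame
in which results on cleaned data are naturally indexed); the pre-filter
frame is available with `report_original_index`.

## Simulator

The generator emulates the study conditions end to end:

* **Founders.**  Each founder haplotype is a mosaic over a shared ancestral
  pool: per-site allele frequencies ~ Uniform(0.05, 0.95), pool of 24
  haplotypes, mosaic switch probability 0.002 per site (expected donor
  segment ≈ 500 sites), giving local LD comparable to dense SNP panels.
  The pool size matters: with a small pool, two unrelated founder
  haplotypes are too often identical by state over multi-hundred-site runs,
  which contradicts the premise that the mutant segment is unique to the
  carrier lineage; 24 makes such coincidences rare while keeping realistic
  LD.  When a coincidence does occur (no shared region contains the
  mutation site), the replicate raises a `SimulationError` and is excluded
  with a logged count rather than silently producing an inconsistent truth.
* **Recombination.**  The χ² interference model: chiasmata are every
  (m+1)-th event of a Poisson process of rate 2(m+1) per Morgan on the
  four-strand bundle (stationary via a uniform random phase), each retained
  on the sampled gamete with probability 1/2; `m = 4` by default, `m = 0`
  recovers Haldane.  The retained intensity is 1 per Morgan for every m
  (map-length conservation, Monte-Carlo checked).  No explicit chromatid
  bookkeeping: chiasma thinning is statistically equivalent for
  single-gamete output and much simpler.
* **Genetic map.**  Default uniform 1 cM per 1,000 sites — the density
  regime of a high-density human SNP panel (order 10⁵ sites on a chromosome
  of a few Morgans), so a 500-site window spans ~0.5 cM.  Desk-scale runs
  use 5,000 sites ≈ 5 cM.  A real map can be loaded from TSV.
* **Forced transmission.**  One diseased member without a diseased parent
  (validated unique) originates the mutant haplotype; at each transmission
  from a carrier parent the gamete's starting strand is flipped, if needed,
  so the allele passed *at the mutation site* descends from the mutant
  strand iff the child is diseased.  Only the strand label is conditioned —
  the crossover pattern is untouched — so the conditioning is exact and the
  recombination law exact everywhere.  A parent carrying two mutant copies
  makes forcing ill-defined and is rejected at validation.
* **Truth regions.**  Shared mutation regions are computed exactly: for
  each of the 2^k diseased-haplotype choices, the maximal agreement runs in
  which every normal haplotype mismatches at least once, reduced to the
  inclusion-maximal set (verified against interval-by-interval brute force).
  The true region is the largest shared region containing the mutation site
  (longest, then leftmost, if several overlap it).

What the generator does **not** emulate: genotyping error, phenocopies,
incomplete penetrance, sex-specific maps, population admixture, and real
LD block structure.  Passing tests therefore demonstrate correctness of the
algorithmics and robust behaviour under idealized inheritance, not
performance on noisy panel data; the missing-data filter and the
`bridge_gap` post-processor are the only error-handling facilities.

## Evaluation

Precision/recall are SNP-count overlaps of the top-k reported regions
(k = 1 and 3, ties in score broken by leftmost start) with the true region;
the primed variants replace the true region by the union of all shared
regions — the union, not the best match, which is the reading under which
precision′ ≥ precision always holds.  Replicate seeds are spawned from one
master seed (`numpy.random.SeedSequence`), making batches reproducible;
means are reported both counting empty reports as zeros and excluding them.

## Problem sizes used by the tests

Exhaustive oracle checks run at window length ≤ 4 with ≤ 3 individuals
(every genotype assignment), fuzz checks at length ≤ 8 with ≤ 5 individuals
(10,000 instances), the parsimony bound at length ≤ 6 with ≤ 4 individuals
(1,000 instances against exhaustive phasing enumeration).  End-to-end
recovery uses a five-generation, ten-individual pedigree at 5,000 sites and
50 replicates; a smoke test exercises a full 110,000-site chromosome.
These sizes keep the whole suite in a few minutes while covering every code
path; the statistics of interest (hit rate, recall ordering, crossover
moments) are stable well below these replicate counts.

## Known limitations

* The Clark-rule solver is a heuristic: `DH` is an upper bound on the true
  parsimony optimum (never below it — asserted against brute force), and
  Type II verdicts may be conservative.
* Genuinely adversarial genotype configurations can commit the solver to
  inconsistent merges that only surface at wild-card resolution; such
  windows are declared Type II false rather than repaired by backtracking.
* Single-family dominant inheritance is assumed; multi-family inputs work
  only insofar as the families share the mutant haplotype segment.
* One chromosome per run; no binary PLINK formats.
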