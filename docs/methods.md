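# Methods

## Problem formulation

Deduplicating UMIs at one alignment position is treated as a sequence of
*return-and-delete* near-neighbor queries on an implicit graph over the N
unique UMIs, rather than as construction of an explicit N × N distance
matrix. The query contract is:

* `remove_near(u, k, F)` — return every not-yet-removed UMI v with
  d(u, v) ≤ k and f(v) ≤ F, mark all of them removed. The queried UMI u is
  always included when it is still alive, **regardless of its own
  frequency**; the frequency ceiling gates only the neighbors. (The
  alternative reading — applying F to u as well — would make directional
  grouping drop its own seeds, since seeds routinely have f(u) > F.)
* `contains(u)` — true iff u is alive. Implemented as an O(1) membership
  test on a shared alive-set.

The alive-set owned by the contract wrapper is the single source of truth
for removal. Each UMI can be returned by at most one query over an index's
lifetime, which is what lets the grouping algorithms run in O(N) queries.

## Substitution-only distance

Only substitution errors are modeled; insertions and deletions in UMIs are
far rarer and are out of scope, which is why all sequences at a position
must share one length M. Each base maps to a 3-bit code from a pairwise
equidistant set (A=110, T=011, C=101, G=000 — vertices of a regular
tetrahedron in {0,1}³), so every mismatch contributes exactly 2 set bits to
the XOR and d(a, b) = popcount(a ⊕ b) / 2. 21 bases fit per 64-bit word
(arbitrary-precision integers extend this transparently to longer UMIs).

`N` (undetermined base call) is a fifth letter: positions are recorded in a
separate bit mask and hold the all-zero pattern in the coded bits. A
position where exactly one side is N counts as a mismatch; both-N counts as
a match. The distance is then
`popcount((a ⊕ b) & not-N-positions)/2 + popcount(nmask_a ⊕ nmask_b)`.
The both-N-matches convention is a deliberate choice (the fifth-letter
reading); the opposite convention would live entirely inside `hamming()`.
Anything outside {A, C, G, T, N} is rejected rather than coerced — coercion
to N would silently change distances.

## Grouping algorithms

* **cluster**: for each seed (visited in lexicographic order for
  determinism), transitively expand with F = ∞. Underestimates molecule
  counts when intermediate UMIs bridge two true molecules.
* **adjacency**: visit in decreasing frequency (ties broken by ascending
  sequence); one non-recursive `remove_near` per surviving seed.
* **directional** (default): as adjacency but recursive; a neighbor v of x
  is admitted iff f(v) ≤ ε(f(x) + 1), the threshold recomputed from each
  newly admitted UMI. ε defaults to 0.5, equivalent to 2 f(v) − 1 ≤ f(x).
  The ε(f+1) form is kept in one function (`directional_threshold`) so the
  boundary convention is changeable in exactly one place.

Expansions use explicit stacks: a 10⁶-UMI component must not overflow the
interpreter's call stack. Group representatives are the highest-frequency
member, ties broken by lexicographically smallest sequence, and a result's
groups are sorted by representative — two runs on the same input are
byte-identical, and the partition (disjoint cover of the key set) is
invariant across all eight backends. Backend equivalence to the naive
linear-scan oracle is the suite's central correctness property.

## Index backends — numerical and structural choices

* **combinations** enumerates the Hamming ball over the 5-letter alphabet
  {A, C, G, T, N} by default (matching the simulator), covering distances
  ≤ k, not exactly k — the contract needs the full ball.
* **subsequences / n-grams** store bins as insertion-ordered lists. A bin
  is compacted when a scan finds more than half its members dead, keeping
  query cost near the number of survivors without global bookkeeping. The
  subsequence placeholder is an internal reserved character (`*`), never
  serialized. N-gram keys carry (slot, span, substring) so equal substrings
  at different offsets occupy different bins. Gram lengths are
  ⌊M/(k+1)⌋ with the remainder attached to the last gram.
* **trie** stores children in fixed A, C, G, T, N order; queries descend
  with an edits-remaining budget.
* **BK-trees** are built by inserting UMIs in increasing (frequency,
  sequence) order, placing low-frequency UMIs near the root so the
  frequency ceiling can prune whole subtrees during directional runs.
  Distance-0 child slots cannot occur (table keys are unique; duplicate
  insertion raises). Queries recurse only into child indices within
  [d(c,u) − k, d(c,u) + k].
* **Fenwick BK-trees** rank-compress the distinct frequency values; UMI at
  rank r lives in the O(log N) Fenwick nodes whose intervals contain r, and
  a ceiling-F query traverses only the prefix decomposition of rank(F) —
  exactly the UMIs with f ≤ F, each in one visited node.
* **Subtree pruning flags** (all-removed, minimum alive frequency) are
  *hints*, refreshed along the paths each query visits. Staleness is
  provably safe-sided: removals only shrink subtrees, so a stale flag can
  only fail to prune. Correctness rests solely on the shared alive-set;
  this matters for the Fenwick and n-gram-BK backends, where one UMI lives
  in several trees and is removed from all of them at once.

## Instrumentation

Every index counts its Hamming evaluations, and additionally accumulates
`naive_scan_equivalent` — the evaluations a naive scan would have spent on
the identical query trace (one per alive UMI per query; the trace is
backend-invariant because outputs are). This gives an exact, machine-
independent work comparison: on a (10⁴, 10, 1) dataset a full directional
run through `ngrambk` spends ~3.9M evaluations (tree construction
included) against ~1.4 × 10¹⁰ for the naive scan — a >3,000× reduction,
measured rather than estimated, with no need to actually execute the
quadratic scan.

## Synthetic datasets

A (C, M, k) dataset draws C center UMIs uniformly from {A, C, G, T, N}^M,
then 20 neighbors per center: for k = 1 exactly one substitution at a
uniform position to a uniform different letter; for k ≥ 2 the edit count e
is drawn uniformly from 1..k, then e distinct positions are substituted.
(The exactly-one reading at k = 1 is the one consistent with the expected
neighborhood size: a length-10 center has 40 possible one-edit variants, of
which 20 uniform draws occupy 40·(1 − (39/40)²⁰) ≈ 15.9 on average, giving
≈ 16.9 unique UMIs per center.) Centers draw frequencies uniformly from
[19, 100] and neighbors from [1, 10], so every center/non-center pair
satisfies 2 f(v) − 1 ≤ f(u) — tight at f(v) = 10, f(u) = 19 — and
directional grouping can in principle recover exactly C groups. The ranges
are configuration constants, not tuned values; any pair of ranges with
2·max_neighbor − 1 ≤ min_center works.

Draw order is fixed and documented (centers, neighbors, center
frequencies, neighbor frequencies) so a seed pins the dataset exactly.
Duplicate sequences keep their first draw; centers are generated first, so
a neighbor colliding with a center keeps the center frequency. Sequence
generation is vectorized (numpy, sequences packed as base-5 integers for
uniqueness counting), which is what makes the C = 10⁵, M = 9 case — ~2.1M
generated sequences in a 5⁹ ≈ 1.95M space, where collisions are
substantial and must emerge from the simulation itself — run in seconds.

What the simulator does *not* emulate: PCR amplification trees (errors are
independent per neighbor, not inherited), quality-score structure, indels,
and read bodies beyond the UMI. Passing tests therefore demonstrate
correctness of the collapsing machinery under the stated error geometry,
not calibration against any particular library-prep chemistry.

## Drivers

FASTQ deduplication uses the entire fixed-length read as the UMI and runs
one global grouping. SAM/BAM deduplication extracts the UMI after the last
`_` in the read name (separator configurable), keys mapped primary reads
by (reference, strand, coordinate) — forward reads by soft-clip-adjusted
5′ start, reverse reads by 3′ end plus trailing soft clips (flag
`clip_aware=False` disables the adjustment, whose convention is not
universal) — and deduplicates each key independently. One consensus read
per group is emitted: among reads carrying the representative UMI, highest
mapping quality, then mean base quality, then earliest file position. No
consensus sequence is synthesized; every output read existed in the input.
Reads lacking the separator are dropped with a warning and counted
(`strict_umi=True` hard-fails); secondary/supplementary alignments are
skipped; unmapped reads are dropped unless `--keep-unmapped`.

## Problem sizes used in the checks

Backend-equivalence checks replay full pipelines on 100 seeded datasets
with C ∈ {8, 15, 25, 40}, M ∈ {8, 10, 12}, k ∈ {1, 2} — sizes at which the
quadratic naive oracle is comfortable while still exercising multi-word
encodings, k = 2 windows and bin collisions. Structure statistics and the
work-reduction measurement use a full (10⁴, 10, 1) dataset (~167k unique
UMIs); simulated-size checks go up to C = 10⁵ with M = 9 (~1.1M unique).

## Known limitations

Single-end reads only; no per-cell or per-gene stratification; no
quality-aware (probabilistic) merging; indices are in-memory and
single-threaded; a consumed index cannot be reused (grouping functions
require a fresh one and raise otherwise).
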