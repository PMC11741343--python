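# Methods

## Hashing

Each base is assigned a fixed 64-bit seed (derived once from splitmix64);
the hash of a k-mer is the XOR of its base seeds, each cyclically rotated
by the base's distance from the k-mer's right end. Rotation distributes
over XOR, so the hash rolls in O(1) per base (`RollingHasher`) and the full
hash array of a sequence has a closed form — rotate-normalized seeds,
prefix-XOR, window XOR, rotate back — which `stream_hashes` evaluates with
NumPy. The scalar and vectorized paths are tested equal at every position.

**Strand policy.** The canonical hash (default) is the sum, mod 2^64, of
the forward hash and the hash of the reverse complement. Addition is
symmetric in the two strands, so a k-mer and its reverse complement hash
identically, and it preserves uniformity over the hash range; combining by
`min` would skew canonical values low (the minimum of two uniform variates
is triangular, which breaks density calculations and bin-uniformity
checks). Forward-only hashing is a flag.

**Width.** Hashes are computed in 64 bits; the 32-bit default folds the
halves (`hi XOR lo`). 32 bits is enough for megabase-scale windows (the
within-window collision probability at w = 32 on 1 Mb is ~10^-2 *per
genome*, and a collision merely shifts one tie-break); 64-bit is available
where tie-freeness matters.

**Ambiguity.** After uppercasing (disable with `strict_case`, which makes
soft-masked lowercase ambiguous), any character outside ACGT — including
every IUPAC degeneracy code — makes the overlapping k-mers unhashable.
The k-mer stream therefore has index gaps, and all window machinery is
defined over *entries*, not base positions.

## Window-minimum structures

All five backends implement `insert(index, hash)` / `min()` over the last
w entries, with ties broken to the newest entry by comparing
`(hash, -insert_counter)`:

* **naive** — bounded deque, `min` is a full linear scan (O(w), but the
  scan is a single C-level pass and wins at small w);
* **naive_memo** — memoizes the minimum; a rescan happens only when the
  memoized entry is evicted, so `min` is O(1) amortized (on random streams
  the memoized entry is evicted while minimal with probability ~1/w per
  step, giving ~n/w rescans; the suite asserts rescans ≤ evictions ≤ n);
* **set** — ordered multiset keyed `(hash, -counter)` (a bisect-maintained
  sorted list; keys are unique because the counter is) plus a FIFO of
  handles for eviction, O(log w) search per operation;
* **monotone** — monotonic queue, increasing hashes front-to-back; on
  insert, entries with hash **≥** the incoming one are purged from the
  back (≥, not >, or an older equal minimum could survive at the front and
  violate the rightmost rule); the front is the minimum;
* **segment_tree** — implicit-array complete binary tree, nodes hold the
  min of their children; leaf count is the smallest power of two ≥ w with
  padding leaves holding a sentinel above every real value; the window
  maps to leaves circularly (counter mod w), overwriting the expiring
  entry, O(log w) per insert, `min` reads the root.

Degenerate inputs: w = 1 is legal everywhere (every entry is its own
minimum); `min()` on an empty window raises `LookupError`; non-increasing
indices raise `ValueError`.

## Adaptive backend selection

`select_backend(w)` consults a table mapping window-size ranges to kinds,
defaulting to `naive` for w ≤ 15 and `naive_memo` for w ≥ 16 — the
crossover where full scans start to dominate the memoized variant's
occasional rescans. The cut is machine-dependent, so the table is a
configurable default, not a constant. `set` and `monotone` are never
auto-selected (they are consistently slower here) but remain available by
name, anchoring the cross-backend equivalence tests; `segment_tree` is
likewise opt-in.

## Digestion semantics

* Coordinates are 0-based; a selected substring of length L at position p
  covers [p, p+L): L = k for modimizers/minimizers, L = w for syncmers
  (the *window start* is reported, since it is the window that is
  selected).
* Minimizers: the window-min backend persists across ambiguity gaps (only
  the entry count defines a window), and a position is emitted once even
  if minimal in many windows — emission happens whenever the minimum of
  the current full window differs from the last emitted position, which
  is equivalent to the deduplicated union over windows because the
  rightmost-minimum index is non-decreasing over consecutive windows.
  End-of-sequence windows are not padded; fewer than w valid k-mers yield
  an empty digest.
* Syncmers: evaluated per maximal run of consecutive valid k-mers with a
  fresh backend, so a window never straddles an ambiguous run. A window is
  selected when the rightmost-tie-broken minimum sits at either end; no
  "both ends" case exists because a single winner is always defined.
* Modimizers: a pure vectorized filter `hash mod n == 0`.

## Parallel digestion

The sequence is cut into equal cores, one per worker, tiling it exactly.
Each worker digests a padded interval and keeps only positions starting in
its core, so concatenated outputs equal the sequential digest exactly —
the module's sole correctness contract, property-tested with ambiguous
runs placed across every partition boundary.

Padding is two-sided for minimizers: every window able to select an owned
position must be visible to the owner, and such windows extend up to w−1
*valid* k-mers on both sides of the core (left-padding alone would lose
positions near a seam that are minimal only in windows ending in the next
core — the next worker sees those windows but does not own the position).
The planner scans the actual sequence, so padding grows across ambiguous
runs until it covers w−1 valid k-mer starts (plus k−1 bases to complete
the last k-mer); in ambiguity-free sequence that is w−1 bases left and
(w−1)+(k−1) right. Syncmers need only w−1 bases of right padding (windows
are literal substrings anchored at the owned start) and modimizers k−1.
Over-padding is harmless — out-of-core selections are dropped — so the
planner errs generous. Workers share nothing and re-hash their padded
interval; the redundant overlap work is the price of exactness. One
partition per worker; a work queue is out of scope.

## Synthetic inputs

`RandomDnaSpec` draws i.i.d. bases (uniform composition by default) and
plants non-overlapping runs of N with geometric lengths (mean 5) until the
target ambiguous fraction is hit exactly. This emulates the two features
of real genomes that matter to the digestion machinery — uniform-looking
hash streams and assembly-gap-like N runs — and nothing else: no repeats,
no composition skew, no soft-masking structure. Passing tests therefore
demonstrate correctness of the selection logic and its edge handling, not
performance or density behaviour on repeat-rich genomes (where ties from
repeated k-mers are common; tie-breaking is deterministic, but density
closed forms assume distinct hashes). `HashArraySpec` provides seeded
uniform hash arrays for the backend benchmark; `bench_backends` sweeps all
backends over one array, recording wall time and a checksum (the sum of
reported minimum indices) that must agree across backends — cheap and
order-sensitive enough to catch eviction bugs. The benchmark default is
10^6 values (the CLI's `--length` raises it); suite-internal sweeps use
10^5 so the full test run stays in minutes on one CPU.

## Numerical and design choices

* Expected densities used in tests: minimizer 2/(w+1), modimizer 1/n,
  closed syncmer 2/(w−k+1), under the independent-uniform-hash
  approximation; tolerances are 5 binomial standard deviations, which is
  conservative because window-based selections are underdispersed
  relative to Bernoulli.
* Strand symmetry of canonical digests (reverse complement selects the
  mirror image) holds exactly only on tie-free input; tests verify
  tie-freeness (64-bit hashes, k = 16) before asserting it, since repeated
  k-mers create genuine ties whose rightmost resolution is not
  reverse-symmetric.
* Determinism: all generators are seeded; CLI output is byte-identical
  across runs and across `--threads` values.

## Limitations

Pure-Python inner loops: throughput is orders of magnitude below a native
implementation, and thread workers mostly interleave rather than truly
parallelize — the parallel driver exists for its exactness contract and
API, not for speed here. DNA only (general alphabets and alphabet
promotion of digests are out of scope), FASTA only (no FASTQ/SAM), closed
syncmers only (no open syncmers or low-density minimizer orders).
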