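# seqdigest

Minimizer, closed-syncmer and modimizer digestion of DNA sequences — a
library and command-line tool.

## The problem

Many sequence-analysis pipelines (read alignment, classification, De
Bruijn-graph assembly) do not need every k-mer of a genome: they work on a
*digest*, a sparse, deterministic selection of substrings that still covers
the sequence densely enough for matching. `seqdigest` implements the three
standard selection schemes over a rolling k-mer hash *h*:

* **modimizer** — keep the k-mer starting at *i* iff `h(i) ≡ 0 (mod n)`;
  expected density 1/n.
* **minimizer** — keep the k-mer iff its hash is minimal in at least one
  window of *w* consecutive k-mers (a span of *w + k − 1* bases); expected
  density 2/(w+1), with the guarantee that every window contains a selected
  k-mer.
* **closed syncmer** — keep the length-*w* window iff the minimal of its
  *w − k + 1* k-mers (*k < w*) is the leftmost or rightmost one; expected
  density 2/(w−k+1) over windows.

Equal minimal hashes are broken toward the rightmost k-mer. Hashing is
ntHash-style (per-base seeds combined by cyclic rotation, O(1) rolling
update), canonical by default so a k-mer and its reverse complement hash
identically; 32-bit (default) and 64-bit widths are available. Ambiguous
characters (N, IUPAC codes) make the overlapping k-mers unhashable:
minimizer windows are counted in *valid* k-mers (an ambiguous run stretches
a window's base span), syncmer windows are literal substrings and are
skipped when interrupted.

The windowed schemes sit on a family of interchangeable sliding-window-
minimum structures — `naive`, `naive_memo`, `set`, `monotone`,
`segment_tree` — that all return identical answers; by default the backend
is chosen adaptively from the window size (naive scan for w ≤ 15, memoized
scan beyond), and digestion can run in overlapping partitions
(`--threads`) with output *identical* to a sequential run.

## Worked example

Digest a 120 bp toy contig (one ambiguous `NNNN` run) with (k=5, w=4)
minimizers:

```sh
$ seqdigest digest toy.fa --scheme minimizer -k 5 -w 4 -v
chr_test: length=120 selected=41 density=0.35345
>chr_test scheme=minimizer k=5 w=4 hash_bits=32 strand=canonical
TACGTCGTGGGGTTATAACCCCGTATACGTCGTTAAGCAGGCAGTAGTTATACGTACGTA
...
```

41 of the 112 valid 5-mers were selected (density 0.353, near the expected
2/(w+1) = 0.4 for so short a sequence); their concatenation forms the
digested FASTA record, 41 × 5 = 205 bases instead of 120 — on megabase
inputs with larger w the digest is many-fold *shorter* than the input,
e.g. density 0.061 at w = 32. The same digest as positions:

```sh
$ seqdigest digest toy.fa --scheme syncmer -k 5 -w 8 --output bed | head -3
chr_test	0	8
chr_test	3	11
chr_test	5	13
```

Each BED interval is a selected length-8 window (0-based, half-open).
`--output hashes` instead prints `position hash` pairs per record, and
`seqdigest bench` times the five window-min backends on uniform random
hash streams, checking that their checksums agree.

Library use mirrors the CLI:

```python
from seqdigest import SchemeParams, digest_parallel
params = SchemeParams("minimizer", k=15, w=11)
res = digest_parallel(seq, params, workers=4)   # == sequential digest
res.positions[:3]                                # e.g. [2, 9, 21]
```

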