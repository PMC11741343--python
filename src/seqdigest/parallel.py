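"""Partitioned digestion whose output is identical to a sequential run.

The sequence is split into disjoint *cores* that tile it exactly, one per
worker.  Each worker digests a *padded* interval around its core and keeps
only the positions whose selected substring starts inside the core, so the
concatenated per-core outputs equal the sequential digest position for
position.

Padding must be generous enough that every window able to select an owned
position is evaluated:

* minimizers — windows containing an owned k-mer extend up to ``w - 1``
  *valid* k-mers on either side, so the padding grows leftward and
  rightward until it covers that many valid k-mer starts (ambiguous runs
  stretch it), plus ``k - 1`` bases to complete the last k-mer;
* syncmers — a window is a literal substring starting at the owned
  position, so only ``w - 1`` bases of right padding are needed;
* modimizers — each k-mer is judged alone: ``k - 1`` bases of right
  padding.

Because the padded entry streams are contiguous slices of the global
k-mer stream, every worker reproduces exactly the windows a sequential run
would form, and tie-breaking is identical; over-padding is harmless (the
extra selections fall outside the core and are dropped).
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .hashing import encode, valid_kmer_starts
from .schemes import DigestResult, SchemeParams, digest

__all__ = ["Partition", "PartitionPlan", "plan_partitions", "digest_parallel"]


@dataclass(frozen=True)
class Partition:
    """One worker's assignment: the owned core and the padded interval."""

    core_start: int
    core_end: int
    pad_start: int
    pad_end: int

    def __post_init__(self) -> None:
        if not (
            0 <= self.pad_start <= self.core_start <= self.core_end <= self.pad_end
        ):
            raise ValueError(f"inconsistent partition bounds: {self}")


@dataclass(frozen=True)
class PartitionPlan:
    partitions: tuple[Partition, ...]
    seq_len: int

    def __post_init__(self) -> None:
        prev = 0
        for p in self.partitions:
            if p.core_start != prev:
                raise ValueError("cores must tile the sequence disjointly in order")
            prev = p.core_end
        if prev != self.seq_len:
            raise ValueError("cores must cover the full sequence")

    def __len__(self) -> int:
        return len(self.partitions)


def plan_partitions(seq: str, num_parts: int, params: SchemeParams) -> PartitionPlan:
    """Split ``seq`` into at most ``num_parts`` cores with scheme-appropriate
    padding.  Fewer partitions are returned when the sequence is shorter
    than the requested count.  The actual sequence is scanned so that
    minimizer padding counts *valid* k-mers, growing across ambiguous runs.
    """
    if num_parts < 1:
        raise ValueError(f"num_parts must be >= 1, got {num_parts}")
    n = len(seq)
    parts = max(1, min(num_parts, n))
    bounds = [(i * n) // parts for i in range(parts + 1)]

    k = params.k
    if params.scheme == "modimizer":
        partitions = [
            Partition(lo, hi, lo, min(n, hi + k - 1))
            for lo, hi in zip(bounds, bounds[1:])
        ]
        return PartitionPlan(tuple(partitions), n)
    if params.scheme == "syncmer":
        w = params.w
        partitions = [
            Partition(lo, hi, lo, min(n, hi + w - 1))
            for lo, hi in zip(bounds, bounds[1:])
        ]
        return PartitionPlan(tuple(partitions), n)

    # minimizer: padding counted in valid k-mer entries on both sides
    w = params.w
    valid = valid_kmer_starts(encode(seq, params.hash_config), k)
    starts = np.flatnonzero(valid)  # sorted valid k-mer start positions
    partitions = []
    for lo, hi in zip(bounds, bounds[1:]):
        # w-1 valid starts strictly before the core
        j = int(np.searchsorted(starts, lo, side="left"))
        pad_start = lo if j == 0 else min(lo, int(starts[max(0, j - (w - 1))]))
        # w-1 valid starts at/after the core end, then complete the k-mer
        j2 = int(np.searchsorted(starts, hi, side="left"))
        last = min(starts.size, j2 + (w - 1)) - 1
        far = int(starts[last]) + k if last >= 0 else 0
        pad_end = min(n, max(hi + k - 1, far))
        partitions.append(Partition(lo, hi, pad_start, pad_end))
    return PartitionPlan(tuple(partitions), n)


def _digest_partition(
    seq: str,
    part: Partition,
    params: SchemeParams,
    backend: str | None,
    with_hashes: bool,
) -> tuple[list[int], list[int] | None]:
    sub = seq[part.pad_start : part.pad_end]
    res = digest(sub, params, backend=backend, with_hashes=with_hashes)
    off = part.pad_start
    positions = []
    hashes = [] if with_hashes else None
    for i, p in enumerate(res.positions):
        gp = p + off
        if part.core_start <= gp < part.core_end:
            positions.append(gp)
            if hashes is not None:
                hashes.append(res.hashes[i])
    return positions, hashes


def digest_parallel(
    seq: str,
    params: SchemeParams,
    workers: int = 1,
    backend: str | None = None,
    with_hashes: bool = False,
) -> DigestResult:
    """Digest ``seq`` in ``workers`` overlapping partitions; the result is
    exactly equal to ``digest(seq, params)`` — same positions, same order."""
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    plan = plan_partitions(seq, workers, params)
    if len(plan) == 1:
        return digest(seq, params, backend=backend, with_hashes=with_hashes)

    def job(part: Partition):
        return _digest_partition(seq, part, params, backend, with_hashes)

    with ThreadPoolExecutor(max_workers=min(workers, len(plan))) as pool:
        pieces = list(pool.map(job, plan.partitions))

    positions: list[int] = []
    hashes: list[int] | None = [] if with_hashes else None
    for ppos, ph in pieces:
        positions.extend(ppos)
        if hashes is not None:
            hashes.extend(ph)
    return DigestResult(positions, params.selected_length, hashes, params)
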