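"""Synthetic fixtures and the backend micro-benchmark.

Two seeded generators supply everything the test-suite and benchmark need:
uniform random hash arrays (the backend benchmark's input) and random DNA
with an optional model of ambiguous-base runs.  ``bench_backends`` sweeps
the window-min structures over a hash array, timing a full insert+min
pass per (kind, window size) and recording a checksum — the sum of the
reported minimum indices — that must agree across all backends.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .window_min import BACKEND_KINDS, make_backend

__all__ = [
    "HashArraySpec",
    "RandomDnaSpec",
    "gen_hash_array",
    "gen_random_dna",
    "bench_backends",
]


@dataclass(frozen=True)
class HashArraySpec:
    """A seeded array of hash values, uniform over the full hash range."""

    length: int
    bits: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if self.bits not in (32, 64):
            raise ValueError("bits must be 32 or 64")


def gen_hash_array(spec: HashArraySpec) -> np.ndarray:
    """Uniform random hashes (dtype uint64, values < 2**bits); same spec,
    same array."""
    rng = np.random.default_rng(spec.seed)
    if spec.bits == 64:
        return rng.integers(0, 2**64, size=spec.length, dtype=np.uint64)
    return rng.integers(0, 2**32, size=spec.length, dtype=np.uint64)


@dataclass(frozen=True)
class RandomDnaSpec:
    """Random DNA with optional runs of ambiguous bases.

    ``n_rate`` is the target fraction of bases replaced by N, laid down as
    non-overlapping runs with geometric lengths of mean ``mean_run_length``
    (the total N count is hit exactly, so the realized fraction matches the
    rate up to rounding).
    """

    length: int
    seed: int = 0
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_rate: float = 0.0
    mean_run_length: float = 5.0

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if not 0.0 <= self.n_rate < 1.0:
            raise ValueError("n_rate must lie in [0, 1)")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if self.mean_run_length < 1.0:
            raise ValueError("mean_run_length must be >= 1")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def gen_random_dna(spec: RandomDnaSpec) -> str:
    """Generate the sequence described by ``spec`` (deterministic per spec)."""
    rng = np.random.default_rng(spec.seed)
    if spec.length == 0:
        return ""
    codes = rng.choice(4, size=spec.length, p=list(spec.composition))
    arr = _BASES[codes]
    target = round(spec.n_rate * spec.length)
    placed = 0
    occupied = np.zeros(spec.length, dtype=bool)
    attempts = 0
    while placed < target and attempts < 20 * max(1, target):
        attempts += 1
        run = min(int(rng.geometric(1.0 / spec.mean_run_length)), target - placed)
        start = int(rng.integers(0, max(1, spec.length - run + 1)))
        if occupied[start : start + run].any():
            continue
        occupied[start : start + run] = True
        arr[start : start + run] = ord("N")
        placed += run
    return arr.tobytes().decode("ascii")


def bench_backends(
    hashes: np.ndarray,
    window_sizes: list[int],
    kinds: tuple[str, ...] = BACKEND_KINDS,
) -> pd.DataFrame:
    """Drive each backend over the full hash array, inserting every value and
    querying ``min`` for every full window.

    Returns a DataFrame with columns ``kind, w, seconds, checksum``; the
    checksum (sum of reported minimum indices) must be identical across
    kinds for every window size.
    """
    unknown = set(kinds) - set(BACKEND_KINDS)
    if unknown:
        raise ValueError(f"unknown backend kinds: {sorted(unknown)}")
    hl = hashes.tolist()
    rows = []
    for w in window_sizes:
        for kind in kinds:
            b = make_backend(kind, w)
            insert = b.insert
            window_min = b.min
            checksum = 0
            full_from = w - 1
            t0 = time.perf_counter()
            for i, h in enumerate(hl):
                insert(i, h)
                if i >= full_from:
                    checksum += window_min()
            seconds = time.perf_counter() - t0
            rows.append((kind, w, seconds, checksum))
    return pd.DataFrame(rows, columns=["kind", "w", "seconds", "checksum"])
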