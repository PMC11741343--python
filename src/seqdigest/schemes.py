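"""Digestion schemes: modimizers, minimizers and closed syncmers.

A digestion scheme selects a sparse, deterministic subset of a sequence's
substrings from the hash values of its k-mers:

* **modimizer** — a k-mer is selected iff its hash is congruent to 0
  modulo ``n``; expected density 1/n on uniform hashes.
* **minimizer** — a k-mer is selected iff its hash is minimal in at least
  one window of ``w`` consecutive valid k-mers (a window spans
  ``w + k - 1`` bases when no ambiguous characters intervene); expected
  density 2/(w+1).
* **closed syncmer** — a length-``w`` window is selected iff the minimal
  of its ``w - k + 1`` constituent k-mers sits at the leftmost or
  rightmost position; expected density 2/(w-k+1) over windows.

Equal minimal hashes are broken toward the rightmost k-mer.

Ambiguous bases (anything outside ACGT) make the overlapping k-mers
unhashable.  Minimizer windows are counted in *valid k-mers*, so an
ambiguous run stretches the base-pair span of a window rather than
truncating it, and the window-min backend persists across skips.  Syncmer
windows, by contrast, are literal length-``w`` substrings: any window
containing an invalid k-mer is simply not evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .adaptive import resolve_backend
from .hashing import HashConfig, stream_hashes
from .window_min import make_backend

__all__ = [
    "SCHEMES",
    "SchemeParams",
    "DigestResult",
    "digest",
    "digest_modimizer",
    "digest_minimizer",
    "digest_syncmer",
]

SCHEMES = ("modimizer", "minimizer", "syncmer")

SchemeName = Literal["modimizer", "minimizer", "syncmer"]


@dataclass(frozen=True)
class SchemeParams:
    """Parameters of a digestion run.

    ``w`` is the number of k-mers per window for minimizers, but the window
    length *in bases* for syncmers (which therefore contain ``w - k + 1``
    k-mers and require ``k < w``).  ``mod`` is the modimizer modulus.
    """

    scheme: SchemeName
    k: int
    w: int | None = None
    mod: int | None = None
    hash_bits: int = 32
    canonical: bool = True
    strict_case: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; choose from {', '.join(SCHEMES)}"
            )
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.scheme == "modimizer":
            if self.mod is None or self.mod < 1:
                raise ValueError("modimizer requires a modulus n >= 1")
        elif self.scheme == "minimizer":
            if self.w is None or self.w < 1:
                raise ValueError("minimizer requires a window of w >= 1 k-mers")
        else:  # syncmer
            if self.w is None or self.w <= self.k:
                raise ValueError(
                    f"syncmer requires window length w > k (got k={self.k}, w={self.w})"
                )

    @property
    def hash_config(self) -> HashConfig:
        return HashConfig(
            bits=self.hash_bits, canonical=self.canonical, strict_case=self.strict_case
        )

    @property
    def selected_length(self) -> int:
        """Length in bases of each selected substring (k, or w for syncmers)."""
        return self.w if self.scheme == "syncmer" else self.k

    @property
    def window_entries(self) -> int:
        """Window capacity in k-mer entries (1 for modimizers)."""
        if self.scheme == "minimizer":
            return self.w
        if self.scheme == "syncmer":
            return self.w - self.k + 1
        return 1


@dataclass
class DigestResult:
    """Ordered selection produced by a digestion scheme.

    ``positions`` are strictly increasing 0-based start positions of the
    selected substrings, each of length ``selected_length``; ``hashes``
    (attached on request) holds, per position, the hash of the k-mer at
    that position.
    """

    positions: list[int]
    selected_length: int
    hashes: list[int] | None = None
    params: SchemeParams | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.positions)


def digest_modimizer(
    seq: str, params: SchemeParams, with_hashes: bool = False
) -> DigestResult:
    """Select every valid k-mer whose hash is 0 modulo ``params.mod``."""
    if params.scheme != "modimizer":
        raise ValueError(f"expected modimizer params, got {params.scheme}")
    pos, h = stream_hashes(seq, params.k, params.hash_config)
    keep = h % np.uint64(params.mod) == 0
    positions = pos[keep].tolist()
    hashes = h[keep].tolist() if with_hashes else None
    return DigestResult(positions, params.selected_length, hashes, params)


def digest_minimizer(
    seq: str,
    params: SchemeParams,
    backend: str | None = None,
    with_hashes: bool = False,
) -> DigestResult:
    """Select every k-mer minimal in some window of ``w`` consecutive valid
    k-mers (deduplicated: each position is emitted once)."""
    if params.scheme != "minimizer":
        raise ValueError(f"expected minimizer params, got {params.scheme}")
    w = params.w
    kind = resolve_backend(backend, w, params.hash_bits)
    pos, h = stream_hashes(seq, params.k, params.hash_config)
    positions: list[int] = []
    if pos.size >= w:
        pl = pos.tolist()
        hl = h.tolist()
        b = make_backend(kind, w)
        insert = b.insert
        window_min = b.min
        full_from = w - 1
        last = -1
        append = positions.append
        for i, (p, hv) in enumerate(zip(pl, hl)):
            insert(p, hv)
            if i >= full_from:
                m = window_min()
                if m != last:
                    append(m)
                    last = m
    hashes = None
    if with_hashes:
        lookup = dict(zip(pos.tolist(), h.tolist()))
        hashes = [lookup[p] for p in positions]
    return DigestResult(positions, params.selected_length, hashes, params)


def digest_syncmer(
    seq: str,
    params: SchemeParams,
    backend: str | None = None,
    with_hashes: bool = False,
) -> DigestResult:
    """Select every length-``w`` window whose minimal k-mer is the leftmost
    or rightmost of its ``w - k + 1`` k-mers (closed syncmers).

    Windows containing any invalid k-mer are skipped entirely; within a
    contiguous run of valid k-mers a fresh window-min structure is used so
    windows never straddle an ambiguous run.
    """
    if params.scheme != "syncmer":
        raise ValueError(f"expected syncmer params, got {params.scheme}")
    k, w = params.k, params.w
    s = w - k + 1  # k-mers per window
    kind = resolve_backend(backend, s, params.hash_bits)
    pos, h = stream_hashes(seq, k, params.hash_config)
    positions: list[int] = []
    hashes: list[int] | None = [] if with_hashes else None
    if pos.size >= s:
        # split into maximal runs of consecutive k-mer starts
        breaks = np.flatnonzero(np.diff(pos) != 1) + 1
        for run_pos, run_h in zip(np.split(pos, breaks), np.split(h, breaks)):
            if run_pos.size < s:
                continue
            pl = run_pos.tolist()
            hl = run_h.tolist()
            b = make_backend(kind, s)
            insert = b.insert
            window_min = b.min
            for i, (p, hv) in enumerate(zip(pl, hl)):
                insert(p, hv)
                if i >= s - 1:
                    j = p - (w - k)  # window start (leftmost k-mer)
                    m = window_min()
                    if m == j or m == p:
                        positions.append(j)
                        if hashes is not None:
                            hashes.append(hl[i - s + 1])
    return DigestResult(positions, params.selected_length, hashes, params)


def digest(
    seq: str,
    params: SchemeParams,
    backend: str | None = None,
    with_hashes: bool = False,
) -> DigestResult:
    """Digest ``seq`` with the scheme named in ``params``.

    Windowed schemes use the adaptively selected backend unless ``backend``
    names a specific one; the choice never changes the result.
    """
    if params.scheme == "modimizer":
        return digest_modimizer(seq, params, with_hashes=with_hashes)
    if params.scheme == "minimizer":
        return digest_minimizer(seq, params, backend=backend, with_hashes=with_hashes)
    return digest_syncmer(seq, params, backend=backend, with_hashes=with_hashes)
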