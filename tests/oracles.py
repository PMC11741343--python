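"""Independent brute-force oracles for the test suite.

These deliberately avoid the package's rolling/vectorized code paths:
hashes are recomputed from scratch per k-mer with explicit Python loops
(sharing only the seed constants), and window minima are found by
rescanning every window.  Vectorized variants (NumPy argmin over an
explicit per-window matrix) are provided for the larger sweeps; they too
rescan every window rather than reusing state between windows.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from seqdigest.hashing import _COMP_SEEDS, _MASK64, _SEEDS

_B2C = {"A": 0, "C": 1, "G": 2, "T": 3}


def _rol(x: int, r: int) -> int:
    r &= 63
    if r == 0:
        return x
    return ((x << r) | (x >> (64 - r))) & _MASK64


def scratch_hash(kmer: str, bits: int = 32, canonical: bool = True) -> int:
    """Direct (non-rolling) evaluation of the k-mer hash definition."""
    codes = [_B2C[c] for c in kmer.upper()]
    k = len(codes)
    f = 0
    r = 0
    for j, c in enumerate(codes):
        f ^= _rol(int(_SEEDS[c]), k - 1 - j)
        r ^= _rol(int(_COMP_SEEDS[c]), j)
    h = (f + r) & _MASK64 if canonical else f
    if bits == 32:
        h = (h ^ (h >> 32)) & 0xFFFFFFFF
    return h


def scratch_stream(seq: str, k: int, bits: int = 32, canonical: bool = True):
    """All (position, hash) pairs of valid k-mers, each hashed from scratch."""
    out = []
    up = seq.upper()
    for i in range(len(up) - k + 1):
        kmer = up[i : i + k]
        if all(c in _B2C for c in kmer):
            out.append((i, scratch_hash(kmer, bits, canonical)))
    return out


def linear_scan_min(entries) -> int:
    """Rightmost index of the minimum hash, by full scan of (index, hash)."""
    best_i, best_h = entries[0]
    for i, h in entries[1:]:
        if h <= best_h:
            best_i, best_h = i, h
    return best_i


def rightmost_argmin_rows(hashes: np.ndarray, w: int) -> np.ndarray:
    """Per-window rightmost argmin as absolute entry offsets (vectorized
    rescan of every window)."""
    win = sliding_window_view(hashes, w)
    j = win[:, ::-1].argmin(axis=1)
    return (w - 1 - j) + np.arange(win.shape[0])


def brute_modimizer(
    seq: str, k: int, n: int, bits: int = 32, canonical: bool = True, entries=None
):
    if entries is None:
        entries = scratch_stream(seq, k, bits, canonical)
    return [p for p, h in entries if h % n == 0]


def brute_minimizer(
    seq: str,
    k: int,
    w: int,
    bits: int = 32,
    canonical: bool = True,
    fast: bool = True,
    entries=None,
):
    """Deduplicated union over all windows of w consecutive valid k-mers of
    the window's rightmost-minimal k-mer start."""
    if entries is None:
        entries = scratch_stream(seq, k, bits, canonical)
    if len(entries) < w:
        return []
    if fast:
        pos = np.array([p for p, _ in entries], dtype=np.int64)
        h = np.array([hh for _, hh in entries], dtype=np.uint64)
        sel = pos[rightmost_argmin_rows(h, w)]
        return sorted(set(sel.tolist()))
    selected = set()
    for t in range(len(entries) - w + 1):
        selected.add(linear_scan_min(entries[t : t + w]))
    return sorted(selected)


def brute_syncmer(
    seq: str, k: int, w: int, bits: int = 32, canonical: bool = True, entries=None
):
    """Window starts j whose w-k+1 k-mers are all valid and whose
    rightmost-tie-broken minimal k-mer sits at offset 0 or w-k."""
    s = w - k + 1
    if entries is None:
        entries = scratch_stream(seq, k, bits, canonical)
    hashes = dict(entries)
    out = []
    for j in range(len(seq) - w + 1):
        window = [(j + t, hashes.get(j + t)) for t in range(s)]
        if any(h is None for _, h in window):
            continue
        m = linear_scan_min(window)
        if m == j or m == j + w - k:
            out.append(j)
    return out
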