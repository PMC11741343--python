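"""Rolling k-mer hashing over the DNA alphabet.

The hash follows the ntHash recipe: every base is assigned a fixed,
well-mixed 64-bit seed, and the hash of a k-mer is the XOR of its base
seeds, each cyclically rotated by the base's distance from the k-mer's
right end.  Because cyclic rotation distributes over XOR, the hash can be
*rolled* — updated in O(1) when the k-mer slides one base to the right —
and the whole hash array of a sequence can equally be computed in closed
form with a prefix-XOR, which is what :func:`stream_hashes` does with
NumPy.

Strand handling: the *forward* hash depends on the strand a k-mer is read
from; the *canonical* hash combines the forward hash and the hash of the
reverse complement by modular addition, so a k-mer and its reverse
complement hash identically while the values stay uniform over the full
hash range (a min/max combination would skew them low/high).  Canonical is
the default.

Hash width: hashes are computed in 64 bits; the 32-bit configuration
folds the two halves together (``hi XOR lo``), which preserves uniformity.

Any character outside ``ACGT`` (after uppercasing; uppercasing can be
disabled) is *ambiguous*: k-mers containing one are not hashable and are
skipped by :func:`stream_hashes`, which therefore emits non-consecutive
start indices around ambiguous runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "AmbiguousBaseError",
    "HashConfig",
    "RollingHasher",
    "encode",
    "hash_kmer",
    "revcomp",
    "stream_hashes",
    "valid_kmer_starts",
]

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    # Standard splitmix64 finalizer; used once to derive the base seeds.
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


# Base codes: A=0, C=1, G=2, T=3; complement(code) == 3 - code.
_SEEDS = np.array([_splitmix64(i + 1) for i in range(4)], dtype=np.uint64)
# Seed of the complement base, indexed by the base itself.
_COMP_SEEDS = _SEEDS[::-1].copy()

_CODE = np.full(256, 255, dtype=np.uint8)
_CODE_STRICT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
    _CODE_STRICT[ord(_b)] = _i

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer containing a non-ACGT character is hashed."""


@dataclass(frozen=True)
class HashConfig:
    """Hash configuration.

    Parameters
    ----------
    bits : int
        Hash width, 32 (default) or 64.
    canonical : bool
        If True (default) a k-mer and its reverse complement hash
        identically; if False the forward-strand hash is used.
    strict_case : bool
        If True, lowercase (soft-masked) bases are treated as ambiguous
        instead of being uppercased.
    """

    bits: int = 32
    canonical: bool = True
    strict_case: bool = False

    def __post_init__(self) -> None:
        if self.bits not in (32, 64):
            raise ValueError(f"hash width must be 32 or 64, got {self.bits}")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str, config: HashConfig = HashConfig()) -> np.ndarray:
    """Encode a sequence as base codes (A=0,C=1,G=2,T=3; 255 = ambiguous)."""
    raw = seq.encode("latin-1", errors="replace")
    table = _CODE_STRICT if config.strict_case else _CODE
    return table[np.frombuffer(raw, dtype=np.uint8)]


def valid_kmer_starts(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean array over k-mer starts: True where the k-mer is pure ACGT."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = codes.size
    if n < k:
        return np.zeros(0, dtype=bool)
    bad = np.concatenate(([0], np.cumsum(codes >= 4)))
    return bad[k:] == bad[:-k]


def _rol(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    # Vectorized 64-bit cyclic left rotation; s must lie in [0, 64).
    return (x << s) | (x >> ((np.uint64(64) - s) & np.uint64(63)))


def _ror(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    return _rol(x, (np.uint64(64) - s) & np.uint64(63))


def _fold32(h: np.ndarray) -> np.ndarray:
    return (h ^ (h >> np.uint64(32))) & np.uint64(0xFFFFFFFF)


def _hash_all(codes: np.ndarray, k: int, config: HashConfig) -> np.ndarray:
    """64-bit (or folded 32-bit) hash of every k-mer start, valid or not.

    Values at starts whose window touches an ambiguous base are garbage and
    must be masked by the caller.
    """
    n = codes.size
    m = n - k + 1
    idx = np.minimum(codes, 3)  # ambiguous positions get a placeholder seed
    rot = np.arange(n, dtype=np.uint64) & np.uint64(63)

    # forward: h(i) = rol^{i+k-1}( XOR_{p=i..i+k-1} ror^p(seed[p]) )
    t = _ror(_SEEDS[idx], rot)
    px = np.zeros(n + 1, dtype=np.uint64)
    np.bitwise_xor.accumulate(t, out=px[1:])
    win = px[k:] ^ px[:-k]
    out_rot = (np.arange(m, dtype=np.uint64) + np.uint64(k - 1)) & np.uint64(63)
    fwd = _rol(win, out_rot)
    if not config.canonical:
        return fwd

    # reverse-complement: r(i) = ror^i( XOR_{p=i..i+k-1} rol^p(compseed[p]) )
    u = _rol(_COMP_SEEDS[idx], rot)
    np.bitwise_xor.accumulate(u, out=px[1:])
    win = px[k:] ^ px[:-k]
    rev = _ror(win, np.arange(m, dtype=np.uint64) & np.uint64(63))
    return fwd + rev  # wraps mod 2^64; symmetric in the two strands


def stream_hashes(
    seq: str, k: int, config: HashConfig = HashConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Hash every valid k-mer of ``seq``.

    Returns ``(positions, hashes)``: the strictly increasing 0-based start
    positions of all k-mers composed solely of A/C/G/T, and their hash
    values.  Positions are not necessarily consecutive — k-mers overlapping
    an ambiguous character are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = encode(seq, config)
    if codes.size < k:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.uint64)
    valid = valid_kmer_starts(codes, k)
    pos = np.flatnonzero(valid).astype(np.int64)
    if pos.size == 0:
        return pos, np.zeros(0, dtype=np.uint64)
    h = _hash_all(codes, k, config)[pos]
    if config.bits == 32:
        h = _fold32(h)
    return pos, h


def iter_hashes(
    seq: str, k: int, config: HashConfig = HashConfig()
) -> Iterator[tuple[int, int]]:
    """Iterate ``(index, hash)`` pairs of :func:`stream_hashes` as Python ints."""
    pos, h = stream_hashes(seq, k, config)
    yield from zip(pos.tolist(), h.tolist())


def _rol1(x: int, r: int) -> int:
    r &= 63
    if r == 0:
        return x
    return ((x << r) | (x >> (64 - r))) & _MASK64


class RollingHasher:
    """Scalar rolling hasher for a fixed k, updated one base at a time.

    This is the O(1)-per-step path the digestion loop conceptually uses;
    :func:`stream_hashes` computes the same values in closed form.  The
    hasher must be re-initialized after an ambiguous base interrupts the
    k-mer stream.
    """

    def __init__(self, kmer: str, config: HashConfig = HashConfig()):
        self.k = len(kmer)
        self.config = config
        codes = self._codes(kmer)
        f = 0
        r = 0
        for j, c in enumerate(codes):
            f = _rol1(f, 1) ^ int(_SEEDS[c])
            r ^= _rol1(int(_COMP_SEEDS[c]), j)
        self._f = f
        self._r = r

    def _codes(self, s: str) -> list[int]:
        codes = encode(s, self.config).tolist()
        if any(c >= 4 for c in codes):
            raise AmbiguousBaseError(f"k-mer {s!r} contains a non-ACGT character")
        return codes

    def roll(self, base_out: str, base_in: str) -> int:
        """Slide the window one base right, dropping ``base_out`` from the
        left and appending ``base_in``; returns the new hash value."""
        (c_out,) = self._codes(base_out)
        (c_in,) = self._codes(base_in)
        k = self.k
        self._f = _rol1(self._f, 1) ^ _rol1(int(_SEEDS[c_out]), k) ^ int(_SEEDS[c_in])
        self._r = _rol1(self._r ^ int(_COMP_SEEDS[c_out]), 64 - 1) ^ _rol1(
            int(_COMP_SEEDS[c_in]), k - 1
        )
        return self.value

    @property
    def value(self) -> int:
        h = (self._f + self._r) & _MASK64 if self.config.canonical else self._f
        if self.config.bits == 32:
            h = (h ^ (h >> 32)) & 0xFFFFFFFF
        return h


def hash_kmer(kmer: str, config: HashConfig = HashConfig()) -> int:
    """Hash a single k-mer from scratch.

    Raises :class:`AmbiguousBaseError` if the k-mer contains any character
    outside A/C/G/T (after case handling): such k-mers are not hashable and
    callers must skip them.
    """
    if not kmer:
        raise ValueError("k-mer must be non-empty")
    return RollingHasher(kmer, config).value
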