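"""Sliding-window range-minimum structures.

Each backend answers, under streaming insertion of ``(index, hash)`` pairs,
"which index among the last ``w`` inserted pairs carries the minimum hash".
Indices must be strictly increasing but need not be consecutive (k-mers
overlapping ambiguous bases are skipped upstream), so the window is counted
in *inserted entries*, never in base-pair span.

Ties are broken toward the most recently inserted entry (the *rightmost*
minimum).  Internally every backend compares ``(hash, -insert_counter)``
tuples, so a newer equal hash always outranks an older one; the monotone
queue purges entries with hash greater *or equal* to the incoming one for
the same reason.

Five interchangeable implementations are provided:

``naive``
    Bounded deque; ``min`` is a full linear scan.  O(w) per query but the
    scan is branch-light and fastest at small w.
``naive_memo``
    Deque plus a memoized minimum; a rescan happens only when the memoized
    entry falls out of the window, so ``min`` is O(1) amortized.
``set``
    Ordered multiset (sorted list keyed by ``(hash, -counter)``) plus a
    FIFO of handles; insert/evict/min are O(log w) lookups.
``monotone``
    Monotonic queue kept strictly increasing in hash; the front is the
    window minimum, O(1) amortized per insert.
``segment_tree``
    Implicit-array complete binary tree whose nodes hold the minimum of
    their children; the leaf count is the smallest power of two >= w and
    padding leaves carry the maximum possible value.  Window slots are
    assigned circularly (insert counter mod w), overwriting the expiring
    entry in place; O(log w) per insert, O(1) min at the root.

All five produce identical answers on any insert sequence; ``naive`` and
``naive_memo`` are the ones selected automatically during digestion (see
:mod:`seqdigest.adaptive`), the others are retained as cross-checks and
for benchmarking.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from bisect import bisect_left, insort
from collections import deque

__all__ = [
    "BACKEND_KINDS",
    "WindowMinBackend",
    "NaiveBackend",
    "NaiveMemoBackend",
    "SetBackend",
    "MonotoneBackend",
    "SegmentTreeBackend",
    "make_backend",
]

BACKEND_KINDS = ("naive", "naive_memo", "set", "monotone", "segment_tree")


class WindowMinBackend(ABC):
    """Abstract insert/min structure over the last ``w`` (index, hash) pairs."""

    kind: str = "abstract"

    def __init__(self, w: int):
        if w < 1:
            raise ValueError(f"window size must be >= 1, got {w}")
        self._w = w
        self._n = 0  # total inserts so far (the insert counter)
        self._last_index = -1

    @property
    def capacity(self) -> int:
        return self._w

    @property
    def size(self) -> int:
        """Number of entries currently in the window."""
        return min(self._n, self._w)

    def _check_index(self, index: int) -> None:
        if index <= self._last_index:
            raise ValueError(
                f"indices must be strictly increasing: {index} after {self._last_index}"
            )
        self._last_index = index

    def _require_nonempty(self) -> None:
        if self._n == 0:
            raise LookupError("min() on an empty window")

    @abstractmethod
    def insert(self, index: int, hash_: int) -> None:
        """Add an entry, evicting the oldest if the window is full."""

    @abstractmethod
    def min(self) -> int:
        """Index of the minimum hash in the window, rightmost among ties."""


class NaiveBackend(WindowMinBackend):
    kind = "naive"

    def __init__(self, w: int):
        super().__init__(w)
        # (hash, -counter, index); deque eviction is FIFO via maxlen
        self._dq: deque[tuple[int, int, int]] = deque(maxlen=w)

    def insert(self, index: int, hash_: int) -> None:
        self._check_index(index)
        self._dq.append((hash_, -self._n, index))
        self._n += 1

    def min(self) -> int:
        self._require_nonempty()
        return min(self._dq)[2]

    def entries(self) -> list[tuple[int, int]]:
        """Current window contents as (index, hash), oldest first."""
        return [(t[2], t[0]) for t in self._dq]


class NaiveMemoBackend(WindowMinBackend):
    kind = "naive_memo"

    def __init__(self, w: int):
        super().__init__(w)
        self._dq: deque[tuple[int, int, int]] = deque(maxlen=w)
        self._memo: tuple[int, int, int] | None = None
        self.rescans = 0  # full window scans performed so far

    def insert(self, index: int, hash_: int) -> None:
        self._check_index(index)
        entry = (hash_, -self._n, index)
        self._dq.append(entry)
        self._n += 1
        memo = self._memo
        if memo is None or -memo[1] < self._n - self._w:
            # memoized minimum left the window: one full rescan
            self._memo = min(self._dq)
            self.rescans += 1
        elif entry < memo:
            self._memo = entry

    def min(self) -> int:
        self._require_nonempty()
        return self._memo[2]

    def entries(self) -> list[tuple[int, int]]:
        return [(t[2], t[0]) for t in self._dq]


class SetBackend(WindowMinBackend):
    kind = "set"

    def __init__(self, w: int):
        super().__init__(w)
        self._sorted: list[tuple[int, int, int]] = []  # ordered multiset
        self._fifo: deque[tuple[int, int, int]] = deque()  # eviction handles

    def insert(self, index: int, hash_: int) -> None:
        self._check_index(index)
        if self._n >= self._w:
            old = self._fifo.popleft()
            del self._sorted[bisect_left(self._sorted, old)]
        entry = (hash_, -self._n, index)
        insort(self._sorted, entry)
        self._fifo.append(entry)
        self._n += 1

    def min(self) -> int:
        self._require_nonempty()
        return self._sorted[0][2]

    def entries(self) -> list[tuple[int, int]]:
        return [(t[2], t[0]) for t in self._fifo]


class MonotoneBackend(WindowMinBackend):
    kind = "monotone"

    def __init__(self, w: int):
        super().__init__(w)
        # (hash, counter, index); hashes strictly increasing front-to-back
        self._dq: deque[tuple[int, int, int]] = deque()

    def insert(self, index: int, hash_: int) -> None:
        self._check_index(index)
        dq = self._dq
        # >= (not >): a newer equal hash must replace the older one so the
        # front is always the *rightmost* minimum
        while dq and dq[-1][0] >= hash_:
            dq.pop()
        dq.append((hash_, self._n, index))
        self._n += 1
        stale = self._n - 1 - self._w
        while dq[0][1] <= stale:
            dq.popleft()

    def min(self) -> int:
        self._require_nonempty()
        return self._dq[0][2]

    @property
    def queue_hashes(self) -> list[int]:
        """Hashes currently held, front to back (strictly increasing)."""
        return [t[0] for t in self._dq]


class SegmentTreeBackend(WindowMinBackend):
    kind = "segment_tree"

    # Padding sentinel: larger than any real hash; the middle field 1 is
    # greater than every real -counter (<= 0) so a real entry carrying the
    # maximum hash still beats padding.
    _PAD = (math.inf, 1, -1)

    def __init__(self, w: int):
        super().__init__(w)
        leaves = 1
        while leaves < w:
            leaves <<= 1
        self._leaves = leaves
        self._tree: list[tuple] = [self._PAD] * (2 * leaves)

    @property
    def leaf_count(self) -> int:
        return self._leaves

    @property
    def padding_count(self) -> int:
        return self._leaves - self._w

    def insert(self, index: int, hash_: int) -> None:
        self._check_index(index)
        tree = self._tree
        # circular slot assignment overwrites the expiring entry in place
        i = self._leaves + self._n % self._w
        tree[i] = (hash_, -self._n, index)
        self._n += 1
        i >>= 1
        while i:
            left = tree[2 * i]
            right = tree[2 * i + 1]
            tree[i] = left if left <= right else right
            i >>= 1

    def min(self) -> int:
        self._require_nonempty()
        return self._tree[1][2]


_REGISTRY: dict[str, type[WindowMinBackend]] = {
    cls.kind: cls
    for cls in (
        NaiveBackend,
        NaiveMemoBackend,
        SetBackend,
        MonotoneBackend,
        SegmentTreeBackend,
    )
}


def make_backend(kind: str, w: int) -> WindowMinBackend:
    """Instantiate a window-min backend by name.

    ``kind`` is one of ``naive``, ``naive_memo``, ``set``, ``monotone``,
    ``segment_tree``; ``w`` is the window capacity in entries.
    """
    try:
        cls = _REGISTRY[kind]
    except KeyError:
        raise ValueError(
            f"unknown backend kind {kind!r}; choose from {', '.join(BACKEND_KINDS)}"
        ) from None
    return cls(w)
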