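"""Adaptive choice of the window-min backend.

Benchmarking the backends on streams of uniformly distributed hash values
shows a crossover: the naive linear scan wins at small windows (its tight
loop beats every asymptotically better structure), while the memoized
variant wins once windows are large enough that full scans dominate.  The
default table encodes that crossover at w = 15/16, but it is a default,
not a constant — crossover points are machine-dependent, so callers can
supply their own table.

The selection never affects results: all backends return identical minima
on any stream, so the choice is purely a matter of speed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .window_min import BACKEND_KINDS, WindowMinBackend, make_backend

__all__ = ["BackendChoice", "DEFAULT_TABLE", "select_backend", "resolve_backend"]

# (largest w handled, kind) pairs, ascending; windows beyond the last bound
# fall through to the final entry's kind with bound None.
DEFAULT_TABLE: tuple[tuple[int | None, str], ...] = (
    (15, "naive"),
    (None, "naive_memo"),
)


@dataclass(frozen=True)
class BackendChoice:
    """The backend kind selected for a given window size."""

    kind: str
    w: int

    def make(self) -> WindowMinBackend:
        return make_backend(self.kind, self.w)


def select_backend(
    w: int,
    hash_bits: int = 32,
    table: tuple[tuple[int | None, str], ...] = DEFAULT_TABLE,
) -> BackendChoice:
    """Pick the default backend for a window of ``w`` entries.

    ``hash_bits`` is accepted for symmetry with the 32/64-bit digester
    configurations; the default table is identical for both widths.
    """
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    if hash_bits not in (32, 64):
        raise ValueError(f"hash width must be 32 or 64, got {hash_bits}")
    for bound, kind in table:
        if bound is None or w <= bound:
            if kind not in BACKEND_KINDS:
                raise ValueError(f"unknown backend kind {kind!r} in table")
            return BackendChoice(kind=kind, w=w)
    raise ValueError("backend table does not cover all window sizes")


def resolve_backend(kind: str | None, w: int, hash_bits: int = 32) -> str:
    """Map a user-facing backend name (or ``auto``/None) to a concrete kind."""
    if kind is None or kind == "auto":
        return select_backend(w, hash_bits).kind
    if kind not in BACKEND_KINDS:
        raise ValueError(
            f"unknown backend {kind!r}; choose auto or one of {', '.join(BACKEND_KINDS)}"
        )
    return kind
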