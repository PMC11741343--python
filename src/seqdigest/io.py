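"""FASTA input/output and digest serialization.

Digested output follows the convention that the selected substrings are
concatenated, in order, into a new sequence per record — so a FASTA genome
goes in and a (much shorter) FASTA digest comes out.  Positions can
alternatively be written as BED3 intervals or as ``position hash`` pairs.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass
from typing import IO, Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .schemes import DigestResult, SchemeParams

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "write_digest_fasta",
    "write_positions_bed",
    "write_hash_pairs",
]


@dataclass
class SequenceRecord:
    """A named sequence: header token, remainder of the header, residues."""

    name: str
    description: str = ""
    seq: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("record name must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


def _as_text_handle(source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "r", encoding="ascii"), True


def read_fasta(source) -> list[SequenceRecord]:
    """Read a FASTA file (path or text handle) into records, in file order.

    Line wrapping is joined, whitespace inside sequence lines is stripped,
    and CRLF line endings are accepted.  An empty file yields an empty
    list; any other content not starting with a ``>`` header is a format
    error.
    """
    handle, owned = _as_text_handle(source)
    try:
        text = handle.read().replace("\r\n", "\n").replace("\r", "\n")
    finally:
        if owned:
            handle.close()
    stripped = text.lstrip()
    if not stripped:
        return []
    if not stripped.startswith(">"):
        raise ValueError("not a FASTA file: first non-blank line must start with '>'")
    records = []
    for title, seq in SimpleFastaParser(_io.StringIO(text)):
        name, _, description = title.partition(" ")
        records.append(
            SequenceRecord(name=name, description=description.strip(), seq="".join(seq.split()))
        )
    return records


def _open_out(out) -> tuple[IO[str], bool]:
    if hasattr(out, "write"):
        return out, False
    return open(os.fspath(out), "w", encoding="ascii", newline="\n"), True


def write_fasta(records: Iterable[SequenceRecord], out, wrap: int = 60) -> None:
    """Write records as FASTA; ``wrap`` bases per line (0 = no wrapping)."""
    handle, owned = _open_out(out)
    try:
        for rec in records:
            header = f">{rec.name} {rec.description}".rstrip()
            handle.write(header + "\n")
            if wrap and wrap > 0:
                for i in range(0, len(rec.seq), wrap):
                    handle.write(rec.seq[i : i + wrap] + "\n")
                if not rec.seq:
                    pass  # header-only record: no sequence lines
            else:
                handle.write(rec.seq + "\n")
    finally:
        if owned:
            handle.close()


def _params_comment(params: SchemeParams) -> str:
    bits = ["scheme=" + params.scheme, f"k={params.k}"]
    if params.w is not None:
        bits.append(f"w={params.w}")
    if params.mod is not None:
        bits.append(f"mod={params.mod}")
    bits.append(f"hash_bits={params.hash_bits}")
    bits.append("strand=" + ("canonical" if params.canonical else "forward"))
    return " ".join(bits)


def digested_sequence(record: SequenceRecord, result: DigestResult) -> str:
    """Concatenate the selected substrings of a record, in order."""
    L = result.selected_length
    seq = record.seq
    return "".join(seq[p : p + L] for p in result.positions)


def write_digest_fasta(
    records: list[SequenceRecord],
    results: list[DigestResult],
    params: SchemeParams,
    out,
    wrap: int = 60,
) -> None:
    """Write one FASTA record per input record, its sequence the in-order
    concatenation of the selected substrings; the header carries the
    original name plus a comment encoding the scheme parameters."""
    if len(records) != len(results):
        raise ValueError(
            f"{len(records)} records but {len(results)} digest results"
        )
    comment = _params_comment(params)
    digested = [
        SequenceRecord(rec.name, comment, digested_sequence(rec, res))
        for rec, res in zip(records, results)
    ]
    write_fasta(digested, out, wrap=wrap)


def write_positions_bed(
    records: list[SequenceRecord], results: list[DigestResult], out
) -> None:
    """Write selections as BED3: ``name  start  start+selected_length``
    (0-based, half-open), sorted within each record."""
    if len(records) != len(results):
        raise ValueError(
            f"{len(records)} records but {len(results)} digest results"
        )
    handle, owned = _open_out(out)
    try:
        for rec, res in zip(records, results):
            L = res.selected_length
            for p in res.positions:
                handle.write(f"{rec.name}\t{p}\t{p + L}\n")
    finally:
        if owned:
            handle.close()


def write_hash_pairs(
    records: list[SequenceRecord], results: list[DigestResult], out
) -> None:
    """Write per-record ``position hash`` pairs, one per line, preceded by a
    ``>name`` separator line so multi-record output stays unambiguous.

    Results must carry hashes (digest with ``with_hashes=True``).
    """
    if len(records) != len(results):
        raise ValueError(
            f"{len(records)} records but {len(results)} digest results"
        )
    handle, owned = _open_out(out)
    try:
        for rec, res in zip(records, results):
            if res.hashes is None:
                raise ValueError("digest results carry no hashes")
            handle.write(f">{rec.name}\n")
            for p, h in zip(res.positions, res.hashes):
                handle.write(f"{p} {h}\n")
    finally:
        if owned:
            handle.close()
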