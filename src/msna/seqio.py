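"""FASTA input/output, alphabet validation, and segment partitioning.

Sequences are plain DNA/RNA over {A, C, G, T, U, N}; ``U`` is normalized to
``T`` on ingest by default so RNA and DNA inputs share one alignment alphabet.
Segments are equal-size slices of a sequence (the last one may be shorter);
they are the unit of suffix-tree matching and of banded pairwise alignment.
All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "Sequence",
    "Segment",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "partition_segments",
]

ALPHABET = frozenset("ACGTUN")
GAP = "-"


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty, duplicate ids, bad symbols)."""


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide sequence (residues uppercased, gap-free)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Segment:
    """One equal-size slice of a sequence.

    ``index`` is the 0-based segment ordinal and ``start == index * segment_size``
    the offset of the slice in the source sequence.
    """

    seq_id: str
    index: int
    start: int
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def _validate_residues(record_id: str, residues: str, allow_gaps: bool) -> None:
    allowed = ALPHABET | {GAP} if allow_gaps else ALPHABET
    for ch in residues:
        if ch not in allowed:
            raise FastaFormatError(
                f"record {record_id!r} contains illegal character {ch!r}"
            )


def read_fasta(
    path,
    *,
    normalize_u: bool = True,
    allow_gaps: bool = False,
) -> list[Sequence]:
    """Read an (optionally gapped) FASTA file into a list of :class:`Sequence`.

    Residues are uppercased; internal whitespace is discarded; ``U`` is mapped
    to ``T`` unless ``normalize_u=False``. Input order is preserved. Raises
    :class:`FastaFormatError` on an empty file, duplicate ids, empty records
    or characters outside the alphabet (``-`` only if ``allow_gaps``).
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace(" ", "").replace("\t", "")
        if not rec.id:
            raise FastaFormatError("record with empty id")
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if not residues:
            raise FastaFormatError(f"record {rec.id!r} is empty")
        _validate_residues(rec.id, residues, allow_gaps)
        if normalize_u:
            residues = residues.replace("U", "T")
        records.append(Sequence(rec.id, residues))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[tuple[str, str]],
    path,
    *,
    width: int = 70,
) -> None:
    """Write ``(id, residues-or-gapped-row)`` pairs as FASTA, wrapped at ``width``.

    Gap characters are preserved verbatim, so alignment rows round-trip through
    :func:`read_fasta` (with ``allow_gaps=True``). An empty collection yields a
    valid empty file.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rec_id, residues in records:
            if rec_id in seen:
                raise ValueError(f"duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            fh.write(f">{rec_id}\n")
            for i in range(0, len(residues), width):
                fh.write(residues[i : i + width] + "\n")


def partition_segments(seq: Sequence, segment_size: int) -> list[Segment]:
    """Split ``seq`` into ``ceil(len/segment_size)`` contiguous segments.

    Every segment except possibly the last has exactly ``segment_size``
    residues; concatenating the segments in index order reproduces the
    sequence.
    """
    if segment_size < 1:
        raise ValueError("segment_size must be >= 1")
    n_seg = math.ceil(len(seq) / segment_size)
    return [
        Segment(
            seq_id=seq.id,
            index=i,
            start=i * segment_size,
            residues=seq.residues[i * segment_size : (i + 1) * segment_size],
        )
        for i in range(n_seg)
    ]


def degap(row: str) -> str:
    """Strip gap characters from an alignment row."""
    return row.replace(GAP, "")
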