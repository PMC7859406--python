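"""FASTA/TSV input-output and the coordinate conventions shared by the pipeline.

All sequences are stored as upper-case DNA over ``{A, C, G, T, N}``; RNA input
is transliterated U→T on read (editing reports still speak of "U" for
inserted/deleted residues, matching the field's vocabulary).  All intervals
are 0-based, half-open; 1-based closed coordinates appear only in report
columns explicitly suffixed ``_1based``.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "Interval",
    "read_fasta",
    "write_fasta",
    "write_table",
    "setup_logging",
]

ALPHABET = frozenset("ACGTN")

logger = logging.getLogger("kinetoedit")


def setup_logging(verbosity: int = 0) -> None:
    """Route package logs to stderr with ISO-8601 timestamps."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbosity > 1 else logging.INFO if verbosity else logging.WARNING)


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (DNA alphabet, upper case)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SeqRecord {self.id!r}: sequence must be non-empty")
        bad = set(self.seq) - ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"SeqRecord {self.id!r}: non-alphabet character {self.seq[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based, half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.seq_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly wrapped) multi-FASTA file into SeqRecords.

    Sequences are upper-cased and U is transliterated to T (logged once per
    file).  Errors on empty files, duplicate ids and non-alphabet characters.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    had_u = False
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            had_u = True
            seq = seq.replace("U", "T")
        records.append(SeqRecord(rec.id, seq, rec.description))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    if had_u:
        logger.info("read_fasta(%s): RNA input detected, transliterated U->T", path)
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                header = f">{rec.description}" if rec.description.startswith(rec.id) else f">{rec.id} {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _fmt(value: object) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records as a TSV with a header row.

    All rows must share one field set; floats are rendered with 6 significant
    digits; row order is input order.  ``columns`` supplies the schema for an
    empty row list (header-only file).
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("write_table: empty rows and no declared schema")
        columns = list(rows[0].keys())
    for i, row in enumerate(rows):
        if list(row.keys()) != list(columns):
            raise ValueError(
                f"write_table: row {i} fields {list(row)} do not match schema {list(columns)}"
            )
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in columns) + "\n")
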