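"""Sequence and table I/O plus the core record types shared by every stage.

All small-RNA and reference sequences are normalized to the RNA alphabet
(T -> U) exactly once, at ingest; every table the package writes therefore
uses U throughout. Coordinates are 1-based, fully closed intervals.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick complement on the RNA alphabet (used by several stages).
RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(RNA_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Library:
    """One sequencing library: a (genotype, treatment) combination.

    ``treatment`` is either ``"control"`` or ``"treated"``.
    """

    id: str
    genotype: str
    treatment: str
    total_clean_reads: int = 0

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "treated"):
            raise ValueError(f"treatment must be control/treated, got {self.treatment!r}")
        if self.total_clean_reads < 0:
            raise ValueError("total_clean_reads must be nonnegative")


@dataclass
class SmallRNATag:
    """A unique small-RNA sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def validate(self, min_len: int = 10, max_len: int = 35) -> None:
        if not set(self.sequence) <= RNA_ALPHABET:
            raise ValueError(f"tag {self.sequence!r} has non-RNA characters")
        if not (min_len <= self.length <= max_len):
            raise ValueError(f"tag length {self.length} outside [{min_len}, {max_len}]")
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("tag has no positive count in any library")


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA reference sequence (miRBase dialect)."""

    name: str
    family: str
    sequence: str


@dataclass(frozen=True)
class StructureRecord:
    """RNA secondary structure: sequence + dot-bracket + free energy (kcal/mol)."""

    id: str
    sequence: str
    dotbracket: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.sequence):
            raise ValueError(
                f"{self.id}: dot-bracket length {len(self.dotbracket)} != "
                f"sequence length {len(self.sequence)}"
            )
        depth = 0
        for ch in self.dotbracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"{self.id}: unbalanced dot-bracket")
            elif ch != ".":
                raise ValueError(f"{self.id}: invalid dot-bracket character {ch!r}")
        if depth != 0:
            raise ValueError(f"{self.id}: unbalanced dot-bracket")

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as 0-based (i, j) tuples, i < j."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for i, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                out.append((stack.pop(), i))
        return sorted(out)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fastq(path: str | Path, library_id: str | None = None
               ) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a 4-line FASTQ file.

    Sequences are uppercased but otherwise untouched; no filtering happens
    here. A record whose quality string length differs from its sequence
    length raises ``ValueError`` naming the (0-based) record index.
    """
    with _open_text(path) as fh:
        index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"record {index}: expected '@' header, got {header!r}")
            seq = fh.readline().rstrip("\n").upper()
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"record {index}: missing '+' separator line")
            if len(qual) != len(seq):
                raise ValueError(
                    f"record {index}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield header[1:].split()[0], seq, qual
            index += 1


def read_fasta(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, description, sequence) for each FASTA record.

    ``id`` is the first whitespace token of the header; multi-line sequences
    are concatenated; U/T are preserved as written. A sequence line before
    any header is a hard error.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        while first and not first.strip():
            first = fh.readline()
        if first and not first.startswith(">"):
            raise ValueError(f"{path}: sequence data before first FASTA header")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            yield rec.id, desc, str(rec.seq)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write (id_or_header, sequence) pairs as FASTA, wrapped at ``width``."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Dot-bracket structure files (RNAfold text dialect)
# ---------------------------------------------------------------------------

def read_structures(path: str | Path) -> Iterator[StructureRecord]:
    """Parse the 3-line RNAfold text dialect.

    Each record is ``>id`` / sequence / ``structure (mfe)`` where the MFE is
    in parentheses after the dot-bracket, e.g. ``((...)) ( -3.40)``.
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for i in range(0, len(lines), 3):
        header, seq, struct_line = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise ValueError(f"structure record {i // 3}: missing '>' header")
        lpar = struct_line.rfind("(")
        dotbracket = struct_line[:lpar].strip()
        mfe = float(struct_line[lpar + 1:].rstrip(")").strip())
        yield StructureRecord(header[1:].split()[0], normalize_rna(seq), dotbracket, mfe)


def write_structures(records: Iterable[StructureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.dotbracket} ({rec.mfe:7.2f})\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

#: Default float precision per logical column kind. Fold changes and TPMs are
#: printed at 1 decimal (round-half-to-even), matching the package's table
#: conventions; everything else falls back to repr.
DEFAULT_PRECISION = {"tpm": 1, "fold_change": 1, "log2fc": 1}


def format_value(value, precision: int | None = None) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if precision is not None:
            return format(value, f".{precision}f")
        return repr(value)
    return str(value)


def write_table(records: Sequence[Mapping], path: str | Path,
                schema: Sequence[str],
                precision: Mapping[str, int] | None = None) -> None:
    """Write records as a TSV with a header row.

    ``schema`` lists the columns in output order; every record must carry
    every column (a missing column is a hard error naming it). ``precision``
    maps column name -> number of decimals for float formatting
    (round-half-to-even, Python's default float formatting).
    """
    precision = dict(precision or {})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(schema) + "\n")
        for i, rec in enumerate(records):
            missing = [c for c in schema if c not in rec]
            if missing:
                raise ValueError(f"record {i} missing column(s): {', '.join(missing)}")
            fh.write("\t".join(
                format_value(rec[c], precision.get(c)) for c in schema) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV with a header row into a list of string-valued dicts."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh if line.strip()]
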