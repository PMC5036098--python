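"""Raw reads -> clean, collapsed unique tags per library.

Cleaning keeps a read when (a) the 3' adapter is found (reads with no
detectable adapter are rejected outright, so untrimmed adapter bases never
enter tag space), (b) every base quality of the retained insert is at or
above ``quality_floor``, and (c) the trimmed insert length lies in
[min_len, max_len]. Reads containing N are rejected. Trimming happens
before length filtering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .sequence_io import Library, SmallRNATag, normalize_rna

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]

REJECT = None  # sentinel: trim_adapter returns None for rejected reads


@njit(cache=False)
def _find_adapter_start(read, adapter, min_overlap, max_rate
                        ):  # pragma: no cover - exercised via trim_adapter
    """Leftmost read position where an adapter prefix of >= min_overlap nt
    matches with mismatch rate <= max_rate; -1 if none."""
    n = read.shape[0]
    m = adapter.shape[0]
    for i in range(0, n - min_overlap + 1):
        overlap = m if m < n - i else n - i
        limit = int(max_rate * overlap)
        mism = 0
        ok = True
        for k in range(overlap):
            if read[i + k] != adapter[k]:
                mism += 1
                if mism > limit:
                    ok = False
                    break
        if ok:
            return i
    return -1


@dataclass(frozen=True)
class PreprocessConfig:
    """Adapter/quality/length policy for read cleaning.

    The alignment tolerance is not a property of the assay, so it is
    configurable: an adapter is called at the leftmost read position where
    a prefix of the adapter of at least ``min_overlap`` nt matches with a
    mismatch rate of at most ``max_adapter_mismatch_rate``.
    """

    adapter3: str = "UCGUAUGCCGUCUUCUGCUUGU"
    min_len: int = 10
    max_len: int = 35
    min_overlap: int = 8
    max_adapter_mismatch_rate: float = 0.1
    quality_floor: int = 20
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if not (0 <= self.max_adapter_mismatch_rate < 0.5):
            raise ValueError("max_adapter_mismatch_rate must be in [0, 0.5)")


@dataclass
class LibrarySummary:
    """Per-library read accounting (raw, clean, unique, length histogram)."""

    library_id: str
    raw_reads: int = 0
    clean_reads: int = 0
    unique_clean_reads: int = 0
    length_histogram: Counter = field(default_factory=Counter)

    @property
    def clean_fraction(self) -> float:
        """Percent of raw reads surviving cleaning."""
        return self.clean_reads / self.raw_reads * 100 if self.raw_reads else 0.0

    @property
    def unique_fraction(self) -> float:
        """Unique clean reads as a percent of raw reads."""
        return self.unique_clean_reads / self.raw_reads * 100 if self.raw_reads else 0.0


def trim_adapter(read_sequence: str, config: PreprocessConfig) -> str | None:
    """Return the 5' insert preceding the adapter, or REJECT (None).

    The read is normalized to RNA. The leftmost occurrence of an adapter
    prefix (>= min_overlap nt, mismatch rate <= max_adapter_mismatch_rate)
    wins; the full-length adapter is also accepted with mismatches at the
    same rate. Reads containing N are rejected.
    """
    seq = normalize_rna(read_sequence)
    if "N" in seq:
        return REJECT
    adapter = normalize_rna(config.adapter3)
    pos = _find_adapter_start(
        np.frombuffer(seq.encode(), dtype=np.uint8),
        np.frombuffer(adapter.encode(), dtype=np.uint8),
        config.min_overlap, config.max_adapter_mismatch_rate)
    return seq[:pos] if pos >= 0 else REJECT


def clean_reads(raw_stream: Iterable[tuple[str, str, str]],
                config: PreprocessConfig,
                library_id: str = "") -> tuple[Iterator[str], LibrarySummary]:
    """Clean a raw FASTQ stream; returns (clean insert iterator, summary).

    The summary is filled in as the iterator is consumed; exhaust the
    iterator (e.g. via collapse_tags) before reading counts off it.
    """
    summary = LibrarySummary(library_id=library_id)

    def _iter() -> Iterator[str]:
        floor = config.quality_floor + config.phred_offset
        for _rid, seq, qual in raw_stream:
            summary.raw_reads += 1
            insert = trim_adapter(seq, config)
            if insert is REJECT:
                continue
            if not (config.min_len <= len(insert) <= config.max_len):
                continue
            # quality applies to the retained insert bases
            if any(ord(q) < floor for q in qual[:len(insert)]):
                continue
            summary.clean_reads += 1
            summary.length_histogram[len(insert)] += 1
            yield insert

    return _iter(), summary


def collapse_tags(clean_streams: Mapping[str, Iterable[str]],
                  summaries: Mapping[str, LibrarySummary] | None = None
                  ) -> list[SmallRNATag]:
    """Collapse clean reads into unique tags with per-library counts.

    ``clean_streams`` maps library id -> iterable of clean insert sequences.
    A duplicate library id is impossible by construction of the mapping, but
    passing the same underlying stream twice is guarded by exhaustion.
    Updates ``summaries[lib].unique_clean_reads`` when summaries are given.
    """
    per_seq: dict[str, dict[str, int]] = {}
    for lib_id, stream in clean_streams.items():
        lib_counter: Counter = Counter(stream)
        for seq, n in lib_counter.items():
            per_seq.setdefault(seq, {})[lib_id] = n
        if summaries is not None and lib_id in summaries:
            summaries[lib_id].unique_clean_reads = len(lib_counter)
    return [SmallRNATag(sequence=s, counts=c) for s, c in sorted(per_seq.items())]


def length_distribution(tags: Iterable[SmallRNATag], library_id: str
                        ) -> dict[int, float]:
    """Percent of a library's clean reads at each insert length."""
    hist: Counter = Counter()
    for tag in tags:
        n = tag.counts.get(library_id, 0)
        if n:
            hist[tag.length] += n
    total = sum(hist.values())
    if total == 0:
        raise ValueError(f"empty library {library_id!r}")
    return {length: n / total * 100 for length, n in sorted(hist.items())}


def preprocess_library(fastq_records: Iterable[tuple[str, str, str]],
                       library: Library,
                       config: PreprocessConfig) -> tuple[list[str], LibrarySummary]:
    """Convenience: clean one library's reads into a materialized list."""
    stream, summary = clean_reads(fastq_records, config, library.id)
    inserts = list(stream)
    return inserts, summary
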