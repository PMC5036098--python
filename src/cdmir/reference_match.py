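"""ncRNA filtering and EST/GSS contig mapping with library-overlap accounting.

A tag "matches" a reference iff its full sequence occurs as an exact
substring of a reference sequence (0 mismatches — the strictest reading of
"matched"). For ncRNA filtering both strands of the reference are searched
(the tag itself is taken sense-only); for contig mapping the
reverse-complement search is configurable and on by default.

The search is backed by a per-length substring index (a hash set of every
L-mer of the reference pool for each distinct tag length), which the test
suite checks against a naive quadratic scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequence_io import SmallRNATag, normalize_rna, revcomp

NCRNA_CLASSES = ("tRNA", "rRNA", "snRNA", "snoRNA")


@dataclass
class ReferenceSet:
    """A class-labeled pool of reference sequences (U alphabet)."""

    name: str
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"reference set {self.name!r} is empty")
        self.sequences = [normalize_rna(s) for s in self.sequences]


class SubstringIndex:
    """Exact-substring membership over a pool of texts, per query length.

    Builds, lazily per query length L, the set of all L-substrings of the
    pool (optionally including reverse complements).
    """

    def __init__(self, texts: Iterable[str], both_strands: bool = False):
        self._texts = [normalize_rna(t) for t in texts]
        if both_strands:
            self._texts += [revcomp(t) for t in self._texts]
        self._by_length: dict[int, frozenset[str]] = {}

    def _index_for(self, length: int) -> frozenset[str]:
        idx = self._by_length.get(length)
        if idx is None:
            grams = set()
            for text in self._texts:
                for i in range(len(text) - length + 1):
                    grams.add(text[i:i + length])
            idx = frozenset(grams)
            self._by_length[length] = idx
        return idx

    def __contains__(self, query: str) -> bool:
        return query in self._index_for(len(query))


def filter_ncrna(tags: Sequence[SmallRNATag],
                 reference_sets: Sequence[ReferenceSet]
                 ) -> tuple[list[SmallRNATag], list[SmallRNATag]]:
    """Partition tags into (kept, removed-as-ncRNA).

    A tag is removed iff it occurs as an exact substring of any reference
    sequence, searched on both reference strands.
    """
    if not reference_sets:
        raise ValueError("no ncRNA reference sets given")
    index = SubstringIndex(
        (s for rs in reference_sets for s in rs.sequences), both_strands=True)
    kept, removed = [], []
    for tag in tags:
        (removed if tag.sequence in index else kept).append(tag)
    return kept, removed


@dataclass
class MappingSummary:
    """Per-library accounting of tags mapped to a contig reference.

    ``specific_in_library`` counts reads (or unique tags) whose counts are
    nonzero in exactly that one library; ``conserved_in_all`` those nonzero
    in every library; ``singleton`` the unique mapped tags with a total
    count of exactly 1 across all libraries (an interpretation — the term
    is not otherwise defined for this layout).
    """

    reference_name: str
    reads_mapped: dict[str, int] = field(default_factory=dict)
    unique_reads_mapped: dict[str, int] = field(default_factory=dict)
    specific_reads: dict[str, int] = field(default_factory=dict)
    specific_unique: dict[str, int] = field(default_factory=dict)
    conserved_reads: dict[str, int] = field(default_factory=dict)
    conserved_unique: dict[str, int] = field(default_factory=dict)
    singleton: dict[str, int] = field(default_factory=dict)

    def percentages(self, raw_reads: Mapping[str, int]) -> dict[str, dict[str, float]]:
        """Each count field as a percent of raw (original) reads."""
        out: dict[str, dict[str, float]] = {}
        for name in ("reads_mapped", "unique_reads_mapped", "specific_reads",
                     "conserved_reads", "specific_unique", "conserved_unique",
                     "singleton"):
            counts = getattr(self, name)
            out[name] = {lib: counts.get(lib, 0) / raw_reads[lib] * 100
                         for lib in raw_reads}
        return out


def map_to_contigs(tags: Sequence[SmallRNATag],
                   reference: ReferenceSet,
                   library_ids: Sequence[str],
                   search_revcomp: bool = True
                   ) -> tuple[dict[str, bool], MappingSummary]:
    """Flag each tag as hit/miss against a contig set and summarize.

    Returns (per-tag-sequence hit flag, MappingSummary). A hit is an exact
    full-length substring occurrence on the given strand of any contig
    (reverse-complement strand too when ``search_revcomp``).
    """
    index = SubstringIndex(reference.sequences, both_strands=search_revcomp)
    hits: dict[str, bool] = {}
    summary = MappingSummary(reference_name=reference.name)
    for lib in library_ids:
        for d in (summary.reads_mapped, summary.unique_reads_mapped,
                  summary.specific_reads, summary.specific_unique,
                  summary.conserved_reads, summary.conserved_unique,
                  summary.singleton):
            d[lib] = 0
    for tag in tags:
        hit = tag.sequence in index
        hits[tag.sequence] = hit
        if not hit:
            continue
        present = [lib for lib in library_ids if tag.counts.get(lib, 0) > 0]
        total = tag.total_count
        for lib in library_ids:
            n = tag.counts.get(lib, 0)
            if n == 0:
                continue
            summary.reads_mapped[lib] += n
            summary.unique_reads_mapped[lib] += 1
            if len(present) == 1:
                summary.specific_reads[lib] += n
                summary.specific_unique[lib] += 1
            if len(present) == len(library_ids):
                summary.conserved_reads[lib] += n
                summary.conserved_unique[lib] += 1
            if total == 1:
                summary.singleton[lib] += 1
    return hits, summary
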