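"""Known-miRNA identification: mismatch-tolerant matching to a mature
reference and family parsing.

"Up to 2 mismatches" is implemented as equal-length Hamming distance (no
indels): on 20-24 nt queries, short-word ungapped hits dominate, and the
Hamming rule is exactly testable against a brute-force all-pairs oracle.
An optional +/-1 nt length slack (prefix/suffix placement of the shorter
sequence inside the longer) is provided, off by default.

A tag that matches several reference entries contributes its full counts
to each of them — paralogs with identical mature sequences all receive the
same reads, mirroring how identical family members share one count profile.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .sequence_io import MatureMiRNA, SmallRNATag, normalize_rna

_FAMILY_RE = re.compile(
    r"^(?:[a-zA-Z]{2,5}-)?(miR|MIR|mir)(\d+)", re.ASCII)


def parse_family(mirna_name: str) -> str:
    """Family from a (possibly species-prefixed) miRNA name.

    "nta-miR166a" -> "miR166"; the species prefix and any paralog letters
    or suffix after the digit block are dropped; case is normalized to
    the conventional "miR".
    """
    m = _FAMILY_RE.match(mirna_name)
    if not m:
        raise ValueError(f"cannot parse miRNA family from name {mirna_name!r}")
    return "miR" + m.group(2)


def load_mature_reference(records: Iterable[tuple[str, str, str]]
                          ) -> list[MatureMiRNA]:
    """Build MatureMiRNA entries from (id, description, sequence) records."""
    return [MatureMiRNA(name=rid, family=parse_family(rid),
                        sequence=normalize_rna(seq))
            for rid, _desc, seq in records]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _bounded_hamming(a: str, b: str, limit: int) -> int | None:
    """Hamming distance if <= limit, else None (early exit)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


@dataclass(frozen=True)
class KnownMatch:
    """One tag matched to one mature reference entry."""

    tag_sequence: str
    mirna: MatureMiRNA
    mismatches: int


def match_known(tags: Sequence[SmallRNATag],
                reference: Sequence[MatureMiRNA],
                max_mismatch: int = 2,
                length_slack: int = 0
                ) -> tuple[list[KnownMatch], dict[str, dict[str, int]]]:
    """Match collapsed tags against a mature reference.

    Returns (matches, per-miRNA counts) where counts[name][library] is the
    sum over all matching tags of that tag's library counts. With
    ``length_slack`` > 0, a tag whose length differs by at most the slack
    also matches if the shorter sequence Hamming-matches a prefix or suffix
    of the longer one.
    """
    if not reference:
        raise ValueError("empty mature reference")
    by_length: dict[int, list[MatureMiRNA]] = defaultdict(list)
    for m in reference:
        by_length[len(m.sequence)].append(m)

    matches: list[KnownMatch] = []
    counts: dict[str, dict[str, int]] = {m.name: {} for m in reference}
    for tag in tags:
        L = tag.length
        candidates: list[tuple[MatureMiRNA, int]] = []
        for m in by_length.get(L, ()):
            d = _bounded_hamming(tag.sequence, m.sequence, max_mismatch)
            if d is not None:
                candidates.append((m, d))
        if length_slack:
            for dL in range(1, length_slack + 1):
                for refs, longer_is_ref in ((by_length.get(L + dL, ()), True),
                                            (by_length.get(L - dL, ()), False)):
                    for m in refs:
                        longer, shorter = ((m.sequence, tag.sequence)
                                           if longer_is_ref
                                           else (tag.sequence, m.sequence))
                        best = None
                        for window in (longer[:len(shorter)], longer[-len(shorter):]):
                            d = _bounded_hamming(shorter, window, max_mismatch)
                            if d is not None and (best is None or d < best):
                                best = d
                        if best is not None:
                            candidates.append((m, best))
        for m, d in candidates:
            matches.append(KnownMatch(tag.sequence, m, d))
            bucket = counts[m.name]
            for lib, n in tag.counts.items():
                bucket[lib] = bucket.get(lib, 0) + n
    return matches, counts


def family_census(counts: Mapping[str, Mapping[str, int]],
                  reference: Sequence[MatureMiRNA]) -> dict[str, int]:
    """Number of distinct detected members (nonzero total counts) per family."""
    fam_of = {m.name: m.family for m in reference}
    census: dict[str, int] = defaultdict(int)
    for name, libs in counts.items():
        if sum(libs.values()) > 0:
            census[fam_of[name]] += 1
    return dict(census)
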