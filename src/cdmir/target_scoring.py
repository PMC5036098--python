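"""Plant miRNA target complementarity scoring.

The classical plant-target penalty ("expectation") scheme: per aligned
column, a mismatch costs 1, a G:U wobble 0.5 and a gap 2, and every
penalty is doubled when it falls at miRNA positions 2-13 (5'->3'), the
seed-extended core that plant targets must pair almost perfectly. The
miRNA is aligned against the target site read 3'->5' (i.e. against the
complement), by a minimal-penalty dynamic program allowing the site to be
up to 2 nt shorter or longer than the miRNA. A site scores 0 iff it is a
perfect reverse complement. Hits are reported up to a maximum expectation
(default 3.0).

This is a reimplementation of the scoring *style* used by plant target
finders, not of any specific web service's engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import normalize_rna

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]

SEED_START, SEED_END = 2, 13  # 1-based miRNA positions with doubled penalties
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0

_WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _mult(position: int) -> float:
    return 2.0 if SEED_START <= position <= SEED_END else 1.0


def _column_state(mirna_base: str, site_base: str) -> str:
    pair = (mirna_base, site_base)
    if pair in _WATSON_CRICK:
        return "match"
    if pair in _WOBBLE:
        return "G:U"
    return "mismatch"


def _column_penalty(state: str, position: int) -> float:
    if state == "match":
        return 0.0
    base = WOBBLE_PENALTY if state == "G:U" else MISMATCH_PENALTY
    return base * _mult(position)


@dataclass(frozen=True)
class TargetHit:
    """One scored miRNA binding site on a transcript (1-based closed)."""

    mirna: str
    transcript: str
    start: int
    end: int
    expectation: float
    alignment: tuple[str, ...]  # per-column states: match / G:U / mismatch / gap
    inhibition: str = ""        # "cleavage" if central positions 9-11 all pair

    @property
    def gaps(self) -> int:
        return sum(1 for s in self.alignment if s == "gap")


def score_site(mirna_sequence: str, site_sequence: str
               ) -> tuple[float, tuple[str, ...]]:
    """Minimal-penalty alignment of a miRNA against one candidate site.

    ``site_sequence`` is the transcript subsequence 5'->3'; it is reversed
    internally so columns run along the miRNA 5'->3'. A gap column takes
    the doubling of the miRNA position it interrupts. Ties prefer fewer
    gaps, resolved by a diagonal-first traceback.
    """
    mirna = normalize_rna(mirna_sequence)
    site = normalize_rna(site_sequence)
    m, s = len(mirna), len(site)
    if s < m - 2:
        raise ValueError(f"site length {s} < miRNA length {m} - 2")
    site_rev = site[::-1]  # 3'->5', so column j faces miRNA position j+1

    INF = float("inf")
    D = [[INF] * (s + 1) for _ in range(m + 1)]
    D[0][0] = 0.0
    for i in range(1, m + 1):
        D[i][0] = D[i - 1][0] + GAP_PENALTY * _mult(i)
    for j in range(1, s + 1):
        D[0][j] = D[0][j - 1] + GAP_PENALTY * _mult(1)
    for i in range(1, m + 1):
        for j in range(1, s + 1):
            diag = D[i - 1][j - 1] + _column_penalty(
                _column_state(mirna[i - 1], site_rev[j - 1]), i)
            up = D[i - 1][j] + GAP_PENALTY * _mult(i)
            left = D[i][j - 1] + GAP_PENALTY * _mult(min(i + 1, m))
            D[i][j] = min(diag, up, left)

    # traceback, diagonal first (fewest gaps among co-optimal alignments)
    states: list[str] = []
    i, j = m, s
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = D[i - 1][j - 1] + _column_penalty(
                _column_state(mirna[i - 1], site_rev[j - 1]), i)
            if diag == D[i][j]:
                states.append(_column_state(mirna[i - 1], site_rev[j - 1]))
                i, j = i - 1, j - 1
                continue
        if i > 0 and D[i - 1][j] + GAP_PENALTY * _mult(i) == D[i][j]:
            states.append("gap")
            i -= 1
            continue
        states.append("gap")
        j -= 1
    return D[m][s], tuple(reversed(states))


def _central_paired(mirna: str, alignment: Sequence[str]) -> bool:
    """True when miRNA positions 9-11 are all paired (match or wobble)."""
    pos = 0
    status: dict[int, str] = {}
    for state in alignment:
        if state != "gap":
            pos += 1
            status[pos] = state
        # a gap column either skips a miRNA base (leaves it unpaired) or
        # inserts a site base; for the central check only aligned miRNA
        # positions count, so track via non-gap columns only
    return all(status.get(p) in ("match", "G:U") for p in (9, 10, 11))


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
#: substitution penalties indexed [mirna_base, site_base] (before doubling)
_SUB = np.full((4, 4), MISMATCH_PENALTY)
for _a, _b in _WATSON_CRICK:
    _SUB[_BASE_CODE[_a], _BASE_CODE[_b]] = 0.0
for _a, _b in _WOBBLE:
    _SUB[_BASE_CODE[_a], _BASE_CODE[_b]] = WOBBLE_PENALTY


@njit(cache=False)
def _scan_expectations(mcodes, tcodes, sub, cutoff, seed_start, seed_end,
                       gap_penalty):  # pragma: no cover - via scan_transcripts
    """Minimal DP expectation for every (start, window length) pair.

    Returns a list of (start0, wlen, expectation) with expectation <= cutoff.
    """
    m = mcodes.shape[0]
    n = tcodes.shape[0]
    out = []
    maxw = m + 2
    D = np.empty((m + 1, maxw + 1))
    mult = np.empty(m + 2)
    for p in range(1, m + 2):
        mult[p] = 2.0 if (seed_start <= p <= seed_end and p <= m) else 1.0
    mult[m + 1] = mult[m]
    for wlen in range(m - 2, m + 3):
        if wlen < 1 or wlen > n:
            continue
        for start in range(0, n - wlen + 1):
            D[0, 0] = 0.0
            for j in range(1, wlen + 1):
                D[0, j] = D[0, j - 1] + gap_penalty * mult[1]
            for i in range(1, m + 1):
                D[i, 0] = D[i - 1, 0] + gap_penalty * mult[i]
                for j in range(1, wlen + 1):
                    # site reversed: column j faces tcodes[start + wlen - j]
                    sc = sub[mcodes[i - 1], tcodes[start + wlen - j]]
                    diag = D[i - 1, j - 1] + sc * mult[i]
                    up = D[i - 1, j] + gap_penalty * mult[i]
                    left = D[i, j - 1] + gap_penalty * mult[i + 1 if i < m else m]
                    best = diag
                    if up < best:
                        best = up
                    if left < best:
                        best = left
                    D[i, j] = best
            if D[m, wlen] <= cutoff:
                out.append((start, wlen, D[m, wlen]))
    return out


def scan_transcripts(mirnas: Mapping[str, str],
                     transcripts: Mapping[str, str],
                     cutoff: float = 3.0) -> list[TargetHit]:
    """Score every candidate window of every transcript for every miRNA.

    Windows of the miRNA length +/- 2 are slid over each transcript (the
    window scan runs through a compiled kernel; alignments for reported
    hits are recomputed with :func:`score_site`); overlapping hits for the
    same miRNA/transcript keep the best (lowest expectation, then fewer
    gaps, then leftmost). Results are sorted by
    (mirna, expectation, transcript, start).
    """
    hits: list[TargetHit] = []
    for mname in sorted(mirnas):
        mseq = normalize_rna(mirnas[mname])
        mcodes = np.array([_BASE_CODE[c] for c in mseq], dtype=np.int64)
        for tname in sorted(transcripts):
            tseq = normalize_rna(transcripts[tname])
            if len(tseq) < len(mseq) - 2:
                continue
            tcodes = np.array([_BASE_CODE[c] for c in tseq], dtype=np.int64)
            raw: list[TargetHit] = []
            for start, wlen, _exp in _scan_expectations(
                    mcodes, tcodes, _SUB, cutoff, SEED_START, SEED_END,
                    GAP_PENALTY):
                site = tseq[start:start + wlen]
                expectation, aln = score_site(mseq, site)
                raw.append(TargetHit(
                    mirna=mname, transcript=tname,
                    start=start + 1, end=start + wlen,
                    expectation=expectation, alignment=aln,
                    inhibition=("cleavage"
                                if _central_paired(mseq, aln) else "")))
            hits.extend(_dedupe_overlaps(raw))
    hits.sort(key=lambda h: (h.mirna, h.expectation, h.transcript, h.start))
    return hits


def _dedupe_overlaps(hits: list[TargetHit]) -> list[TargetHit]:
    """Keep the best hit in each cluster of mutually overlapping windows."""
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    kept: list[TargetHit] = []
    cluster: list[TargetHit] = []

    def flush() -> None:
        if cluster:
            kept.append(min(cluster,
                            key=lambda h: (h.expectation, h.gaps, h.start)))

    for hit in hits:
        if cluster and hit.start <= cluster[-1].end:
            cluster.append(hit)
        else:
            flush()
            cluster = [hit]
    flush()
    return kept
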