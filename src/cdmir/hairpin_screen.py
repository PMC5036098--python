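"""Novel-miRNA prediction: candidate precursor extraction, folding, and
stem-loop screening.

The built-in folder is a weighted base-pair-maximization dynamic program
(GC=3, AU=2, GU=1, scored in tenths of kcal/mol as a pseudo-energy;
mfe = -score/10) with a minimum hairpin loop of 3 unpaired bases. It is a
deliberately simple, fully deterministic stand-in for a thermodynamic
folder; real RNAfold structures can be imported from the standard
dot-bracket text dialect (``sequence_io.read_structures``) or computed via
the ``RNAfold`` binary when one is on PATH, and then screened with the
thermodynamic-scale criteria.

Because the pseudo-energy scale tops out near -15 kcal/mol per 100 nt
(a perfect GC stem), screening thresholds come in two calibrations:
``ScreenCriteria()`` uses the thermodynamic default (max AMFE -25.0,
bracketing the observed plant-precursor range down to about -65), and
``ScreenCriteria.for_pseudo_energy()`` rescales the AMFE bound for
structures produced by the built-in folder.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .sequence_io import StructureRecord, normalize_rna

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard runtime expectation
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
#: pair weights in tenths of kcal/mol: GC=3, AU=2, GU=1
_PAIR_WEIGHT = np.zeros((4, 4), dtype=np.int64)
for _a, _b, _w in (("G", "C", 3), ("A", "U", 2), ("G", "U", 1)):
    _PAIR_WEIGHT[_BASE_INDEX[_a], _BASE_INDEX[_b]] = _w
    _PAIR_WEIGHT[_BASE_INDEX[_b], _BASE_INDEX[_a]] = _w

MIN_HAIRPIN_LOOP = 3


@njit(cache=False)
def _fill_dp(codes, weights):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    M = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                w = weights[codes[i], codes[k]]
                if w > 0:
                    inner = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = M[k + 1, j] if k + 1 <= j else 0
                    cand = w + inner + right
                    if cand > best:
                        best = cand
            M[i, j] = best
    return M


def _traceback(codes: np.ndarray, M: np.ndarray, i: int, j: int,
               structure: list[str]) -> None:
    """Canonical deterministic traceback: pair position i with the smallest
    admissible partner k achieving the optimum before leaving i unpaired."""
    while i < j:
        if j - i <= MIN_HAIRPIN_LOOP:
            return
        target = M[i, j]
        paired = False
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            w = _PAIR_WEIGHT[codes[i], codes[k]]
            if w == 0:
                continue
            inner = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
            right = M[k + 1, j] if k + 1 <= j else 0
            if w + inner + right == target:
                structure[i] = "("
                structure[k] = ")"
                _traceback(codes, M, i + 1, k - 1, structure)
                i = k + 1
                paired = True
                break
        if not paired:
            i += 1


def fold(sequence: str, record_id: str = "", min_len: int = 15) -> StructureRecord:
    """Fold an RNA sequence with the built-in pseudo-energy folder.

    Raises on non-RNA characters or sequences shorter than ``min_len``
    (precursor folding refuses fragments; pass a smaller ``min_len`` to
    fold short oligos, e.g. for exhaustive cross-checks).
    """
    seq = normalize_rna(sequence)
    if len(seq) < min_len:
        raise ValueError(f"sequence too short to fold ({len(seq)} < {min_len} nt)")
    try:
        codes = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-RNA character in sequence: {exc}") from exc
    M = _fill_dp(codes, _PAIR_WEIGHT)
    structure = ["."] * len(seq)
    _traceback(codes, M, 0, len(seq) - 1, structure)
    score = int(M[0, len(seq) - 1])
    return StructureRecord(id=record_id or "seq", sequence=seq,
                           dotbracket="".join(structure), mfe=-score / 10.0)


def fold_score(sequence: str) -> int:
    """Raw pseudo-energy pair score (tenths of kcal) without traceback."""
    seq = normalize_rna(sequence)
    codes = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    M = _fill_dp(codes, _PAIR_WEIGHT)
    return int(M[0, len(seq) - 1])


def fold_rnafold(sequence: str, record_id: str = "seq") -> StructureRecord:
    """Fold with the external ViennaRNA ``RNAfold`` binary (thermodynamic MFE)."""
    if shutil.which("RNAfold") is None:
        raise RuntimeError("RNAfold binary not found on PATH")
    seq = normalize_rna(sequence)
    out = subprocess.run(["RNAfold", "--noPS"], input=f">{record_id}\n{seq}\n",
                         capture_output=True, text=True, check=True).stdout
    lines = [ln for ln in out.splitlines() if ln.strip()]
    struct_line = lines[-1]
    lpar = struct_line.rfind("(")
    return StructureRecord(id=record_id, sequence=seq,
                           dotbracket=struct_line[:lpar].strip(),
                           mfe=float(struct_line[lpar + 1:].rstrip(")").strip()))


def compute_amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: kcal/mol per 100 nt of precursor."""
    if length <= 0:
        raise ValueError("precursor length must be positive")
    return mfe / length * 100.0


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_windows(tag_sequence: str, contig_sequence: str,
                    flank: int = 150) -> list[tuple[int, int]]:
    """Candidate precursor windows (1-based closed) around each exact hit.

    For a hit spanning [h1, h2], emits [h1-flank, h2] and [h1, h2+flank],
    clipped at the contig ends. The default flank of 150 nt keeps the
    longest plausible plant precursor (~313 nt) reachable.
    """
    tag = normalize_rna(tag_sequence)
    contig = normalize_rna(contig_sequence)
    n = len(contig)
    windows: list[tuple[int, int]] = []
    start = contig.find(tag)
    if start == -1:
        raise ValueError("tag does not occur in contig")
    while start != -1:
        h1, h2 = start + 1, start + len(tag)  # 1-based closed
        left = (max(1, h1 - flank), h2)
        right = (h1, min(n, h2 + flank))
        for w in (left, right):
            if w not in windows:
                windows.append(w)
        start = contig.find(tag, start + 1)
    return windows


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenCriteria:
    """Stem-loop acceptance thresholds.

    ``max_amfe`` is an upper bound (structures must be at least this
    stable); the default -25.0 kcal/mol/100nt is calibrated for
    thermodynamic MFEs so that the observed plant-precursor AMFE range
    (roughly -65 to -25) lies inside the acceptance region. Use
    :meth:`for_pseudo_energy` for structures from the built-in folder.
    """

    min_precursor_len: int = 50
    max_precursor_len: int = 313
    min_mature_len: int = 20
    max_mature_len: int = 23
    max_amfe: float = -25.0
    max_unpaired_mature: int = 6
    require_single_loop: bool = True

    def __post_init__(self) -> None:
        if self.min_precursor_len > self.max_precursor_len:
            raise ValueError("min_precursor_len > max_precursor_len")
        if self.min_mature_len > self.max_mature_len:
            raise ValueError("min_mature_len > max_mature_len")

    @classmethod
    def for_pseudo_energy(cls, max_amfe: float = -8.0, **kwargs) -> "ScreenCriteria":
        """Criteria rescaled to the built-in folder's pseudo-energy units."""
        return cls(max_amfe=max_amfe, **kwargs)


@dataclass
class HairpinCandidate:
    """A folded precursor window with a placed mature sequence."""

    id: str
    contig_id: str
    window_start: int  # 1-based closed, on the contig
    window_end: int
    strand: str
    precursor: str
    structure: StructureRecord
    mature_start: int  # 1-based closed, within the precursor
    mature_end: int
    arm: str = ""

    @property
    def precursor_length(self) -> int:
        return len(self.precursor)

    @property
    def mature_length(self) -> int:
        return self.mature_end - self.mature_start + 1

    @property
    def mfe(self) -> float:
        return self.structure.mfe

    @property
    def amfe(self) -> float:
        return compute_amfe(self.structure.mfe, self.precursor_length)


def terminal_loops(structure: StructureRecord) -> list[tuple[int, int]]:
    """Hairpin (terminal) loops as 0-based closed unpaired intervals.

    A terminal loop is the maximal unpaired interval directly enclosed by
    an innermost pair (i, j) with no pairs between them.
    """
    pairs = structure.pairs()
    loops = []
    for i, j in pairs:
        if not any(i < a < j for a, b in pairs if (a, b) != (i, j)) and \
           not any(i < b < j for a, b in pairs if (a, b) != (i, j)):
            loops.append((i + 1, j - 1))
    return loops


def screen(candidate: HairpinCandidate, criteria: ScreenCriteria
           ) -> tuple[bool, str]:
    """Apply all stem-loop criteria; returns (accepted, reason).

    ``reason`` is "ACCEPT" or the name of the first failing criterion.
    Checks run in a fixed order: precursor length, mature length, AMFE,
    loop topology, mature-vs-loop placement, mature pairing.
    """
    if not (1 <= candidate.mature_start <= candidate.mature_end
            <= candidate.precursor_length):
        raise ValueError("mature interval outside precursor")
    c = candidate
    if not (criteria.min_precursor_len <= c.precursor_length
            <= criteria.max_precursor_len):
        return False, "precursor_length"
    if not (criteria.min_mature_len <= c.mature_length <= criteria.max_mature_len):
        return False, "mature_length"
    if c.amfe > criteria.max_amfe:
        return False, "amfe"
    loops = terminal_loops(c.structure)
    if not loops:
        return False, "no_loop"
    if criteria.require_single_loop and len(loops) > 1:
        return False, "multiple_loops"
    loop_start, loop_end = loops[0]
    m0, m1 = c.mature_start - 1, c.mature_end - 1  # 0-based
    if m0 <= loop_end and m1 >= loop_start:
        return False, "mature_crosses_loop"
    c.arm = "5p" if m1 < loop_start else "3p"
    unpaired = sum(1 for p in range(m0, m1 + 1)
                   if c.structure.dotbracket[p] == ".")
    if unpaired > criteria.max_unpaired_mature:
        return False, "unpaired_mature"
    return True, "ACCEPT"


def build_candidates(tag_sequence: str,
                     contigs: dict[str, str],
                     flank: int = 150,
                     fold_fn: Callable[[str, str], StructureRecord] = fold
                     ) -> list[HairpinCandidate]:
    """Fold every window around every exact hit of a tag in the contig set."""
    tag = normalize_rna(tag_sequence)
    candidates: list[HairpinCandidate] = []
    for contig_id, contig_seq in contigs.items():
        contig_seq = normalize_rna(contig_seq)
        if tag not in contig_seq:
            continue
        for ws, we in extract_windows(tag, contig_seq, flank):
            precursor = contig_seq[ws - 1:we]
            offset = precursor.find(tag)
            if offset == -1 or len(precursor) < 15:
                continue
            structure = fold_fn(precursor, f"{contig_id}:{ws}-{we}")
            candidates.append(HairpinCandidate(
                id=f"{contig_id}:{ws}-{we}", contig_id=contig_id,
                window_start=ws, window_end=we, strand="+",
                precursor=precursor, structure=structure,
                mature_start=offset + 1, mature_end=offset + len(tag)))
    return candidates


def predict_novel(tag_sequence: str,
                  contigs: dict[str, str],
                  criteria: ScreenCriteria,
                  flank: int = 150,
                  fold_fn: Callable[[str, str], StructureRecord] = fold
                  ) -> HairpinCandidate | None:
    """Best accepted hairpin candidate for a tag, or None.

    Overlapping accepted windows for the same tag are deduplicated by
    keeping the lowest-AMFE candidate.
    """
    accepted = [c for c in build_candidates(tag_sequence, contigs, flank, fold_fn)
                if screen(c, criteria)[0]]
    if not accepted:
        return None
    return min(accepted, key=lambda c: (c.amfe, c.id))
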