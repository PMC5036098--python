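"""Integrated Cd-tolerance scoring from growth/physiology measurements and
stem-loop qRT-PCR analysis via the 2^-ddCt model.

The integrated score is a weighted sum of the signed percent changes
(Cd vs control) of five parameters — SPAD (chlorophyll), shoot height,
root length, fresh weight, dry weight — each weighted 0.1429 (~1/7, as
published; the five weights sum to ~0.7145, not 1, and the weight is
exposed as a parameter). With signed percent changes, Cd damage makes the
score more negative, so the more tolerant genotype is the one with the
score closest to zero: `rank_tolerance` orders genotypes by descending
score. (Equivalently, expressing reductions as positive percentages gives
the tolerant genotype the lower score; the two conventions agree on the
ranking.)

qRT-PCR: per replicate, ddCt = (Ct_target - Ct_ref)_treated -
(Ct_target - Ct_ref)_control; RQ = 2^-ddCt; log2 fold change = -ddCt.
Replicate fold changes are averaged on the log scale and classified with
the same +/-1.5 rule as the sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Mapping, Sequence

from .expression import Category, DEFAULT_THRESHOLD

PHENOTYPE_PARAMETERS = ("SPAD", "shoot_height", "root_length",
                        "fresh_weight", "dry_weight")
DEFAULT_WEIGHT = 0.1429


def percent_change(control: float, treated: float) -> float:
    """(treated - control) / control x 100, signed."""
    if control <= 0:
        raise ValueError("control mean must be positive")
    return (treated - control) / control * 100.0


def integrated_score(percent_changes: Mapping[str, float],
                     weight: float = DEFAULT_WEIGHT) -> float:
    """Weighted sum of the five parameters' percent changes."""
    missing = [p for p in PHENOTYPE_PARAMETERS if p not in percent_changes]
    if missing:
        raise ValueError(f"missing phenotype parameter(s): {', '.join(missing)}")
    return sum(percent_changes[p] * weight for p in PHENOTYPE_PARAMETERS)


def genotype_scores(phenotype_rows: Sequence[Mapping],
                    weight: float = DEFAULT_WEIGHT) -> dict[str, float]:
    """Integrated score per genotype from rows with genotype / parameter /
    control_mean / treated_mean fields."""
    changes: dict[str, dict[str, float]] = {}
    for row in phenotype_rows:
        changes.setdefault(row["genotype"], {})[row["parameter"]] = \
            percent_change(float(row["control_mean"]), float(row["treated_mean"]))
    return {g: integrated_score(pc, weight) for g, pc in sorted(changes.items())}


def rank_tolerance(scores: Mapping[str, float]) -> list[str]:
    """Genotypes from most to least Cd-tolerant (descending score)."""
    return sorted(scores, key=lambda g: (-scores[g], g))


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR replicate: target and reference Ct under both conditions."""

    mirna: str
    genotype: str
    replicate: int
    ct_target_control: float
    ct_reference_control: float
    ct_target_treated: float
    ct_reference_treated: float

    def __post_init__(self) -> None:
        for v in (self.ct_target_control, self.ct_reference_control,
                  self.ct_target_treated, self.ct_reference_treated):
            if not (0 < v < 45):
                raise ValueError(f"Ct value {v} outside (0, 45)")

    @property
    def ddct(self) -> float:
        return ((self.ct_target_treated - self.ct_reference_treated)
                - (self.ct_target_control - self.ct_reference_control))


def ddct_fold(replicates: Sequence[QpcrRecord],
              threshold: float = DEFAULT_THRESHOLD
              ) -> tuple[float, float, Category]:
    """(mean RQ, mean log2 fold change, category) over replicates.

    Fold change per replicate is log2(2^-ddCt) = -ddCt; replicates are
    averaged on the log scale (mean fold), and mean RQ is reported as
    2^mean_fold for consistency with that classification.
    """
    if not replicates:
        raise ValueError("no qPCR replicates given")
    folds = [-r.ddct for r in replicates]
    fold = mean(folds)
    if fold >= threshold:
        cat = Category.UP
    elif fold <= -threshold:
        cat = Category.DOWN
    else:
        cat = Category.UNCHANGED
    return 2.0 ** fold, fold, cat


def concordance(qpcr_calls: Mapping[tuple[str, str], tuple[float, Category]],
                seq_calls: Mapping[tuple[str, str], tuple[float | None, Category]]
                ) -> dict:
    """Direction and category agreement between qPCR and sequencing.

    Keys are (mirna, genotype). Direction agreement compares the sign of
    the fold change (sequencing ONLY_* categories count as +/- infinity
    direction; ABSENT keys are skipped for direction). Returns per-key
    flags and summary fractions.
    """
    shared = sorted(set(qpcr_calls) & set(seq_calls))
    if not shared:
        raise ValueError("no shared (mirna, genotype) keys")
    per_key = {}
    dir_agree = cat_agree = dir_total = 0
    for key in shared:
        qf, qc = qpcr_calls[key]
        sf, sc = seq_calls[key]
        if sc == Category.ONLY_TREATED:
            sdir = 1.0
        elif sc == Category.ONLY_CONTROL:
            sdir = -1.0
        elif sf is None:
            sdir = None
        else:
            sdir = 1.0 if sf > 0 else (-1.0 if sf < 0 else 0.0)
        d_ok = None
        if sdir is not None:
            qdir = 1.0 if qf > 0 else (-1.0 if qf < 0 else 0.0)
            d_ok = qdir == sdir
            dir_total += 1
            dir_agree += d_ok
        c_ok = qc == sc or (qc == Category.UP and sc == Category.ONLY_TREATED) \
            or (qc == Category.DOWN and sc == Category.ONLY_CONTROL)
        cat_agree += c_ok
        per_key[key] = {"direction_agrees": d_ok, "category_agrees": c_ok}
    return {
        "per_key": per_key,
        "direction_agreement": dir_agree / dir_total if dir_total else None,
        "category_agreement": cat_agree / len(shared),
        "n": len(shared),
    }
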