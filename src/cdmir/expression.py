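"""TPM normalization, log2 fold-change classification and cross-genotype
comparison of Cd-responsive miRNAs.

The classification rule: with N = TPM_treated / TPM_control and both TPMs
positive, log2 N >= +threshold is UP, log2 N <= -threshold is DOWN, anything
in between (including exactly 0) is UNCHANGED. Zeros route to dedicated
categories rather than pseudocounts: ONLY_TREATED (expressed under Cd
only), ONLY_CONTROL (expressed in control only), ABSENT (neither). The
default threshold is 1.5 log2 units.

An optional significance gate (two-sided Fisher exact test on raw counts
vs library totals, p < 0.01) can demote UP/DOWN calls to UNCHANGED; it is
off by default so that published TPM tables are reproducible from TPM
columns alone, and on for synthetic cohort analysis.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from scipy.stats import fisher_exact

DEFAULT_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.01


class Category(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    UNCHANGED = "UNCHANGED"
    ONLY_TREATED = "ONLY_TREATED"   # arrow-up in the table notation
    ONLY_CONTROL = "ONLY_CONTROL"   # arrow-down
    ABSENT = "ABSENT"               # em-dash

    @property
    def arrow(self) -> str:
        return {"ONLY_TREATED": "up", "ONLY_CONTROL": "down"}.get(self.name, "")


def tpm(count: int | float, total_clean_reads: int) -> float:
    """Tags per million: count / library total clean reads x 1e6."""
    if total_clean_reads <= 0:
        raise ValueError("total_clean_reads must be positive")
    return count / total_clean_reads * 1e6


def classify(tpm_control: float, tpm_treated: float,
             threshold: float = DEFAULT_THRESHOLD
             ) -> tuple[float | None, Category]:
    """(log2 fold change or None for the zero cases, Category)."""
    if tpm_control < 0 or tpm_treated < 0:
        raise ValueError("TPM values must be nonnegative")
    if tpm_control == 0 and tpm_treated == 0:
        return None, Category.ABSENT
    if tpm_control == 0:
        return None, Category.ONLY_TREATED
    if tpm_treated == 0:
        return None, Category.ONLY_CONTROL
    log2n = math.log2(tpm_treated / tpm_control)
    if log2n >= threshold:
        return log2n, Category.UP
    if log2n <= -threshold:
        return log2n, Category.DOWN
    return log2n, Category.UNCHANGED


def significance(count_control: int, count_treated: int,
                 total_control: int, total_treated: int) -> float:
    """Two-sided Fisher exact p-value on the 2x2 count table."""
    if count_control > total_control or count_treated > total_treated:
        raise ValueError("counts exceed library totals")
    table = [[count_control, total_control - count_control],
             [count_treated, total_treated - count_treated]]
    return float(fisher_exact(table, alternative="two-sided").pvalue)


@dataclass
class ExpressionRecord:
    """Per-miRNA expression across the 4-library design."""

    name: str
    family: str
    sequence: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    tpm: dict[str, float] = field(default_factory=dict)
    log2fc: dict[str, float | None] = field(default_factory=dict)   # per genotype
    category: dict[str, Category] = field(default_factory=dict)     # per genotype
    p_value: dict[str, float] = field(default_factory=dict)         # per genotype


def build_expression_records(counts: Mapping[str, Mapping[str, int]],
                             totals: Mapping[str, int],
                             pairs: Mapping[str, tuple[str, str]],
                             families: Mapping[str, str] | None = None,
                             sequences: Mapping[str, str] | None = None,
                             threshold: float = DEFAULT_THRESHOLD,
                             p_gate: bool = False,
                             alpha: float = DEFAULT_ALPHA
                             ) -> list[ExpressionRecord]:
    """Normalize counts to TPM and classify each miRNA per genotype.

    ``pairs`` maps genotype -> (control library id, treated library id).
    With ``p_gate``, UP/DOWN calls whose Fisher p >= alpha are demoted to
    UNCHANGED.
    """
    records = []
    for name in sorted(counts):
        c = dict(counts[name])
        rec = ExpressionRecord(
            name=name,
            family=(families or {}).get(name, ""),
            sequence=(sequences or {}).get(name, ""),
            counts=c,
            tpm={lib: tpm(c.get(lib, 0), totals[lib]) for lib in totals})
        for genotype, (ctrl, trt) in pairs.items():
            log2n, cat = classify(rec.tpm[ctrl], rec.tpm[trt], threshold)
            if p_gate and cat in (Category.UP, Category.DOWN):
                p = significance(c.get(ctrl, 0), c.get(trt, 0),
                                 totals[ctrl], totals[trt])
                rec.p_value[genotype] = p
                if p >= alpha:
                    cat = Category.UNCHANGED
            rec.log2fc[genotype] = log2n
            rec.category[genotype] = cat
        records.append(rec)
    return records


@dataclass
class CrossGenotypeResult:
    """Category pair table, Venn counts and tolerance-associated calls."""

    pair_table: dict[tuple[Category, Category], int]
    venn: dict[Category, dict[str, int]]   # category -> shared / only_a / only_b
    strict_differential: list[str]         # category differs between genotypes
    paper_union: list[str]                 # strict_differential + changed-in-both
    genotype_a: str
    genotype_b: str


def cross_genotype(records: Sequence[ExpressionRecord],
                   genotype_a: str, genotype_b: str) -> CrossGenotypeResult:
    """Compare per-genotype calls across the same miRNA universe.

    "Changed" for the tolerance rules means any non-UNCHANGED, non-ABSENT
    category. ``strict_differential`` lists miRNAs whose categories differ
    between the genotypes; ``paper_union`` additionally includes miRNAs
    changed in both genotypes (e.g. down-regulated in both).
    """
    missing = [r.name for r in records
               if genotype_a not in r.category or genotype_b not in r.category]
    if missing:
        raise ValueError(f"records lack both genotype calls: {missing[:5]}")
    pair_table: Counter = Counter()
    venn: dict[Category, dict[str, int]] = {
        cat: {"shared": 0, "only_" + genotype_a: 0, "only_" + genotype_b: 0}
        for cat in Category}
    strict, union = [], []
    changed = {Category.UP, Category.DOWN, Category.ONLY_TREATED,
               Category.ONLY_CONTROL}
    for rec in sorted(records, key=lambda r: r.name):
        ca, cb = rec.category[genotype_a], rec.category[genotype_b]
        pair_table[(ca, cb)] += 1
        for cat in Category:
            in_a, in_b = ca == cat, cb == cat
            if in_a and in_b:
                venn[cat]["shared"] += 1
            elif in_a:
                venn[cat]["only_" + genotype_a] += 1
            elif in_b:
                venn[cat]["only_" + genotype_b] += 1
        if ca != cb:
            strict.append(rec.name)
            union.append(rec.name)
        elif ca in changed:  # same changed category in both genotypes
            union.append(rec.name)
    return CrossGenotypeResult(pair_table=dict(pair_table), venn=venn,
                               strict_differential=strict, paper_union=union,
                               genotype_a=genotype_a, genotype_b=genotype_b)


def category_counts(records: Sequence[ExpressionRecord], genotype: str
                    ) -> dict[Category, int]:
    out: Counter = Counter(r.category[genotype] for r in records)
    return {cat: out.get(cat, 0) for cat in Category}
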