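"""Seeded generator for a complete synthetic input universe with ground truth.

The generator emulates a two-genotype, control-vs-Cd small-RNA experiment:
four libraries (genotype x treatment) of adapter-ligated reads containing

* planted known miRNAs drawn from a generated mature reference, each with a
  designed per-genotype expression category realized as a TPM profile
  (treated = control x 2^(+/-effect) for UP/DOWN, a +/-0.5 log2 wiggle for
  UNCHANGED, and a hard zero for the ONLY_CONTROL / ONLY_TREATED cases),
* novel miRNAs embedded as near-perfect inverted-repeat hairpins inside
  transcript contigs,
* ncRNA-derived contamination and short degradation fragments (both exact
  substrings of the generated ncRNA references, so the filtering stage can
  remove them), with the treated libraries shifted toward 15-nt fragments,
* unannotated junk tags, and a small designed fraction of reads that fail
  cleaning (low base quality or no detectable 3' adapter).

Counts are realized multinomially per library so library totals are exact
and the TPM denominator is deterministic. A machine-readable TruthManifest
records every planted sequence, designed category, realized count, hairpin
structure, qPCR RQ and phenotype effect, sufficient to recompute every
stage's expected output. One master seed drives per-stage child streams
(``numpy.random.SeedSequence.spawn``) so adding a stage never perturbs
earlier streams; identical config+seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .hairpin_screen import ScreenCriteria, fold, predict_novel
from .sequence_io import Library, write_fasta, write_table
from .preprocess import PreprocessConfig

RNA_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: library ids in fixed order: genotype G (sensitive), Y (tolerant)
LIBRARY_DESIGN = (
    Library("G-ctl", "G", "control"),
    Library("G-cd", "G", "treated"),
    Library("Y-ctl", "Y", "control"),
    Library("Y-cd", "Y", "treated"),
)

#: designed (category_G, category_Y) pairs for the expressed known miRNAs,
#: emulating the study's mixture: down-in-both, up-in-both, genotype-specific
#: calls and unchanged controls.
DEFAULT_KNOWN_DESIGN = (
    [("DOWN", "DOWN")] * 10
    + [("UP", "UP")] * 8
    + [("UP", "UNCHANGED")] * 4
    + [("UNCHANGED", "DOWN")] * 6
    + [("UNCHANGED", "UNCHANGED")] * 8
)

DEFAULT_NOVEL_DESIGN = (
    [("DOWN", "DOWN"), ("UNCHANGED", "DOWN"), ("ONLY_CONTROL", "ONLY_CONTROL"),
     ("ONLY_TREATED", "UNCHANGED"), ("UP", "UP"), ("UP", "UNCHANGED"),
     ("UNCHANGED", "ONLY_TREATED"), ("UNCHANGED", "UNCHANGED"),
     ("UNCHANGED", "UNCHANGED"), ("UNCHANGED", "UNCHANGED")]
)


@dataclass
class SimConfig:
    """All tunable simulation conditions (defaults ARE the study design)."""

    seed: int = 0
    library_depth: int = 200_000
    read_length: int = 60
    adapter3: str = "UCGUAUGCCGUCUUCUGCUUGU"
    # known miRNA universe
    n_known_reference: int = 48
    known_length_weights: Mapping[int, float] = field(
        default_factory=lambda: {20: 0.15, 21: 0.55, 22: 0.20, 24: 0.10})
    known_design: Sequence[tuple[str, str]] = tuple(DEFAULT_KNOWN_DESIGN)
    baseline_tpm_range: tuple[float, float] = (500.0, 20_000.0)
    effect_log2fc: float = 2.5
    unchanged_wiggle_log2: float = 0.5
    isomir_fraction: float = 0.15    # share of a miRNA's reads on a 1-mm variant
    min_reference_spacing: int = 4   # pairwise Hamming between equal-length refs
    # novel hairpins
    novel_design: Sequence[tuple[str, str]] = tuple(DEFAULT_NOVEL_DESIGN)
    novel_tpm_range: tuple[float, float] = (500.0, 5_000.0)
    novel_mature_length_weights: Mapping[int, float] = field(
        default_factory=lambda: {20: 0.2, 21: 0.2, 22: 0.4, 23: 0.2})
    precursor_length_range: tuple[int, int] = (50, 160)
    # background composition (shares of the non-miRNA remainder, per treatment)
    background_shares: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {  # (contamination, degradation, junk)
            "control": (0.50, 0.12, 0.38),
            "treated": (0.35, 0.40, 0.25)})
    n_contaminant_tags: int = 400
    n_degradation_tags: int = 300
    n_junk_tags: int = 1500
    reject_fraction: float = 0.05   # reads designed to fail cleaning
    # ncRNA reference sizes: class -> (n sequences, length)
    ncrna_sizes: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"tRNA": (20, 75), "rRNA": (6, 1500),
                                 "snRNA": (10, 150), "snoRNA": (10, 120)})
    n_plain_contigs: int = 20
    plain_contig_length: int = 500
    # phenotype / qPCR
    phenotype_control_means: Mapping[str, float] = field(
        default_factory=lambda: {"SPAD": 38.5, "shoot_height": 24.0,
                                 "root_length": 16.0, "fresh_weight": 8.5,
                                 "dry_weight": 0.9})
    phenotype_changes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "G": {"SPAD": -35.0, "shoot_height": -30.0, "root_length": -40.0,
                  "fresh_weight": -32.0, "dry_weight": -28.0},
            "Y": {"SPAD": -17.5, "shoot_height": -15.0, "root_length": -20.0,
                  "fresh_weight": -16.0, "dry_weight": -14.0}})
    ct_noise_sigma: float = 0.1
    qpcr_replicates: int = 3
    n_qpcr_known: int = 4
    n_qpcr_novel: int = 2

    def __post_init__(self) -> None:
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if not (0 <= self.reject_fraction < 1):
            raise ValueError("reject_fraction must be in [0, 1)")
        for shares in self.background_shares.values():
            if abs(sum(shares) - 1.0) > 1e-9:
                raise ValueError("background shares must sum to 1")


@dataclass
class TruthManifest:
    """Ground truth for every planted feature; JSON-serializable."""

    libraries: list[dict]
    known_mirnas: list[dict]
    novel_mirnas: list[dict]
    contaminants: list[dict]
    degradation: list[dict]
    n_junk_tags: int
    qpcr: list[dict]
    phenotype: dict
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def default(obj):
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            raise TypeError(f"not JSON-serializable: {type(obj)}")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=default)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_BASES, size=length))


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Altschul-Erickson style: permute each base's successor list, retrying
    until the chosen last-edges form a walk that uses every edge (a valid
    Eulerian path from the first to the last base).
    """
    seq = sequence
    if len(seq) < 3:
        return seq
    for _ in range(200):
        successors: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            successors.setdefault(a, []).append(b)
        for lst in successors.values():
            perm = rng.permutation(len(lst))
            lst[:] = [lst[i] for i in perm]
        out = [seq[0]]
        node = seq[0]
        ok = True
        for _step in range(len(seq) - 1):
            nxt_list = successors.get(node)
            if not nxt_list:
                ok = False
                break
            node = nxt_list.pop(0)
            out.append(node)
        if ok and len(out) == len(seq):
            return "".join(out)
    return seq  # degenerate composition; identity is a valid shuffle


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

@dataclass
class References:
    mature: list[tuple[str, str]]          # (name, sequence), full reference
    ncrna: dict[str, list[tuple[str, str]]]
    contigs: list[tuple[str, str]]
    hairpins: list[dict]                   # novel hairpin truth entries


def _draw_lengths(rng: np.random.Generator, weights: Mapping[int, float],
                  n: int) -> list[int]:
    lengths = sorted(weights)
    p = np.array([weights[k] for k in lengths], dtype=float)
    p /= p.sum()
    return [int(x) for x in rng.choice(lengths, size=n, p=p)]


def _adapter_probe(config: SimConfig, preprocess: PreprocessConfig | None = None
                   ) -> str:
    overlap = preprocess.min_overlap if preprocess else 8
    return config.adapter3[:overlap]


def _valid_insert(seq: str, probe: str, adapter: str) -> bool:
    """Insert must not trigger adapter trimming early (also across the
    insert/adapter junction) so the pipeline recovers it verbatim."""
    return (seq + adapter).find(probe) == len(seq)


def simulate_references(config: SimConfig, rng: np.random.Generator
                        ) -> References:
    """Generate mature/ncRNA/contig references with planted hairpins.

    Mature sequences of equal length are pairwise >= ``min_reference_spacing``
    mismatches apart so <=2-mismatch matching is unambiguous even for the
    planted 1-mismatch isomiR variants; novel matures keep the same spacing
    from the known reference. Raises if the requested count cannot be placed.
    """
    probe = _adapter_probe(config)
    adapter = config.adapter3

    # --- mature reference ---
    lengths = _draw_lengths(rng, config.known_length_weights,
                            config.n_known_reference)
    by_length: dict[int, list[str]] = {}
    mature: list[tuple[str, str]] = []
    for idx, L in enumerate(lengths):
        for attempt in range(500):
            cand = _random_rna(rng, L)
            if not _valid_insert(cand, probe, adapter):
                continue
            if all(_hamming(cand, other) >= config.min_reference_spacing
                   for other in by_length.get(L, [])):
                by_length.setdefault(L, []).append(cand)
                mature.append((f"syn-miR{idx + 1}", cand))
                break
        else:
            raise ValueError(
                "cannot place requested mature reference with the required "
                "spacing; reduce n_known_reference or length concentration")

    # --- ncRNA references ---
    ncrna: dict[str, list[tuple[str, str]]] = {}
    for cls, (n, L) in config.ncrna_sizes.items():
        ncrna[cls] = [(f"{cls}-{i + 1}", _random_rna(rng, L)) for i in range(n)]

    # --- novel matures + hairpin contigs ---
    pseudo_criteria = ScreenCriteria.for_pseudo_energy(
        min_precursor_len=config.precursor_length_range[0],
        max_precursor_len=config.precursor_length_range[1] + 160)
    ncrna_pool = [s for recs in ncrna.values() for _n, s in recs]
    contigs: list[tuple[str, str]] = []
    hairpins: list[dict] = []
    mature_lengths = _draw_lengths(rng, config.novel_mature_length_weights,
                                   len(config.novel_design))
    for h_idx, mlen in enumerate(mature_lengths):
        name = f"novel-mir{h_idx + 1}"
        placed = False
        for attempt in range(60):
            cand = _random_rna(rng, mlen)
            if not _valid_insert(cand, probe, adapter):
                continue
            if any(cand in ref for ref in ncrna_pool):
                continue
            if not all(_hamming(cand, other) >= config.min_reference_spacing
                       for other in by_length.get(mlen, [])):
                continue
            if any(_hamming(cand, prev["mature"]) < config.min_reference_spacing
                   for prev in hairpins if len(prev["mature"]) == mlen):
                continue
            prec_len = int(rng.integers(config.precursor_length_range[0],
                                        config.precursor_length_range[1] + 1))
            loop_len = int(rng.integers(4, 9))
            arm_len = (prec_len - loop_len) // 2
            if arm_len < mlen:
                prec_len = 2 * mlen + loop_len + 4
                arm_len = mlen + 2
            arm5 = cand + _random_rna(rng, arm_len - mlen)
            loop = "".join(rng.choice(np.array(list("AC")), size=loop_len))
            precursor = arm5 + loop + _revcomp(arm5)
            # low-structure pads so the hairpin is the only stable fold
            pad5 = "".join(rng.choice(np.array(list("AC")),
                                      size=int(rng.integers(20, 61))))
            pad3 = "".join(rng.choice(np.array(list("AC")),
                                      size=int(rng.integers(20, 61))))
            contig_seq = pad5 + precursor + pad3
            if contig_seq.find(cand) != len(pad5):
                continue  # mature accidentally occurs in a pad
            best = predict_novel(cand, {f"contig-hp{h_idx + 1}": contig_seq},
                                 pseudo_criteria)
            if best is None:
                continue
            contig_id = f"contig-hp{h_idx + 1}"
            contigs.append((contig_id, contig_seq))
            structure = fold(precursor, name)
            hairpins.append({
                "name": name, "mature": cand, "contig": contig_id,
                "precursor": precursor,
                "precursor_start": len(pad5) + 1,
                "precursor_end": len(pad5) + len(precursor),
                "dotbracket": structure.dotbracket,
                "pseudo_mfe": structure.mfe,
            })
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place hairpin {name}; relax "
                             "precursor/mature length parameters")

    for i in range(config.n_plain_contigs):
        contigs.append((f"contig-{i + 1}",
                        _random_rna(rng, config.plain_contig_length)))
    return References(mature=mature, ncrna=ncrna, contigs=contigs,
                      hairpins=hairpins)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _designed_tpm(category: str, base: float, effect: float, wiggle: float,
                  rng: np.random.Generator) -> tuple[float, float]:
    """(control TPM, treated TPM) realizing a designed category."""
    if category == "UP":
        return base, base * 2 ** effect
    if category == "DOWN":
        return base, base * 2 ** -effect
    if category == "UNCHANGED":
        shift = rng.uniform(-wiggle, wiggle)
        return base, base * 2 ** shift
    if category == "ONLY_TREATED":
        return 0.0, base
    if category == "ONLY_CONTROL":
        return base, 0.0
    if category == "ABSENT":
        return 0.0, 0.0
    raise ValueError(f"unknown designed category {category!r}")


def _mutate_one(seq: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(seq)))
    alternatives = [b for b in "ACGU" if b != seq[pos]]
    return seq[:pos] + alternatives[int(rng.integers(3))] + seq[pos + 1:]


def _draw_substring(rng: np.random.Generator, pool: list[str],
                    length: int) -> str:
    src = pool[int(rng.integers(len(pool)))]
    if len(src) <= length:
        return src
    start = int(rng.integers(len(src) - length + 1))
    return src[start:start + length]


def simulate_libraries(config: SimConfig, references: References,
                       rng: np.random.Generator, outdir: Path
                       ) -> TruthManifest:
    """Write four FASTQ libraries and return the TruthManifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    adapter_dna = config.adapter3.replace("U", "T")
    probe = _adapter_probe(config)
    warnings: list[str] = []

    # ---- designed miRNA expression ----
    expressed = references.mature[:len(config.known_design)]
    if len(expressed) < len(config.known_design):
        raise ValueError("known_design longer than mature reference")
    known_entries: list[dict] = []
    lo, hi = config.baseline_tpm_range
    for (name, seq), (cat_g, cat_y) in zip(expressed, config.known_design):
        entry = {"name": name, "sequence": seq,
                 "category": {"G": cat_g, "Y": cat_y}, "tpm": {}, "variant": None}
        for genotype, cat in (("G", cat_g), ("Y", cat_y)):
            base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            ctl, trt = _designed_tpm(cat, base, config.effect_log2fc,
                                     config.unchanged_wiggle_log2, rng)
            entry["tpm"][f"{genotype}-ctl"] = ctl
            entry["tpm"][f"{genotype}-cd"] = trt
        if config.isomir_fraction > 0:
            for _ in range(50):
                var = _mutate_one(seq, rng)
                if _valid_insert(var, probe, config.adapter3):
                    entry["variant"] = var
                    break
        known_entries.append(entry)

    novel_entries: list[dict] = []
    lo_n, hi_n = config.novel_tpm_range
    for hp, (cat_g, cat_y) in zip(references.hairpins, config.novel_design):
        entry = dict(hp)
        entry["category"] = {"G": cat_g, "Y": cat_y}
        entry["tpm"] = {}
        for genotype, cat in (("G", cat_g), ("Y", cat_y)):
            base = float(np.exp(rng.uniform(np.log(lo_n), np.log(hi_n))))
            ctl, trt = _designed_tpm(cat, base, config.effect_log2fc,
                                     config.unchanged_wiggle_log2, rng)
            entry["tpm"][f"{genotype}-ctl"] = ctl
            entry["tpm"][f"{genotype}-cd"] = trt
        novel_entries.append(entry)

    # ---- background pools ----
    ncrna_pool = [s for recs in references.ncrna.values() for _n, s in recs]
    taken: set[str] = {e["sequence"] for e in known_entries}
    taken |= {e["variant"] for e in known_entries if e["variant"]}
    taken |= {e["mature"] for e in novel_entries}

    def draw_pool(n: int, length_weights: Mapping[int, float],
                  from_ncrna: bool, label: str) -> list[dict]:
        out: list[dict] = []
        lengths = _draw_lengths(rng, length_weights, n)
        for L in lengths:
            for _ in range(200):
                if from_ncrna:
                    cls_idx = int(rng.integers(len(references.ncrna)))
                    cls = sorted(references.ncrna)[cls_idx]
                    src = [s for _n, s in references.ncrna[cls]]
                    seq = _draw_substring(rng, src, L)
                else:
                    cls = label
                    seq = _random_rna(rng, L)
                if seq in taken or not _valid_insert(seq, probe, config.adapter3):
                    continue
                taken.add(seq)
                out.append({"sequence": seq, "class": cls})
                break
        return out

    contaminant_weights = {20: 0.08, 21: 0.10, 22: 0.10, 23: 0.07, 24: 0.45,
                           25: 0.06, 26: 0.05, 28: 0.05, 30: 0.04}
    degradation_weights = {12: 0.08, 13: 0.10, 14: 0.15, 15: 0.40, 16: 0.12,
                           17: 0.08, 18: 0.07}
    junk_weights = {18: 0.06, 20: 0.10, 21: 0.08, 22: 0.08, 23: 0.06,
                    24: 0.42, 26: 0.08, 28: 0.06, 30: 0.06}
    contaminants = draw_pool(config.n_contaminant_tags, contaminant_weights,
                             True, "contaminant")
    degradation = draw_pool(config.n_degradation_tags, degradation_weights,
                            True, "degradation")
    junk = draw_pool(config.n_junk_tags, junk_weights, False, "junk")

    # fixed per-tag relative weights within each background pool
    cont_w = rng.random(len(contaminants)) + 0.2
    deg_w = rng.random(len(degradation)) + 0.2
    junk_w = rng.random(len(junk)) + 0.2

    # ---- per-library species probabilities and counts ----
    n_clean = int(round(config.library_depth * (1 - config.reject_fraction)))
    species: list[str] = []     # insert sequences in fixed order
    for e in known_entries:
        species.append(e["sequence"])
        if e["variant"]:
            species.append(e["variant"])
    species += [e["mature"] for e in novel_entries]
    species += [c["sequence"] for c in contaminants]
    species += [d["sequence"] for d in degradation]
    species += [j["sequence"] for j in junk]

    libraries_meta: list[dict] = []
    for e in known_entries + novel_entries:
        e["counts"] = {}
    realized: dict[str, dict[str, int]] = {}

    for lib in LIBRARY_DESIGN:
        p = np.zeros(len(species))
        i = 0
        mirna_mass = 0.0
        for e in known_entries:
            tpm = e["tpm"][lib.id] / 1e6
            if e["variant"]:
                p[i] = tpm * (1 - config.isomir_fraction)
                p[i + 1] = tpm * config.isomir_fraction
                i += 2
            else:
                p[i] = tpm
                i += 1
            mirna_mass += tpm
        for e in novel_entries:
            p[i] = e["tpm"][lib.id] / 1e6
            mirna_mass += p[i]
            i += 1
        remainder = 1.0 - mirna_mass
        if remainder <= 0:
            raise ValueError("designed miRNA TPMs exceed the library")
        shares = config.background_shares[lib.treatment]
        for pool_w, share in ((cont_w, shares[0]), (deg_w, shares[1]),
                              (junk_w, shares[2])):
            block = pool_w / pool_w.sum() * remainder * share
            p[i:i + len(pool_w)] = block
            i += len(pool_w)
        smallest = p[p > 0].min() * n_clean
        if smallest < 1.0:
            warnings.append(
                f"{lib.id}: smallest designed species expects {smallest:.2f} "
                "reads (<1); depth may be too small")
        counts = rng.multinomial(n_clean, p / p.sum())
        realized[lib.id] = {}
        i = 0
        for e in known_entries:
            c = int(counts[i])
            if e["variant"]:
                c += int(counts[i + 1])
                i += 2
            else:
                i += 1
            e["counts"][lib.id] = c
        for e in novel_entries:
            e["counts"][lib.id] = int(counts[i])
            i += 1
        for seq, c in zip(species, counts):
            realized[lib.id][seq] = int(c)

        # ---- emit FASTQ ----
        reads: list[tuple[str, str]] = []
        for seq, c in zip(species, counts):
            if c == 0:
                continue
            insert_dna = seq.replace("U", "T")
            body = insert_dna + adapter_dna
            tail_len = config.read_length - len(body)
            for _ in range(int(c)):
                tail = ("".join(rng.choice(RNA_BASES, size=tail_len))
                        .replace("U", "T") if tail_len > 0 else "")
                reads.append((body + tail, "I" * (len(body) + len(tail))))
        n_reject = config.library_depth - n_clean
        n_lowq = n_reject // 2
        for k in range(n_reject):
            L = int(rng.integers(15, 31))
            ins = _random_rna(rng, L)
            while not _valid_insert(ins, probe, config.adapter3):
                ins = _random_rna(rng, L)
            if k < n_lowq:  # low-quality base inside the insert
                body = ins.replace("U", "T") + adapter_dna
                tail_len = config.read_length - len(body)
                tail = ("".join(rng.choice(RNA_BASES, size=tail_len))
                        .replace("U", "T") if tail_len > 0 else "")
                qual = list("I" * (len(body) + len(tail)))
                qual[int(rng.integers(L))] = "#"
                reads.append((body + tail, "".join(qual)))
            else:           # no detectable adapter anywhere
                seq_na = _random_rna(rng, config.read_length).replace("U", "T")
                while probe.replace("U", "T") in seq_na:
                    seq_na = _random_rna(rng, config.read_length).replace("U", "T")
                reads.append((seq_na, "I" * config.read_length))
        order = rng.permutation(len(reads))
        with open(outdir / f"{lib.id}.fastq", "w") as fh:
            for rank, idx in enumerate(order):
                seq, qual = reads[idx]
                fh.write(f"@{lib.id}_{rank}\n{seq}\n+\n{qual}\n")
        libraries_meta.append({
            "id": lib.id, "genotype": lib.genotype, "treatment": lib.treatment,
            "raw_reads": config.library_depth, "clean_reads": n_clean,
            "rejected_reads": n_reject})

    return TruthManifest(
        libraries=libraries_meta,
        known_mirnas=known_entries,
        novel_mirnas=novel_entries,
        contaminants=contaminants,
        degradation=degradation,
        n_junk_tags=len(junk),
        qpcr=[], phenotype={}, warnings=warnings)


# ---------------------------------------------------------------------------
# phenotype + qPCR tables
# ---------------------------------------------------------------------------

def simulate_tables(config: SimConfig, manifest: TruthManifest,
                    rng: np.random.Generator, outdir: Path) -> None:
    """Write phenotype and Ct tables; extends the manifest in place."""
    outdir = Path(outdir)
    pheno_rows = []
    for genotype in sorted(config.phenotype_changes):
        for param, ctrl in config.phenotype_control_means.items():
            pc = config.phenotype_changes[genotype][param]
            pheno_rows.append({"genotype": genotype, "parameter": param,
                               "control_mean": ctrl,
                               "treated_mean": ctrl * (1 + pc / 100.0)})
    write_table(pheno_rows, outdir / "phenotype.tsv",
                ["genotype", "parameter", "control_mean", "treated_mean"])
    manifest.phenotype = {
        "designed_changes": {g: dict(v)
                             for g, v in config.phenotype_changes.items()},
        "control_means": dict(config.phenotype_control_means)}

    # qPCR panel: first n known + first n novel planted miRNAs
    panel = (manifest.known_mirnas[:config.n_qpcr_known]
             + manifest.novel_mirnas[:config.n_qpcr_novel])
    ct_rows, qpcr_truth = [], []
    for entry in panel:
        name = entry["name"]
        assay_seq = entry.get("sequence") or entry["mature"]
        for genotype in ("G", "Y"):
            ctl_tpm = entry["tpm"][f"{genotype}-ctl"]
            trt_tpm = entry["tpm"][f"{genotype}-cd"]
            if ctl_tpm > 0 and trt_tpm > 0:
                fold = float(np.log2(trt_tpm / ctl_tpm))
            elif trt_tpm > 0:
                fold = 3.0     # expressed under Cd only: strong induction
            elif ctl_tpm > 0:
                fold = -3.0
            else:
                continue
            qpcr_truth.append({"mirna": name, "sequence": assay_seq,
                               "genotype": genotype,
                               "designed_fold": fold,
                               "designed_rq": float(2.0 ** fold)})
            for rep in range(1, config.qpcr_replicates + 1):
                noise = rng.normal(0.0, config.ct_noise_sigma, size=4)
                common = {"mirna": name, "sequence": assay_seq,
                          "genotype": genotype, "replicate": rep}
                ct_rows += [
                    {**common, "condition": "control",
                     "ct_target": 25.0 + noise[0], "ct_reference": 20.0 + noise[1]},
                    {**common, "condition": "treated",
                     "ct_target": 25.0 - fold + noise[2],
                     "ct_reference": 20.0 + noise[3]},
                ]
    write_table(ct_rows, outdir / "qpcr_ct.tsv",
                ["mirna", "sequence", "genotype", "condition", "replicate",
                 "ct_target", "ct_reference"],
                precision={"ct_target": 3, "ct_reference": 3})
    manifest.qpcr = qpcr_truth


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig, outdir: str | Path) -> TruthManifest:
    """Generate the complete input universe under ``outdir``.

    Writes: four FASTQ libraries, mature.fa, one FASTA per ncRNA class,
    contigs.fa, phenotype.tsv, qpcr_ct.tsv and manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_ref = np.random.default_rng(streams[0])
    rng_lib = np.random.default_rng(streams[1])
    rng_tab = np.random.default_rng(streams[2])

    refs = simulate_references(config, rng_ref)
    write_fasta(refs.mature, outdir / "mature.fa")
    for cls, recs in refs.ncrna.items():
        write_fasta(recs, outdir / f"{cls.lower()}.fa")
    write_fasta(refs.contigs, outdir / "contigs.fa")

    manifest = simulate_libraries(config, refs, rng_lib, outdir)
    simulate_tables(config, manifest, rng_tab, outdir)
    manifest.to_json(outdir / "manifest.json")
    return manifest
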