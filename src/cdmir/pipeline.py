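"""End-to-end orchestration: preprocess -> ncRNA filter -> known matching ->
novel hairpin prediction -> differential expression -> target scan ->
phenotype/qPCR, with per-stage record accounting and a plain-text report.

Every stage logs its input/output record counts; no record is dropped
silently. Re-running with an unchanged config and inputs reproduces
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import expression as expr
from . import phenotype_qpcr as pq
from .hairpin_screen import ScreenCriteria, fold, predict_novel
from .known_mirna import family_census, load_mature_reference, match_known
from .preprocess import PreprocessConfig, clean_reads, collapse_tags, \
    length_distribution
from .reference_match import NCRNA_CLASSES, ReferenceSet, filter_ncrna, \
    map_to_contigs
from .sequence_io import Library, normalize_rna, read_fasta, read_fastq, \
    read_table, write_table
from .target_scoring import scan_transcripts

log = logging.getLogger("cdmir")


@dataclass
class RunConfig:
    """Declarative run description (usually loaded from YAML)."""

    libraries: list[dict]                 # id / genotype / treatment / fastq
    mature_fa: str
    ncrna_fa: dict[str, str]              # class -> FASTA path
    contig_fa: list[str]
    outdir: str
    phenotype_tsv: str | None = None
    qpcr_tsv: str | None = None
    seed: int = 0
    adapter3: str = "UCGUAUGCCGUCUUCUGCUUGU"
    quality_floor: int = 20
    min_len: int = 10
    max_len: int = 35
    threshold: float = 1.5
    p_gate: bool = True
    flank: int = 150
    pseudo_energy_criteria: bool = True   # built-in folder -> pseudo AMFE scale
    target_cutoff: float = 3.0
    scan_targets_for: str = "novel"       # "novel", "all" or "none"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> list[Library]:
        libs = [Library(d["id"], d["genotype"], d["treatment"])
                for d in self.libraries]
        per_genotype: dict[str, set[str]] = {}
        for lib in libs:
            per_genotype.setdefault(lib.genotype, set()).add(lib.treatment)
        for genotype, treatments in per_genotype.items():
            if treatments != {"control", "treated"}:
                raise ValueError(
                    f"genotype {genotype!r} needs exactly one control and one "
                    f"treated library, has {sorted(treatments)}")
        if len({lib.id for lib in libs}) != len(libs):
            raise ValueError("duplicate library id")
        for d in self.libraries:
            if not Path(d["fastq"]).exists():
                raise FileNotFoundError(d["fastq"])
        return libs


@dataclass
class RunResult:
    """Everything the pipeline computed, for programmatic access."""

    summaries: dict
    tags: list
    mapping_summary: object
    known_counts: dict
    novel: list[dict]
    records: list
    cross: object
    target_hits: list
    phenotype_scores: dict[str, float]
    tolerance_ranking: list[str]
    qpcr_calls: dict
    concordance: dict | None
    length_histograms: dict[str, dict[int, float]] = field(default_factory=dict)


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage for which inputs are configured."""
    libs = config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pre_cfg = PreprocessConfig(adapter3=config.adapter3,
                               min_len=config.min_len, max_len=config.max_len,
                               quality_floor=config.quality_floor)

    # --- preprocess + collapse ---
    streams, summaries = {}, {}
    for lib, d in zip(libs, config.libraries):
        stream, summary = clean_reads(read_fastq(d["fastq"], lib.id),
                                      pre_cfg, lib.id)
        streams[lib.id] = stream
        summaries[lib.id] = summary
    tags = collapse_tags(streams, summaries)
    for lib in libs:
        s = summaries[lib.id]
        log.info("preprocess %s: %d raw -> %d clean (%d unique)",
                 lib.id, s.raw_reads, s.clean_reads, s.unique_clean_reads)
    hists = {lib.id: length_distribution(tags, lib.id) for lib in libs}

    # --- ncRNA filtering ---
    ncrna_sets = [ReferenceSet(cls, [s for _i, _d, s in read_fasta(path)])
                  for cls, path in config.ncrna_fa.items()]
    kept, removed = filter_ncrna(tags, ncrna_sets)
    log.info("ncRNA filter: %d tags in, %d kept, %d removed",
             len(tags), len(kept), len(removed))

    # --- contig mapping accounting ---
    contigs: dict[str, str] = {}
    for path in config.contig_fa:
        for cid, _desc, seq in read_fasta(path):
            contigs[cid] = normalize_rna(seq)
    contig_set = ReferenceSet("EST/GSS", list(contigs.values()))
    lib_ids = [lib.id for lib in libs]
    hit_flags, mapping_summary = map_to_contigs(kept, contig_set, lib_ids)

    # --- known miRNA matching ---
    mature = load_mature_reference(read_fasta(config.mature_fa))
    matches, known_counts = match_known(kept, mature)
    matched_tag_seqs = {m.tag_sequence for m in matches}
    log.info("known matching: %d tags matched %d reference entries",
             len(matched_tag_seqs),
             sum(1 for c in known_counts.values() if sum(c.values())))

    # --- novel prediction on unannotated contig-mapped tags ---
    criteria = (ScreenCriteria.for_pseudo_energy()
                if config.pseudo_energy_criteria else ScreenCriteria())
    novel: list[dict] = []
    for tag in kept:
        if tag.sequence in matched_tag_seqs or not hit_flags.get(tag.sequence):
            continue
        best = predict_novel(tag.sequence, contigs, criteria,
                             flank=config.flank, fold_fn=fold)
        if best is not None:
            novel.append({"sequence": tag.sequence, "counts": dict(tag.counts),
                          "candidate": best})
    novel.sort(key=lambda n: n["sequence"])
    for k, n in enumerate(novel, start=1):
        n["name"] = f"novel-mir{k}"
    log.info("novel prediction: %d accepted hairpins", len(novel))

    # --- differential expression ---
    totals = {lib.id: summaries[lib.id].clean_reads for lib in libs}
    pairs = {}
    for lib in libs:
        pairs.setdefault(lib.genotype, {})[lib.treatment] = lib.id
    pairs = {g: (d["control"], d["treated"]) for g, d in sorted(pairs.items())}
    counts = {name: dict(c) for name, c in known_counts.items()}
    families = {m.name: m.family for m in mature}
    sequences = {m.name: m.sequence for m in mature}
    for n in novel:
        counts[n["name"]] = n["counts"]
        families[n["name"]] = "novel"
        sequences[n["name"]] = n["sequence"]
    records = expr.build_expression_records(
        counts, totals, pairs, families, sequences,
        threshold=config.threshold, p_gate=config.p_gate)
    genotypes = sorted(pairs)
    cross = (expr.cross_genotype(records, genotypes[0], genotypes[1])
             if len(genotypes) == 2 else None)

    # --- target scan ---
    if config.scan_targets_for == "none":
        target_hits = []
    else:
        if config.scan_targets_for == "all":
            query = {name: sequences[name] for name in counts
                     if sum(counts[name].values()) > 0}
        else:
            query = {n["name"]: n["sequence"] for n in novel}
        target_hits = scan_transcripts(query, contigs, config.target_cutoff)
    log.info("target scan: %d hits at cutoff %.1f",
             len(target_hits), config.target_cutoff)

    # --- phenotype scores ---
    phenotype_scores: dict[str, float] = {}
    ranking: list[str] = []
    if config.phenotype_tsv:
        rows = read_table(config.phenotype_tsv)
        phenotype_scores = pq.genotype_scores(rows)
        ranking = pq.rank_tolerance(phenotype_scores)

    # --- qPCR ---
    qpcr_calls: dict = {}
    concord = None
    if config.qpcr_tsv:
        qpcr_calls = analyze_qpcr(read_table(config.qpcr_tsv), config.threshold)
        seq_by_sequence = {r.sequence: r for r in records if r.sequence}
        seq_calls = {}
        for (name, assay_seq, genotype), (_rq, fold_val, _cat) in qpcr_calls.items():
            rec = seq_by_sequence.get(normalize_rna(assay_seq))
            if rec is not None and genotype in rec.category:
                seq_calls[(name, genotype)] = (rec.log2fc[genotype],
                                               rec.category[genotype])
        flat_qpcr = {(name, genotype): (fold_val, cat)
                     for (name, _s, genotype), (_rq, fold_val, cat)
                     in qpcr_calls.items()}
        if seq_calls:
            concord = pq.concordance(flat_qpcr, seq_calls)

    result = RunResult(
        summaries=summaries, tags=tags, mapping_summary=mapping_summary,
        known_counts=known_counts, novel=novel, records=records, cross=cross,
        target_hits=target_hits, phenotype_scores=phenotype_scores,
        tolerance_ranking=ranking, qpcr_calls=qpcr_calls, concordance=concord,
        length_histograms=hists)
    write_outputs(result, libs, outdir, config)
    return result


def analyze_qpcr(rows: Sequence[Mapping], threshold: float = 1.5
                 ) -> dict[tuple[str, str, str], tuple[float, float, object]]:
    """Group Ct rows into replicates and compute 2^-ddCt folds.

    Rows carry mirna / sequence / genotype / condition / replicate /
    ct_target / ct_reference. Returns
    {(mirna, sequence, genotype): (mean RQ, mean fold, category)}.
    """
    grouped: dict[tuple, dict[str, dict[str, float]]] = {}
    for row in rows:
        key = (row["mirna"], row.get("sequence", ""), row["genotype"],
               int(row["replicate"]))
        grouped.setdefault(key, {})[row["condition"]] = {
            "t": float(row["ct_target"]), "r": float(row["ct_reference"])}
    assays: dict[tuple, list[pq.QpcrRecord]] = {}
    for (mirna, seq, genotype, rep), conditions in sorted(grouped.items()):
        if set(conditions) != {"control", "treated"}:
            raise ValueError(
                f"assay {mirna}/{genotype} replicate {rep} lacks a condition")
        assays.setdefault((mirna, seq, genotype), []).append(pq.QpcrRecord(
            mirna=mirna, genotype=genotype, replicate=rep,
            ct_target_control=conditions["control"]["t"],
            ct_reference_control=conditions["control"]["r"],
            ct_target_treated=conditions["treated"]["t"],
            ct_reference_treated=conditions["treated"]["r"]))
    return {key: pq.ddct_fold(reps, threshold)
            for key, reps in assays.items()}


# ---------------------------------------------------------------------------
# outputs + report
# ---------------------------------------------------------------------------

def write_outputs(result: RunResult, libs: Sequence[Library], outdir: Path,
                  config: RunConfig) -> None:
    lib_ids = [lib.id for lib in libs]

    rows = [{"sequence": t.sequence, "length": t.length,
             **{lib: t.counts.get(lib, 0) for lib in lib_ids}}
            for t in result.tags]
    write_table(rows, outdir / "tags.tsv",
                ["sequence", "length", *lib_ids])

    srows = []
    for lib in libs:
        s = result.summaries[lib.id]
        srows.append({"library": lib.id, "genotype": lib.genotype,
                      "treatment": lib.treatment, "raw_reads": s.raw_reads,
                      "clean_reads": s.clean_reads,
                      "clean_pct": s.clean_fraction,
                      "unique_clean_reads": s.unique_clean_reads,
                      "unique_pct": s.unique_fraction})
    write_table(srows, outdir / "summary.tsv",
                ["library", "genotype", "treatment", "raw_reads",
                 "clean_reads", "clean_pct", "unique_clean_reads",
                 "unique_pct"],
                precision={"clean_pct": 1, "unique_pct": 1})

    genotypes = sorted({lib.genotype for lib in libs})
    erows = []
    for rec in result.records:
        row = {"name": rec.name, "family": rec.family,
               "sequence": rec.sequence}
        for lib in lib_ids:
            row[f"tpm_{lib}"] = rec.tpm.get(lib, 0.0)
        for g in genotypes:
            fc = rec.log2fc.get(g)
            row[f"log2fc_{g}"] = fc
            row[f"category_{g}"] = rec.category[g].value
        erows.append(row)
    schema = (["name", "family", "sequence"]
              + [f"tpm_{lib}" for lib in lib_ids]
              + sum([[f"log2fc_{g}", f"category_{g}"] for g in genotypes], []))
    write_table(erows, outdir / "expression.tsv", schema,
                precision={**{f"tpm_{lib}": 1 for lib in lib_ids},
                           **{f"log2fc_{g}": 1 for g in genotypes}})

    nrows = [{"name": n["name"], "sequence": n["sequence"],
              "length": len(n["sequence"]), "contig": n["candidate"].contig_id,
              "window_start": n["candidate"].window_start,
              "window_end": n["candidate"].window_end,
              "precursor_length": n["candidate"].precursor_length,
              "arm": n["candidate"].arm,
              "mfe": n["candidate"].mfe, "amfe": n["candidate"].amfe,
              "structure": n["candidate"].structure.dotbracket}
             for n in result.novel]
    write_table(nrows, outdir / "novel.tsv",
                ["name", "sequence", "length", "contig", "window_start",
                 "window_end", "precursor_length", "arm", "mfe", "amfe",
                 "structure"],
                precision={"mfe": 2, "amfe": 2})

    trows = [{"mirna": h.mirna, "transcript": h.transcript, "start": h.start,
              "end": h.end, "expectation": h.expectation,
              "inhibition": h.inhibition} for h in result.target_hits]
    write_table(trows, outdir / "targets.tsv",
                ["mirna", "transcript", "start", "end", "expectation",
                 "inhibition"], precision={"expectation": 1})

    with open(outdir / "report.txt", "w") as fh:
        fh.write(render_report(result, libs))


def render_report(result: RunResult, libs: Sequence[Library]) -> str:
    """Paper-style plain-text summary: read accounting, category counts,
    Venn overlap and tolerance-associated lists."""
    lines = ["# Library accounting (percentages of raw reads)"]
    for lib in libs:
        s = result.summaries[lib.id]
        lines.append(
            f"{lib.id}\traw={s.raw_reads}\tclean={s.clean_reads}"
            f"({s.clean_fraction:.1f})\tunique={s.unique_clean_reads}"
            f"({s.unique_fraction:.1f})")
    genotypes = sorted({lib.genotype for lib in libs})
    lines.append("")
    lines.append("# Expression categories per genotype")
    for g in genotypes:
        cc = expr.category_counts(result.records, g)
        total = sum(cc.values())
        parts = "\t".join(f"{cat.value}={n}" for cat, n in cc.items())
        lines.append(f"{g}\t{parts}\tuniverse={total}")
    if result.cross is not None:
        cross = result.cross
        lines.append("")
        lines.append("# Cross-genotype Venn (per category)")
        for cat, counts in cross.venn.items():
            lines.append(f"{cat.value}\t" + "\t".join(
                f"{k}={v}" for k, v in counts.items()))
        lines.append("")
        lines.append(f"# Tolerance-associated (strict_differential): "
                     f"{len(cross.strict_differential)}")
        lines.append(", ".join(cross.strict_differential) or "(none)")
        lines.append(f"# Tolerance-associated (paper_union): "
                     f"{len(cross.paper_union)}")
        lines.append(", ".join(cross.paper_union) or "(none)")
    if result.phenotype_scores:
        lines.append("")
        lines.append("# Integrated tolerance scores (higher = less Cd impact)")
        for g, score in sorted(result.phenotype_scores.items()):
            lines.append(f"{g}\t{score:.2f}")
        lines.append("ranking (most tolerant first): "
                     + " > ".join(result.tolerance_ranking))
    if result.concordance is not None:
        lines.append("")
        lines.append("# qRT-PCR vs sequencing concordance")
        lines.append(
            f"direction_agreement={result.concordance['direction_agreement']}"
            f"\tcategory_agreement={result.concordance['category_agreement']}"
            f"\tn={result.concordance['n']}")
    return "\n".join(lines) + "\n"
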