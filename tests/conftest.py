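"""Shared fixtures: seeded synthetic universes at two scales.

The small universe (20k reads/library) keeps unit/integration tests fast;
the full-scale universe (200k reads/library, the generator default) backs
the parameter-recovery acceptance checks.
"""

from pathlib import Path

import pytest

from cdmir.pipeline import RunConfig, run_all
from cdmir.synthetic_data import SimConfig, simulate_all

NCRNA_CLASSES = ("tRNA", "rRNA", "snRNA", "snoRNA")


def make_run_config(simdir: Path, outdir: Path, **overrides) -> RunConfig:
    import json
    manifest = json.loads((simdir / "manifest.json").read_text())
    kwargs = dict(
        libraries=[{"id": l["id"], "genotype": l["genotype"],
                    "treatment": l["treatment"],
                    "fastq": str(simdir / f"{l['id']}.fastq")}
                   for l in manifest["libraries"]],
        mature_fa=str(simdir / "mature.fa"),
        ncrna_fa={c: str(simdir / f"{c.lower()}.fa") for c in NCRNA_CLASSES},
        contig_fa=[str(simdir / "contigs.fa")],
        outdir=str(outdir),
        phenotype_tsv=str(simdir / "phenotype.tsv"),
        qpcr_tsv=str(simdir / "qpcr_ct.tsv"))
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def _manifest_dict(simdir: Path) -> dict:
    import json
    return json.loads((simdir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim_small")
    config = SimConfig(seed=11, library_depth=20_000)
    simulate_all(config, outdir)
    return config, outdir, _manifest_dict(outdir)


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    _config, simdir, manifest = small_sim
    outdir = tmp_path_factory.mktemp("run_small")
    result = run_all(make_run_config(simdir, outdir))
    return manifest, result, outdir


@pytest.fixture(scope="session")
def full_sim(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim_full")
    config = SimConfig(seed=7)
    simulate_all(config, outdir)
    return config, outdir, _manifest_dict(outdir)


@pytest.fixture(scope="session")
def full_run(full_sim, tmp_path_factory):
    _config, simdir, manifest = full_sim
    outdir = tmp_path_factory.mktemp("run_full")
    result = run_all(make_run_config(simdir, outdir))
    return manifest, result, outdir
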