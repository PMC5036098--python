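"""Bundled reference datasets.

Small TSV tables from a published two-genotype tobacco root small-RNA
cadmium experiment (cultivars Guiyan 1, Cd-sensitive, and Yunyan 2,
Cd-tolerant; 50 uM Cd for 5 days): per-miRNA TPM profiles with the
fold-change calls as printed, and the per-library read accounting with the
printed percentages. They serve as regression inputs: the package's own
TPM/fold-change/classification arithmetic is checked against the printed
values. Library ids follow the package convention: G-ctl / G-cd /
Y-ctl / Y-cd.
"""

from __future__ import annotations

from importlib import resources

from .sequence_io import read_table

LIBRARY_IDS = ("G_ctl", "G_cd", "Y_ctl", "Y_cd")


def _load(name: str) -> list[dict[str, str]]:
    with resources.as_file(resources.files("cdmir.data") / name) as path:
        return read_table(path)


def known_mirna_tpm() -> list[dict[str, str]]:
    """Known Cd-responsive miRNAs: TPM per library and printed fold changes.

    Columns: family, name, sequence, length, tpm_G_ctl, tpm_G_cd,
    tpm_Y_ctl, tpm_Y_cd, printed_fc_G, printed_fc_Y (numeric strings,
    1 decimal).
    """
    return _load("tobacco_cd_known_tpm.tsv")


def novel_mirna_tpm() -> list[dict[str, str]]:
    """Differentially expressed novel miRNAs: TPM per library and printed
    calls; printed_fc_* is "up" (expressed under Cd only), "down"
    (expressed in control only) or "dash" (absent or unchanged)."""
    return _load("tobacco_cd_novel_tpm.tsv")


def library_read_counts() -> list[dict[str, str]]:
    """Per-library raw/clean/unique read counts with printed percentages."""
    return _load("tobacco_cd_library_counts.tsv")
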