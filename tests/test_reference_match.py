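"""ncRNA filtering and contig mapping vs a naive quadratic scan."""

import numpy as np
import pytest

from cdmir.reference_match import (MappingSummary, ReferenceSet, filter_ncrna,
                                   map_to_contigs)
from cdmir.sequence_io import SmallRNATag, revcomp


def _tag(seq, **counts):
    return SmallRNATag(sequence=seq, counts=counts)


class TestFilterNcrna:
    def test_tag_equal_to_rrna_slice_removed(self):
        rrna = "ACGU" * 30
        tag = _tag(rrna[10:31], L1=2)
        kept, removed = filter_ncrna([tag], [ReferenceSet("rRNA", [rrna])])
        assert removed == [tag] and kept == []

    def test_reverse_strand_of_reference_is_searched(self):
        ref = "GGGAUCCGUAAGGCUAAGCCUAGGAAACCCUUU"
        tag = _tag(revcomp(ref[5:26]), L1=1)
        _kept, removed = filter_ncrna([tag], [ReferenceSet("tRNA", [ref])])
        assert removed == [tag]

    def test_absent_tag_kept(self):
        tag = _tag("UUUUUUUUUUGGGGG", L1=1)
        kept, removed = filter_ncrna(
            [tag], [ReferenceSet("rRNA", ["ACGUACGUACGUACGUACGU"])])
        assert kept == [tag] and removed == []

    def test_empty_reference_list_errors(self):
        with pytest.raises(ValueError):
            filter_ncrna([_tag("ACGUACGUACGU", L1=1)], [])

    def test_partition_exhaustive_and_planted_contaminants_removed(
            self, small_sim, small_run):
        from cdmir.sequence_io import read_fasta
        _config, simdir, _m = small_sim
        manifest, result, _o = small_run
        sets = [ReferenceSet(cls, [s for _i, _d, s in
                                   read_fasta(simdir / f"{cls.lower()}.fa")])
                for cls in ("tRNA", "rRNA", "snRNA", "snoRNA")]
        kept, removed = filter_ncrna(result.tags, sets)
        assert len(kept) + len(removed) == len(result.tags)
        assert not {t.sequence for t in kept} & {t.sequence for t in removed}
        planted = {c["sequence"] for c in manifest["contaminants"]}
        planted |= {d["sequence"] for d in manifest["degradation"]}
        sequenced_planted = planted & {t.sequence for t in result.tags}
        assert sequenced_planted  # the pools were actually sequenced
        assert sequenced_planted <= {t.sequence for t in removed}


def naive_hits(tags, contigs, search_revcomp=True):
    texts = list(contigs) + ([revcomp(c) for c in contigs]
                             if search_revcomp else [])
    out = {}
    for tag in tags:
        out[tag.sequence] = any(
            any(text[i:i + len(tag.sequence)] == tag.sequence
                for i in range(len(text) - len(tag.sequence) + 1))
            for text in texts)
    return out


class TestMapToContigs:
    def test_library_specific_tag_counted_as_specific(self):
        contig = "AAAACCCCGGGGUUUUACGUACGUAAAA"
        tags = [_tag(contig[4:18], L1=3),
                _tag("GGGGGGGGGGGGGG", L1=1, L2=1)]
        _hits, summary = map_to_contigs(tags, ReferenceSet("EST", [contig]),
                                        ["L1", "L2"])
        assert summary.specific_reads["L1"] == 3
        assert summary.specific_unique["L1"] == 1
        assert summary.reads_mapped["L2"] == 0

    def test_tag_in_all_libraries_counted_conserved(self):
        contig = "AAAACCCCGGGGUUUUACGUACGUAAAA"
        tag = _tag(contig[0:12], L1=2, L2=5)
        _hits, summary = map_to_contigs([tag], ReferenceSet("EST", [contig]),
                                        ["L1", "L2"])
        assert summary.conserved_reads == {"L1": 2, "L2": 5}
        assert summary.singleton == {"L1": 0, "L2": 0}

    def test_total_count_one_is_singleton(self):
        contig = "ACGUGGCCAAUUGGCCACGU"
        tag = _tag(contig[2:14], L1=1)
        _hits, summary = map_to_contigs([tag], ReferenceSet("EST", [contig]),
                                        ["L1"])
        assert summary.singleton["L1"] == 1

    def test_index_agrees_with_naive_quadratic_scan(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGU"))
        contigs = ["".join(rng.choice(bases, size=200)) for _ in range(5)]
        tags = []
        for _ in range(60):
            if rng.random() < 0.5:  # planted slice (possibly revcomp)
                c = contigs[int(rng.integers(5))]
                start = int(rng.integers(0, 180))
                seq = c[start:start + 15]
                if rng.random() < 0.3:
                    seq = revcomp(seq)
            else:
                seq = "".join(rng.choice(bases, size=15))
            tags.append(_tag(seq, L1=int(rng.integers(1, 5))))
        hits, _summary = map_to_contigs(tags, ReferenceSet("EST", contigs),
                                        ["L1"])
        assert hits == naive_hits(tags, contigs)

    def test_full_summary_matches_naive_recomputation(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGU"))
        contigs = ["".join(rng.choice(bases, size=150)) for _ in range(3)]
        lib_ids = ["L1", "L2", "L3", "L4"]
        tags = []
        for i in range(40):
            if rng.random() < 0.6:
                c = contigs[int(rng.integers(3))]
                start = int(rng.integers(0, 130))
                seq = c[start:start + 14]
            else:
                seq = "".join(rng.choice(bases, size=14))
            counts = {lib: int(rng.integers(0, 4)) for lib in lib_ids}
            if not any(counts.values()):
                counts["L1"] = 1
            tags.append(_tag(seq, **counts))
        hits, summary = map_to_contigs(tags, ReferenceSet("EST", contigs),
                                       lib_ids)
        naive = naive_hits(tags, contigs)
        expect = MappingSummary("EST")
        for lib in lib_ids:
            for d in (expect.reads_mapped, expect.unique_reads_mapped,
                      expect.specific_reads, expect.specific_unique,
                      expect.conserved_reads, expect.conserved_unique,
                      expect.singleton):
                d[lib] = 0
        for tag in tags:
            if not naive[tag.sequence]:
                continue
            present = [lib for lib in lib_ids if tag.counts.get(lib, 0)]
            for lib in present:
                n = tag.counts[lib]
                expect.reads_mapped[lib] += n
                expect.unique_reads_mapped[lib] += 1
                if len(present) == 1:
                    expect.specific_reads[lib] += n
                    expect.specific_unique[lib] += 1
                if len(present) == len(lib_ids):
                    expect.conserved_reads[lib] += n
                    expect.conserved_unique[lib] += 1
                if tag.total_count == 1:
                    expect.singleton[lib] += 1
        assert summary == expect
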