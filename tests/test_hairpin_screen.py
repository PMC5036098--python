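"""Folding DP vs exhaustive enumeration, window extraction, screening."""

import numpy as np
import pytest

from cdmir.hairpin_screen import (HairpinCandidate, ScreenCriteria,
                                  compute_amfe, extract_windows, fold,
                                  predict_novel, screen, terminal_loops)
from cdmir.sequence_io import revcomp

PAIR_WEIGHT = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
               ("G", "U"): 1, ("U", "G"): 1}


def best_score_by_enumeration(seq: str) -> int:
    """Exhaustively enumerate every nested structure (min loop 3) and
    return the maximum total pair weight."""
    def scores(i, j):
        if j - i < 4:
            yield 0
            return
        yield from scores(i + 1, j)
        for k in range(i + 4, j + 1):
            w = PAIR_WEIGHT.get((seq[i], seq[k]))
            if w:
                for a in scores(i + 1, k - 1):
                    for b in scores(k + 1, j):
                        yield w + a + b
    return max(scores(0, len(seq) - 1))


class TestFold:
    def test_gc_hairpin_has_unique_maximum(self):
        rec = fold("GGGGGAAAACCCCC", min_len=1)
        assert rec.dotbracket == "(((((....)))))"
        assert rec.mfe == -1.5

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError, match="short"):
            fold("ACGUACGUACGUAC")  # 14 nt < default minimum

    def test_non_rna_characters_error(self):
        with pytest.raises(ValueError):
            fold("ACGUXACGUACGUACG")

    def test_dp_matches_exhaustive_enumeration_for_short_sequences(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGU"))
        for _ in range(200):
            n = int(rng.integers(5, 15))
            seq = "".join(rng.choice(bases, size=n))
            rec = fold(seq, min_len=1)
            assert int(round(-rec.mfe * 10)) == best_score_by_enumeration(seq)

    def test_structure_score_is_consistent_with_reported_mfe(self):
        rng = np.random.default_rng(9)
        seq = "".join(np.random.default_rng(9).choice(list("ACGU"), size=80))
        rec = fold(seq)
        total = sum(PAIR_WEIGHT[(seq[i], seq[j])] for i, j in rec.pairs())
        assert total == int(round(-rec.mfe * 10))


class TestComputeAmfe:
    def test_formula(self):
        assert compute_amfe(-52.6, 100) == pytest.approx(-52.6)
        assert compute_amfe(-30.0, 120) == pytest.approx(-25.0)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            compute_amfe(-10.0, 0)


class TestExtractWindows:
    CONTIG = "A" * 400

    def test_windows_around_internal_hit(self):
        contig = "G" * 199 + "UCGGACCAGGCUUCAUUCCCCA" + "A" * 179
        tag = "UCGGACCAGGCUUCAUUCCCC"  # at 1-based positions 200-220
        assert extract_windows(tag, contig, flank=150) == [(50, 220), (200, 370)]

    def test_hit_at_position_one_clips_left_window(self):
        tag = "UCGGACCAGGCUUCAUUCCCC"
        contig = tag + "A" * 100
        assert extract_windows(tag, contig, flank=150) == [(1, 21), (1, 121)]

    def test_absent_tag_errors(self):
        with pytest.raises(ValueError, match="does not occur"):
            extract_windows("UCGGACCAGGCUUCAUUCCCC", "AAAAAAAA" * 30)


def _stem_candidate(arm_len=30, loop="ACAA", mature_len=21):
    rng = np.random.default_rng(12)
    arm = "".join(rng.choice(list("ACGU"), size=arm_len))
    precursor = arm + loop + revcomp(arm)
    rec = fold(precursor)
    return HairpinCandidate(
        id="c", contig_id="c", window_start=1, window_end=len(precursor),
        strand="+", precursor=precursor, structure=rec,
        mature_start=1, mature_end=mature_len)


class TestScreen:
    CRIT = ScreenCriteria.for_pseudo_energy()

    def test_perfect_inverted_repeat_accepted(self):
        cand = _stem_candidate()
        ok, reason = screen(cand, self.CRIT)
        assert (ok, reason) == (True, "ACCEPT")
        assert cand.arm == "5p"

    def test_mature_spanning_terminal_loop_rejected(self):
        cand = _stem_candidate()
        loops = terminal_loops(cand.structure)
        (ls, le), = loops
        cand.mature_start, cand.mature_end = ls - 4, ls + 17  # crosses loop
        ok, reason = screen(cand, self.CRIT)
        assert not ok and reason == "mature_crosses_loop"

    def test_mature_outside_precursor_is_an_error(self):
        cand = _stem_candidate()
        cand.mature_end = len(cand.precursor) + 5
        with pytest.raises(ValueError):
            screen(cand, self.CRIT)

    def test_weak_amfe_rejected(self):
        cand = _stem_candidate()
        crit = ScreenCriteria.for_pseudo_energy(max_amfe=cand.amfe - 1.0)
        ok, reason = screen(cand, crit)
        assert not ok and reason == "amfe"

    def test_tightening_any_threshold_never_flips_reject_to_accept(self):
        rng = np.random.default_rng(31)
        candidates = [_stem_candidate(arm_len=a, loop=lp, mature_len=m)
                      for a, lp, m in [(30, "ACAA", 21), (24, "AACC", 20),
                                       (40, "CACAC", 23)]]
        # add weakly structured candidates that the base criteria reject
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGU"), size=90))
            candidates.append(HairpinCandidate(
                id="r", contig_id="r", window_start=1, window_end=90,
                strand="+", precursor=seq, structure=fold(seq),
                mature_start=5, mature_end=25))
        base = ScreenCriteria.for_pseudo_energy()
        for cand in candidates:
            base_ok, _ = screen(cand, base)
            for tight in [
                    ScreenCriteria.for_pseudo_energy(min_precursor_len=60),
                    ScreenCriteria.for_pseudo_energy(max_precursor_len=80),
                    ScreenCriteria.for_pseudo_energy(min_mature_len=22),
                    ScreenCriteria.for_pseudo_energy(max_mature_len=21),
                    ScreenCriteria.for_pseudo_energy(max_amfe=-11.0),
                    ScreenCriteria.for_pseudo_energy(max_unpaired_mature=1)]:
                tight_ok, _ = screen(cand, tight)
                assert not (tight_ok and not base_ok)

    def test_accepted_candidates_lie_in_configured_boxes(self, small_run):
        _manifest, result, _o = small_run
        crit = ScreenCriteria.for_pseudo_energy()
        for n in result.novel:
            cand = n["candidate"]
            assert crit.min_precursor_len <= cand.precursor_length \
                <= crit.max_precursor_len
            assert crit.min_mature_len <= cand.mature_length \
                <= crit.max_mature_len
            assert cand.amfe <= crit.max_amfe
            assert cand.amfe == pytest.approx(
                cand.mfe / cand.precursor_length * 100, abs=1e-9)


class TestPredictNovel:
    def test_planted_hairpin_window_contains_precursor(self, small_sim):
        _config, _simdir, manifest = small_sim
        hp = manifest["novel_mirnas"][0]
        contig_seq = None
        from cdmir.sequence_io import read_fasta
        for cid, _d, seq in read_fasta(_simdir / "contigs.fa"):
            if cid == hp["contig"]:
                contig_seq = seq
        windows = extract_windows(hp["mature"], contig_seq, flank=150)
        assert any(ws <= hp["precursor_start"] and we >= hp["precursor_end"]
                   for ws, we in windows)

    def test_shuffled_decoys_rejected_at_default_criteria(self, small_sim):
        from cdmir.synthetic_data import dinucleotide_shuffle
        _config, _simdir, manifest = small_sim
        rng = np.random.default_rng(99)
        crit = ScreenCriteria.for_pseudo_energy()
        rejected = total = 0
        for hp in manifest["novel_mirnas"]:
            precursor = hp["precursor"]
            m0 = precursor.find(hp["mature"]) + 1
            for _ in range(5):
                decoy = dinucleotide_shuffle(precursor, rng)
                cand = HairpinCandidate(
                    id="d", contig_id="d", window_start=1,
                    window_end=len(decoy), strand="+", precursor=decoy,
                    structure=fold(decoy), mature_start=m0,
                    mature_end=m0 + len(hp["mature"]) - 1)
                ok, _reason = screen(cand, crit)
                total += 1
                rejected += not ok
        assert rejected / total >= 0.9
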