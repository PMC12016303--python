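"""Hallmark detectors: polyA, TSD, EN motif, classification, polishing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tprt_detect._dna import revcomp
from tprt_detect.te_annotate import (
    AnnotationConfig,
    TEAnnotation,
    TsdRecord,
    classify_te,
    consensus_polish,
    detect_en_cut,
    detect_polyA,
    detect_pseudogene,
    detect_tsd,
    en_context,
    hallmark_filter,
)

CFG = AnnotationConfig()


def brute_force_polyA(seq: str, min_len: int, purity: float) -> tuple[bool, int]:
    """Independent oracle: enumerate every suffix of the sequence."""
    best = 0
    for i in range(1, len(seq) + 1):
        suffix = seq[-i:]
        if suffix[-1] != "A" or suffix[0] != "A":
            continue
        if suffix.count("A") / i >= purity:
            best = i
    return (best >= min_len, best if best >= min_len else 0)


class TestDetectPolyA:
    def test_clean_tail(self):
        assert detect_polyA("CGT" * 20 + "A" * 30, CFG) == (True, 30)

    def test_no_tail(self):
        assert detect_polyA("ACGTACGTACGT" + "GGGG", CFG) == (False, 0)

    def test_interrupted_tail_matches_suffix_enumeration(self):
        seq = "A" * 15 + "G" + "A" * 15
        assert detect_polyA(seq, CFG) == brute_force_polyA(seq, 10, 0.8) == (True, 31)

    @settings(max_examples=150, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_agrees_with_suffix_enumeration(self, seq):
        assert detect_polyA(seq, CFG) == brute_force_polyA(seq, CFG.polyA_min_len, CFG.polyA_min_purity)


class TestDetectTsd:
    REF = {"c": "ACGT" * 300}

    @pytest.mark.parametrize("d,kind", [(4, "none"), (5, "duplication"), (13, "duplication"),
                                        (25, "duplication"), (26, "none")])
    def test_duplication_window_boundaries(self, d, kind):
        rec = detect_tsd(self.REF, "c", 100 + d, 100, CFG)
        assert rec.kind == kind
        if kind == "duplication":
            assert rec.length == d and rec.sequence == self.REF["c"][100:100 + d]

    @pytest.mark.parametrize("d,kind", [(7, "deletion"), (25, "deletion"), (26, "none")])
    def test_deletion_window_boundaries(self, d, kind):
        rec = detect_tsd(self.REF, "c", 100, 100 + d, CFG)
        assert rec.kind == kind
        if kind == "deletion":
            assert rec.length == d

    def test_antisymmetry(self):
        for d in (5, 12, 25):
            dup = detect_tsd(self.REF, "c", 200 + d, 200, CFG)
            dele = detect_tsd(self.REF, "c", 200, 200 + d, CFG)
            assert dup.kind == "duplication" and dele.kind == "deletion"
            assert dup.length == dele.length == d

    def test_off_chromosome_errors(self):
        with pytest.raises(ValueError):
            detect_tsd(self.REF, "c", -5, 10, CFG)


class TestDetectEnCut:
    @pytest.mark.parametrize("up,down,motif", [
        ("GGGTTT" + "TTTT", "A" + "CGT", "TTTT/A"),
        ("GGGTTT" + "TTTT", "G" + "CGT", "TTTT/G"),
        ("GGGTTT" + "TTTC", "A" + "CGT", "TTTC/A"),
        ("GGGGGG" + "GGGG", "C" + "CGT", "none"),
        ("GGGTTT" + "TTTC", "G" + "CGT", "none"),
    ])
    def test_motifs(self, up, down, motif):
        assert detect_en_cut(up, down) == motif

    def test_short_context_errors(self):
        with pytest.raises(ValueError):
            detect_en_cut("TTT", "A")
        with pytest.raises(ValueError):
            detect_en_cut("TTTT", "")

    def test_context_strand_geometry(self):
        # plus-strand insertion: the A-tract downstream on the top strand
        # reads TTTT on the nick strand; motif recovered via en_context
        ref = "G" * 20 + "T" + "AAAA" + "G" * 20   # nick at 21 (after the T)
        up, down = en_context(ref, 21, "+")
        assert detect_en_cut(up, down) == "TTTT/A"
        ref_minus = "G" * 17 + "TTTT" + "A" + "G" * 20  # nick at 21 on minus
        up, down = en_context(ref_minus, 21, "-")
        assert detect_en_cut(up, down) == "TTTT/A"


class TestClassifyTe:
    def test_exact_alu_copy(self, library, ann_cfg):
        seq = library["AluY"].sequence + "A" * 30
        family, sub, strand, segs = classify_te(seq, library, ann_cfg)
        assert (family, sub, strand) == ("Alu", "AluY", "+")
        assert segs and segs[0].t_start == 0 and segs[0].t_end == 311

    def test_reverse_complement_flips_strand_only(self, library, ann_cfg):
        seq = library["L1HS"].sequence[5000:] + "A" * 25
        f1, s1, strand1, _ = classify_te(seq, library, ann_cfg)
        f2, s2, strand2, _ = classify_te(revcomp(seq), library, ann_cfg)
        assert (f1, s1) == (f2, s2) == ("L1", "L1HS")
        assert {strand1, strand2} == {"+", "-"}

    def test_random_sequence_with_tail_is_orphan(self, library, ann_cfg):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 300)) + "A" * 30
        family, _, _, _ = classify_te(seq, library, ann_cfg)
        assert family == "orphan"

    def test_random_sequence_without_tail_is_none(self, library, ann_cfg):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("CGT"), 300))
        family, _, _, _ = classify_te(seq, library, ann_cfg)
        assert family == "none"

    def test_empty_library_errors(self, ann_cfg):
        from tprt_detect.io_formats import SequenceLibrary

        with pytest.raises(ValueError):
            classify_te("ACGT" * 30, SequenceLibrary(entries={}), ann_cfg)


class TestConsensusPolish:
    def test_single_read_identity(self):
        assert consensus_polish(["ACGTACGT"]) == "ACGTACGT"

    def test_identical_reads(self):
        assert consensus_polish(["ACGTACGTACGT"] * 3) == "ACGTACGTACGT"

    def test_majority_base_wins(self):
        # hand-enumerated 20 bp toy: one read carries one substitution
        clean = "ACGTACGTACGTACGTACGT"
        noisy = clean[:7] + "C" + clean[8:]
        assert clean[7] != "C"
        assert consensus_polish([clean, clean, noisy]) == clean

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            consensus_polish([])


class TestPseudogeneAndFilter:
    def test_te_consensus_is_not_a_pseudogene(self, library, ann_cfg):
        seq = library["AluY"].sequence + "A" * 30
        assert detect_pseudogene(seq, library, ann_cfg) is None

    def test_short_sequence_skipped(self, library, ann_cfg):
        assert detect_pseudogene("ACGT" * 30, library, ann_cfg) is None

    def _ann(self, family, count):
        a = TEAnnotation(call_id=f"{family}{count}", te_family=family)
        a.hallmark_count = count
        return a

    def test_tprt_without_hallmarks_removed(self):
        anns = [self._ann("L1", 1), self._ann("Alu", 0), self._ann("ERV", 0),
                self._ann("PP", 0), self._ann("none", 0)]
        kept = hallmark_filter(anns)
        families = [a.te_family for a in kept]
        assert families == ["L1", "ERV", "none"]

    def test_filter_idempotent_and_shrinking(self):
        anns = [self._ann("Alu", 0), self._ann("SVA", 2)]
        once = hallmark_filter(anns)
        assert len(once) <= len(anns)
        assert hallmark_filter(once) == once
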