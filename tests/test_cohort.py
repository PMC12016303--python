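"""Cohort merging and somatic/germline filtering against brute-force oracles."""

import numpy as np
import pytest

from tprt_detect.cohort import (
    CohortCall,
    TypeFilterInput,
    apply_type_filter,
    expected_false_somatic_rate,
    known_db_compare,
    merge_calls,
    positional_somatic_filter,
    te_type_somatic_filter,
)
from tprt_detect.io_formats import KnownTeTable


def _call(i, sample, pos, tissue="normal", sv="INS", strand="+", chrom="c1", support=3, family="L1"):
    return CohortCall(
        id=f"{i}", sample_id=sample, tissue=tissue, chrom=chrom, pos=pos,
        sv_type=sv, strand=strand, read_support=support, te_family=family,
    )


class TestMergeCalls:
    def test_distance_boundary(self):
        a, b = _call(1, "s1", 100), _call(2, "s2", 150)
        assert len(merge_calls([a, b])) == 1       # 50 bp apart: merged
        c = _call(3, "s2", 151)
        assert len(merge_calls([a, c])) == 2       # 51 bp apart: separate

    def test_type_and_strand_separate_loci(self):
        a = _call(1, "s1", 100, sv="INS")
        b = CohortCall("2", "s2", "normal", "c1", 100, "DEL", "+", "none", 3)
        assert len(merge_calls([a, b])) == 2
        c, d = _call(3, "s1", 100, strand="+"), _call(4, "s2", 100, strand="-")
        assert len(merge_calls([c, d])) == 2

    def test_representative_is_highest_support_then_leftmost(self):
        calls = [_call(1, "s1", 100, support=3), _call(2, "s2", 130, support=9),
                 _call(3, "s3", 120, support=9)]
        (locus,) = merge_calls(calls)
        assert locus.pos == 120  # support tie at 9 -> leftmost

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        calls = [
            _call(i, f"s{i % 4}", int(p), sv="INS")
            for i, p in enumerate(sorted(rng.integers(0, 3000, 60)))
        ]
        base = [(l.chrom, l.pos, tuple(c.id for c in l.calls)) for l in merge_calls(calls)]
        for _ in range(5):
            shuffled = list(calls)
            rng.shuffle(shuffled)
            got = [(l.chrom, l.pos, tuple(c.id for c in l.calls)) for l in merge_calls(shuffled)]
            assert got == base


def brute_force_somatic(calls, window=10):
    """O(n^2) oracle: per tumor call, scan every other sample's calls."""
    status = {}
    for c in calls:
        if c.tissue != "tumor":
            status[c.id] = "germline"
            continue
        near = any(
            o.sample_id != c.sample_id
            and o.chrom == c.chrom
            and abs(o.pos - c.pos) <= window
            for o in calls
        )
        status[c.id] = "germline" if near else "somatic_candidate"
    return status


class TestPositionalSomaticFilter:
    def _run(self, calls):
        loci = merge_calls(calls, max_distance=0)
        positional_somatic_filter(loci, calls)
        return {c.id: l.status for l in loci for c in l.calls}

    def test_isolated_tumor_call_is_somatic(self):
        calls = [_call(1, "t1", 100, tissue="tumor"), _call(2, "n1", 111)]
        assert self._run(calls)["1"] == "somatic_candidate"  # 11 bp away

    def test_window_boundary_inclusive(self):
        calls = [_call(1, "t1", 100, tissue="tumor"), _call(2, "n1", 110)]
        assert self._run(calls)["1"] == "germline"           # exactly 10 bp

    def test_same_position_in_normal_is_germline(self):
        calls = [_call(1, "t1", 500, tissue="tumor"), _call(2, "n1", 500)]
        assert self._run(calls)["1"] == "germline"

    def test_non_te_insertion_also_blocks(self):
        calls = [_call(1, "t1", 500, tissue="tumor", family="L1"),
                 _call(2, "n1", 510, family="none")]
        assert self._run(calls)["1"] == "germline"

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(5, 200))
            calls = [
                _call(
                    i, f"s{rng.integers(0, 6)}", int(rng.integers(0, 2000)),
                    tissue="tumor" if rng.random() < 0.4 else "normal",
                )
                for i in range(n)
            ]
            # a sample is consistently one tissue
            tissue_of = {}
            for c in calls:
                c.tissue = tissue_of.setdefault(c.sample_id, c.tissue)
            expected = brute_force_somatic(calls)
            loci = merge_calls(calls, max_distance=0)
            positional_somatic_filter(loci, calls)
            got = {}
            for locus in loci:
                for c in locus.calls:
                    got[c.id] = locus.status
            # merged multi-sample loci are germline in both definitions
            for call in calls:
                if expected[call.id] == "somatic_candidate":
                    assert got[call.id] == "somatic_candidate", trial
                else:
                    assert got[call.id] == "germline", trial


class TestTypeFilter:
    def test_paper_style_inputs(self):
        inp = TypeFilterInput(
            n_germline_samples=105,
            unique_germline_counts_by_type={"Alu": 1088, "L1": 254, "SVA": 88, "ERV": 46},
            n_tumors_without_normal=50,
            somatic_candidate_counts_by_type={"Alu": 232, "L1": 1468, "SVA": 12, "ERV": 4},
        )
        decisions = {d.family: d for d in te_type_somatic_filter(inp)}
        assert decisions["Alu"].decision == "exclude"
        assert decisions["SVA"].decision == "exclude"
        assert decisions["ERV"].decision == "exclude"
        assert decisions["L1"].decision == "keep"
        assert decisions["Alu"].expected == pytest.approx(1088 / 105 * 50, rel=1e-9)

    def test_zero_germline_with_candidates_kept(self):
        inp = TypeFilterInput(1, {"L1": 0}, 10, {"L1": 5})
        (d,) = te_type_somatic_filter(inp)
        assert d.decision == "keep"

    def test_apply_marks_loci(self):
        calls = [_call(1, "t1", 100, tissue="tumor", family="Alu")]
        loci = merge_calls(calls)
        positional_somatic_filter(loci, calls)
        assert loci[0].status == "somatic_candidate"
        apply_type_filter(loci, te_type_somatic_filter(TypeFilterInput(1, {"Alu": 10}, 5, {"Alu": 1})))
        assert loci[0].status == "excluded_by_type"


class TestExpectedFalseSomaticRate:
    def test_published_operating_point(self):
        assert expected_false_somatic_rate(14.2, 31.46) == pytest.approx(45.14, abs=0.01)

    def test_degenerate_cases(self):
        assert expected_false_somatic_rate(0.0, 5.0) == 0.0
        assert expected_false_somatic_rate(7.0, 7.0) == 100.0
        with pytest.raises(ValueError):
            expected_false_somatic_rate(1.0, 0.0)


class TestKnownDbCompare:
    def _locus(self, pos, family="L1"):
        calls = [_call(1, "s1", pos, family=family)]
        (locus,) = merge_calls(calls)
        return locus

    @pytest.mark.parametrize("offset,known_type,expected", [
        (250, "L1", True),    # within 300, type matches
        (300, "L1", True),    # boundary inclusive
        (301, "L1", False),   # outside window
        (250, "Alu", False),  # type mismatch
    ])
    def test_window_and_type(self, offset, known_type, expected):
        locus = self._locus(1000)
        table = KnownTeTable(records=[("c1", 1000 + offset, known_type)])
        known_db_compare([locus], table)
        assert locus.known is expected

    def test_empty_table_all_novel(self):
        locus = self._locus(1000)
        known_db_compare([locus], KnownTeTable(records=[]))
        assert locus.known is False
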