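"""Allele-graph support counting, nanopore/Illumina evidence rules, curation."""

import itertools

import pytest

from tprt_detect.io_formats import InsertionCall
from tprt_detect.read_support import (
    NanoporeEvidence,
    NodeInterval,
    ReadPair,
    align_read_to_graph,
    auto_curate,
    build_allele_graph,
    count_graph_support,
    discordant_ratio,
    nanopore_support_reads,
)


def _ins_call(pos=5000, seq_len=200, chrom="c1"):
    return InsertionCall("x", "s1", chrom, pos, "INS", seq="ACGT" * (seq_len // 4))


@pytest.fixture(scope="module")
def toy_ref():
    import numpy as np

    rng = np.random.default_rng(7)
    return {"c1": "".join(rng.choice(list("ACGT"), 20000))}


class TestBuildAlleleGraph:
    def test_full_flanks(self, toy_ref):
        g = build_allele_graph(toy_ref, _ins_call(pos=5000))
        assert len(g.left_flank) == len(g.right_flank) == 2000
        assert not g.truncated
        assert g.left_span == (3000, 5000) and g.right_span == (5000, 7000)

    def test_contig_end_truncates_and_flags(self, toy_ref):
        g = build_allele_graph(toy_ref, _ins_call(pos=500))
        assert len(g.left_flank) == 500 and g.truncated

    def test_empty_seq_errors(self, toy_ref):
        call = InsertionCall("x", "s1", "c1", 100, "DEL", del_span=(100, 200))
        with pytest.raises(ValueError):
            build_allele_graph(toy_ref, call)

    def test_gfa_serialization_lists_bubble(self, toy_ref):
        g = build_allele_graph(toy_ref, _ins_call())
        gfa = g.to_gfa()
        assert gfa.count("\nS\t") == 4 and gfa.count("\nL\t") == 4


class TestCountGraphSupport:
    @pytest.mark.parametrize("flank_nt,ins_nt,expected", [
        (60, 60, 1),   # both overlaps clear 50 nt
        (50, 50, 1),   # boundary inclusive
        (60, 49, 0),   # insertion overlap below threshold
        (49, 60, 0),   # flank overlap below threshold
    ])
    def test_insertion_support_rule(self, toy_ref, flank_nt, ins_nt, expected):
        g = build_allele_graph(toy_ref, _ins_call())
        chain = [
            NodeInterval("left_flank", 2000 - flank_nt, 2000),
            NodeInterval("insertion", 0, ins_nt),
        ]
        ins, ref = count_graph_support(g, [chain])
        assert (ins, ref) == (expected, 0)

    @pytest.mark.parametrize("left_nt,right_nt,expected", [
        (50, 50, 1),
        (49, 50, 0),
        (50, 49, 0),
    ])
    def test_reference_support_rule(self, toy_ref, left_nt, right_nt, expected):
        g = build_allele_graph(toy_ref, _ins_call())
        chain = [
            NodeInterval("left_flank", 2000 - left_nt, 2000),
            NodeInterval("right_flank", 0, right_nt),
        ]
        ins, ref = count_graph_support(g, [chain])
        assert (ins, ref) == (0, expected)

    def test_read_counts_for_at_most_one_path(self, toy_ref):
        g = build_allele_graph(toy_ref, _ins_call())
        chains = [
            [NodeInterval("left_flank", 1900, 2000), NodeInterval("insertion", 0, 100)],
            [NodeInterval("left_flank", 1900, 2000), NodeInterval("right_flank", 0, 100)],
        ]
        ins, ref = count_graph_support(g, chains)
        assert ins + ref <= len(chains)
        assert (ins, ref) == (1, 1)

    def test_path_aligner_on_simulated_alleles(self, toy_ref):
        call = _ins_call(pos=5000, seq_len=400)
        g = build_allele_graph(toy_ref, call)
        ins_read = g.left_flank[-300:] + call.seq + g.right_flank[:300]
        ref_read = g.left_flank[-300:] + g.right_flank[:300]
        chains = [align_read_to_graph(g, ins_read), align_read_to_graph(g, ref_read)]
        ins, ref = count_graph_support(g, chains)
        assert (ins, ref) == (1, 1)


class TestNanoporeSupport:
    CALL = _ins_call(pos=1000, seq_len=400)

    @pytest.mark.parametrize("pos,length,counted", [
        (1080, 240, True),    # 0.6x length at +80 bp
        (1100, 400, True),    # position boundary inclusive
        (1101, 400, False),   # beyond 100 bp
        (1000, 199, False),   # below half length
        (1000, 200, True),    # half length inclusive
        (1000, 800, True),    # double length inclusive
        (1000, 801, False),
    ])
    def test_insertion_length_and_position_rules(self, pos, length, counted):
        ev = NanoporeEvidence(insertions=[(pos, length)])
        assert nanopore_support_reads(self.CALL, ev) == int(counted)

    @pytest.mark.parametrize("clip_len,end,counted", [
        (31, 1010, True),     # > 30 bp ending 10 bp away
        (30, 1000, False),    # exactly 30 bp: excluded (strict >)
        (31, 1011, False),    # ends beyond 10 bp
    ])
    def test_softclip_rules(self, clip_len, end, counted):
        ev = NanoporeEvidence(softclips=[(clip_len, end)])
        assert nanopore_support_reads(self.CALL, ev) == int(counted)


class TestDiscordantRatio:
    CALL = _ins_call(pos=10_000)

    def test_ten_percent_threshold_case(self):
        pairs = [ReadPair(10_050, "c1", 10_100) for _ in range(27)]
        pairs += [ReadPair(10_050, "c2", 500) for _ in range(3)]
        d, n, ratio = discordant_ratio(self.CALL, pairs)
        assert (d, n) == (3, 30) and ratio == pytest.approx(0.10)

    @pytest.mark.parametrize("mate_pos,discordant", [
        (10_650, False),  # 600 bp away: concordant (strict >)
        (10_751, True),   # 701 bp from the read at +50
    ])
    def test_mate_distance_rule(self, mate_pos, discordant):
        pairs = [ReadPair(10_050, "c1", mate_pos)]
        d, n, _ = discordant_ratio(self.CALL, pairs)
        assert d == int(discordant) and n == 1

    def test_window_rule_and_empty(self):
        pairs = [ReadPair(10_101, "c2", 5)]  # outside the 100 bp window
        d, n, ratio = discordant_ratio(self.CALL, pairs)
        assert (d, n, ratio) == (0, 0, None)
        d, n, ratio = discordant_ratio(self.CALL, [ReadPair(10_000, "c1", 10_100)] * 40)
        assert (d, n, ratio) == (0, 40, 0.0)


def curate_oracle(tumor, nanopore, discordant, depth_ok):
    """Truth-table restatement of the curation rules."""
    if tumor < 3:
        return "false_positive"
    if nanopore is None and discordant is None:
        return "unclassifiable"
    if nanopore is not None and nanopore >= 1:
        return "germline"
    if discordant is not None and discordant >= 4:
        return "germline"
    if nanopore == 0:
        return "true_somatic"
    return "true_somatic" if depth_ok else "unclassifiable"


class TestAutoCurate:
    CALL = _ins_call()

    @pytest.mark.parametrize("tumor,nano,expected", [
        (3, 0, "true_somatic"),
        (5, 1, "germline"),
        (2, 0, "false_positive"),
    ])
    def test_named_cases(self, tumor, nano, expected):
        assert auto_curate(self.CALL, tumor, normal_nanopore=nano) == expected

    def test_discordant_rules(self):
        assert auto_curate(self.CALL, 4, normal_discordant=4) == "germline"
        assert auto_curate(self.CALL, 4, normal_discordant=3) == "true_somatic"
        assert auto_curate(self.CALL, 4, normal_discordant=3, normal_depth_ok=False) == "unclassifiable"

    def test_exhaustive_truth_table(self):
        for tumor, nano, disc, depth_ok in itertools.product(
            range(0, 7), [None, 0, 1, 2], [None, 0, 3, 4, 7], [True, False]
        ):
            got = auto_curate(self.CALL, tumor, nano, disc, depth_ok)
            assert got == curate_oracle(tumor, nano, disc, depth_ok), (tumor, nano, disc, depth_ok)
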