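"""Rates, densities, PWM, timing comparisons and hallmark tables."""

import math

import numpy as np
import pytest

from tprt_detect.io_formats import IntervalTrack
from tprt_detect.target_stats import (
    PWM,
    RateInput,
    annotation_overlap,
    bootstrap_ci,
    chi_square_2x2,
    compare_replication_timing,
    en_pwm,
    proportion_pct,
    rect_kde,
    relative_insertion_rate,
)


class TestRelativeInsertionRate:
    def test_hand_computed_values(self):
        assert relative_insertion_rate(RateInput(19, 99, 999, 9999)) == pytest.approx(1.0)
        assert relative_insertion_rate(RateInput(4, 9, 4, 99)) == pytest.approx(
            math.log2((5 / 10) / (5 / 100))
        )

    def test_identity_case_is_zero(self):
        assert relative_insertion_rate(RateInput(0, 0, 7, 7)) == 0.0

    def test_monotonicity(self):
        base = relative_insertion_rate(RateInput(10, 100, 1000, 100000))
        assert relative_insertion_rate(RateInput(11, 100, 1000, 100000)) > base
        assert relative_insertion_rate(RateInput(10, 100, 2000, 100000)) < base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            RateInput(5, 4, 10, 100)
        with pytest.raises(ValueError):
            RateInput(1, 4, 0, 100)


class TestBootstrapCi:
    LABELS = [True] * 20 + [False] * 80

    def test_deterministic_under_seed(self):
        a = bootstrap_ci(self.LABELS, 1000, 10000, r_reps=2000, seed=3)
        b = bootstrap_ci(self.LABELS, 1000, 10000, r_reps=2000, seed=3)
        assert a == b

    def test_contains_point_estimate(self):
        lo, hi = bootstrap_ci(self.LABELS, 1000, 10000, r_reps=2000, seed=3)
        point = relative_insertion_rate(RateInput(20, 100, 1000, 10000))
        assert lo <= point <= hi

    def test_constant_labels_zero_width(self):
        lo, hi = bootstrap_ci([True] * 30, 1000, 10000, r_reps=500, seed=1)
        assert lo == hi


class TestRectKde:
    def test_single_value_box(self):
        xs, ys = rect_kde([100.0], 40.0)
        inside = ys[(xs > 60.5) & (xs < 139.5)]
        outside = ys[(xs < 59.5) | (xs > 140.5)]
        assert np.allclose(inside, 1 / 80)
        assert np.allclose(outside, 0.0)

    def test_two_disjoint_boxes(self):
        xs, ys = rect_kde([0.0, 200.0], 40.0)
        assert np.allclose(ys[(xs > 0.5) & (xs < 39.5)], 1 / 160)
        assert np.allclose(ys[(xs > 41) & (xs < 159)], 0.0)

    @pytest.mark.parametrize("values", [[5.0], [0.0, 1.0, 2.0], list(np.arange(30.0)), [3.0, 3.0, 90.0]])
    def test_integrates_to_one(self, values):
        xs, ys = rect_kde(values, 7.5)
        assert np.trapezoid(ys, xs) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rect_kde([], 10.0)
        with pytest.raises(ValueError):
            rect_kde([1.0], 0.0)


class TestEnPwm:
    def test_planted_motif_recovered_exactly(self):
        # plus-strand geometry: A-tract after the nick, T before it
        ref = {"c": ("G" * 30 + "T" + "AAAA" + "G" * 30) * 3}
        nicks = [("c", 31, "+"), ("c", 96, "+"), ("c", 161, "+")]
        pwm = en_pwm(nicks, ref)
        for pos in (-4, -3, -2, -1):
            assert pwm.row(pos)["T"] == 1.0
        assert pwm.row(1)["A"] == 1.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        ref = {"c": "".join(rng.choice(list("ACGT"), 5000))}
        nicks = [("c", int(p), "+") for p in rng.integers(50, 4950, 40)]
        pwm = en_pwm(nicks, ref)
        assert np.allclose(pwm.fractions.sum(axis=1).to_numpy(), 1.0, atol=1e-9)

    def test_single_insertion_one_hot(self):
        ref = {"c": "ACGT" * 20}
        pwm = en_pwm([("c", 40, "-")], ref)
        assert set(np.unique(pwm.fractions.to_numpy())) == {0.0, 1.0}

    def test_uniform_contexts_near_quarter(self):
        rng = np.random.default_rng(1)
        n = 400
        ref = {"c": "".join(rng.choice(list("ACGT"), 60000))}
        nicks = [("c", int(p), "+") for p in rng.integers(100, 59900, n)]
        pwm = en_pwm(nicks, ref)
        sigma = math.sqrt(0.25 * 0.75 / n)
        assert (np.abs(pwm.fractions.to_numpy() - 0.25) < 3 * sigma + 1e-9).mean() > 0.95

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            en_pwm([], {"c": "ACGT"})


class TestReplicationTiming:
    def test_identical_groups_degenerate(self):
        table, _ = compare_replication_timing({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        row = table.iloc[0]
        assert row.t == 0.0 and row.p == 1.0 and bool(row.degenerate)

    def test_large_shift_small_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100)
        table, _ = compare_replication_timing({"a": a, "b": a + 10})
        assert table.iloc[0].p < 1e-20

    def test_matches_welch_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 500), rng.normal(0.2, 1.3, 500)
        table, ecdfs = compare_replication_timing({"a": a, "b": b})
        # independent hand computation of the Welch statistic
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_manual = (a.mean() - b.mean()) / math.sqrt(va + vb)
        assert table.iloc[0].t == pytest.approx(t_manual, abs=1e-9)
        assert ecdfs["a"].cdf.iloc[-1] == 1.0


class TestHallmarkStats:
    def test_twin_priming_chi_square_published_value(self):
        _, p = chi_square_2x2(328, 1495, 165, 897)
        assert p == pytest.approx(0.038, abs=0.0005)

    def test_yates_correction_differs(self):
        _, p = chi_square_2x2(328, 1495, 165, 897, correction=True)
        assert round(p, 3) != 0.038

    def test_identical_groups_p_one(self):
        stat, p = chi_square_2x2(10, 100, 10, 100)
        assert (stat, p) == (0.0, 1.0)

    def test_proportion_rounding_half_away(self):
        assert proportion_pct(1048, 1495, 1) == 70.1
        assert proportion_pct(1, 8, 0) == 13.0  # 12.5 rounds away from zero
        with pytest.raises(ValueError):
            proportion_pct(1, 0)


class TestAnnotationOverlap:
    TRACKS = {
        "repeats": IntervalTrack("repeats", [("c", 100, 200, "SINE|+|AluY", None)]),
        "genes": IntervalTrack("genes", [("c", 150, 400, "GENE1", None)]),
    }

    def test_point_overlap_labels(self):
        per_locus, counts = annotation_overlap(
            [("l1", "c", 150), ("l2", "c", 50)], self.TRACKS
        )
        by_id = per_locus.set_index("locus_id")
        assert by_id.loc["l1", "repeat_class"] == "SINE"
        assert bool(by_id.loc["l1", "genes"])
        assert by_id.loc["l2", "repeat_class"] == "Unique"
        assert dict(zip(counts["class"], counts["count"]))["SINE"] == 1

    def test_half_open_boundary(self):
        per_locus, _ = annotation_overlap([("l1", "c", 200)], self.TRACKS)
        assert per_locus.iloc[0]["repeat_class"] == "Unique"  # pos == end: outside
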