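import math

import numpy as np
import pandas as pd
import pytest

from mirprio.qpcr import (
    AnalysisError,
    CqTable,
    benjamini_hochberg,
    compare_groups,
    compare_independent_ddcq,
    correlate,
    fit_efficiency,
    malignancy_levels,
    normalize,
    per_sample_ddcq,
)


def make_table(cq_dict, groups, refs=("ref1",), paired=None):
    cq = pd.DataFrame(cq_dict)
    group = pd.Series(groups)
    return CqTable(cq=cq, group=group, reference_assays=tuple(refs), paired_normal=paired or {})


class TestFitEfficiency:
    def test_perfect_doubling_five_fold_series(self):
        step = math.log2(5)
        series = [(5**k, 20 + k * step) for k in range(1, 5)]
        fit = fit_efficiency(series)
        assert fit.efficiency == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope < 0
        assert fit.accepted

    def test_planted_efficiency_recovered(self):
        e = 1.9
        # Cq advances by log_E(5) per 5-fold dilution step
        step = math.log(5) / math.log(e)
        series = [(5**k, 18 + k * step) for k in range(1, 5)]
        fit = fit_efficiency(series)
        assert fit.efficiency == pytest.approx(1.9, abs=1e-9)

    def test_constant_cq_is_an_error(self):
        with pytest.raises(AnalysisError, match="slope"):
            fit_efficiency([(5, 20.0), (25, 20.0), (125, 20.0)])

    def test_too_few_points(self):
        with pytest.raises(AnalysisError, match=">= 3"):
            fit_efficiency([(5, 20.0), (25, 22.3)])


class TestNormalize:
    def test_reference_mean_subtracted(self):
        table = make_table(
            {"tgt": [30.0], "ref1": [25.0], "ref2": [27.0]},
            {0: "normal"},
            refs=("ref1", "ref2"),
        )
        res = normalize(table)
        assert res.delta_cq.loc[0, "tgt"] == pytest.approx(4.0)

    def test_equal_cqs_give_zero(self):
        table = make_table({"tgt": [22.0], "ref1": [22.0]}, {0: "normal"})
        assert normalize(table).delta_cq.loc[0, "tgt"] == pytest.approx(0.0)

    def test_per_sample_shift_invariance(self, rng):
        cq = {
            "tgt": list(rng.uniform(20, 30, 5)),
            "ref1": list(rng.uniform(20, 30, 5)),
            "ref2": list(rng.uniform(20, 30, 5)),
        }
        groups = {i: "normal" for i in range(5)}
        base = normalize(make_table(cq, groups, refs=("ref1", "ref2"))).delta_cq
        shifted = {a: [v + 3.7 for v in vals] for a, vals in cq.items()}
        shifted_res = normalize(make_table(shifted, groups, refs=("ref1", "ref2"))).delta_cq
        pd.testing.assert_frame_equal(base, shifted_res)

    def test_missing_reference_excludes_sample_with_reason(self):
        table = make_table(
            {"tgt": [30.0, 31.0], "ref1": [25.0, np.nan]},
            {0: "normal", 1: "normal"},
        )
        res = normalize(table)
        assert list(res.delta_cq.index) == [0]
        assert res.excluded[0][0] == 1
        assert "ref1" in res.excluded[0][1]

    def test_efficiency_correction_rescales(self):
        table = make_table({"tgt": [30.0], "ref1": [25.0]}, {0: "normal"})
        res = normalize(table, efficiency_correction=True, efficiencies={"tgt": 4.0})
        # log2(4) = 2: target Cq counts double
        assert res.delta_cq.loc[0, "tgt"] == pytest.approx(60.0 - 25.0)

    def test_no_reference_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="reference"):
            make_table({"tgt": [30.0]}, {0: "normal"}, refs=())


class TestCompareGroups:
    @staticmethod
    def series(a_vals, b_vals, group_a="adenoma", group_b="normal"):
        idx_a = [f"a{i}" for i in range(len(a_vals))]
        idx_b = [f"b{i}" for i in range(len(b_vals))]
        delta = pd.Series(list(a_vals) + list(b_vals), index=idx_a + idx_b, dtype=float)
        groups = pd.Series([group_a] * len(a_vals) + [group_b] * len(b_vals), index=idx_a + idx_b)
        return delta, groups

    def test_identical_groups(self):
        delta, groups = self.series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = compare_groups(delta, groups, "adenoma", "normal")
        assert res.delta_delta_cq == pytest.approx(0.0)
        assert res.fold_change == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.test_name == "mann_whitney_u"

    def test_fold_from_ddcq_definition(self):
        delta, groups = self.series([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        res = compare_groups(delta, groups, "adenoma", "normal")
        assert res.delta_delta_cq == pytest.approx(-1.0)
        assert res.fold_change == pytest.approx(2.0)

    def test_downregulation_reported_as_reciprocal_fold(self):
        # ddCq = +2.632 -> fold 2^-2.632 ~ 0.161 ~ 1/6.20
        delta, groups = self.series([2.632] * 4, [0.0] * 4)
        res = compare_groups(delta, groups, "adenoma", "normal")
        assert res.fold_change == pytest.approx(2 ** -2.632)
        assert res.fold_change == pytest.approx(1 / 6.20, rel=5e-3)
        assert res.fold_display == "6.20-fold down"
        assert res.direction == "down"

    def test_reciprocal_symmetry(self):
        delta, groups = self.series([1.0, 1.5, 0.5], [3.0, 3.5, 2.5])
        ab = compare_groups(delta, groups, "adenoma", "normal")
        ba = compare_groups(delta, groups, "normal", "adenoma")
        assert ab.fold_change * ba.fold_change == pytest.approx(1.0)

    def test_paired_wilcoxon_on_linked_samples(self):
        delta = pd.Series(
            {"t1": 1.0, "t2": 0.5, "t3": 1.5, "t4": 0.8,
             "n1": 3.0, "n2": 2.5, "n3": 3.1, "n4": 3.2}
        )
        groups = pd.Series(
            {k: ("crc_n0" if k.startswith("t") else "normal") for k in delta.index}
        )
        paired = {"t1": "n1", "t2": "n2", "t3": "n3", "t4": "n4"}
        res = compare_groups(delta, groups, "crc_n0", "normal", paired=True, paired_normal=paired)
        assert res.test_name == "wilcoxon_signed_rank"
        assert res.delta_delta_cq < 0  # tumours have lower dCq = upregulated
        assert res.p_value < 0.2

    def test_all_zero_differences_give_p_one(self):
        delta = pd.Series({"t1": 1.0, "t2": 2.0, "t3": 3.0, "n1": 1.0, "n2": 2.0, "n3": 3.0})
        groups = pd.Series({k: ("crc_n0" if k.startswith("t") else "normal") for k in delta.index})
        paired = {"t1": "n1", "t2": "n2", "t3": "n3"}
        res = compare_groups(delta, groups, "crc_n0", "normal", paired=True, paired_normal=paired)
        assert res.p_value == 1.0

    def test_insufficient_samples_lists_counts(self):
        delta, groups = self.series([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(AnalysisError, match="n=2"):
            compare_groups(delta, groups, "adenoma", "normal")

    def test_not_detected_samples_dropped(self):
        delta, groups = self.series([1.0, 2.0, 3.0, np.nan], [1.0, 2.0, 3.0])
        res = compare_groups(delta, groups, "adenoma", "normal")
        assert len(res.delta_cq_a) == 3


class TestIndependentDdcq:
    def test_equal_distributions(self):
        res = compare_independent_ddcq([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_u_statistic_matches_pairwise_win_count(self, rng):
        a = list(rng.normal(2.0, 1.0, 10))
        b = list(rng.normal(0.0, 1.0, 10))
        res = compare_independent_ddcq(a, b)
        u_brute = sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )
        assert res.statistic == pytest.approx(u_brute)

    def test_single_sample_group_is_an_error(self):
        with pytest.raises(AnalysisError):
            compare_independent_ddcq([1.0], [1.0, 2.0, 3.0])

    def test_per_sample_ddcq_uses_corresponding_normal(self):
        delta = pd.Series({"t1": 5.0, "t2": 6.0, "n1": 3.0, "n2": 2.0})
        out = per_sample_ddcq(delta, {"t1": "n1", "t2": "n2"}, ["t1", "t2"])
        assert out.to_dict() == {"t1": 2.0, "t2": 4.0}


class TestCorrelate:
    def test_perfect_positive_and_negative(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_tied_fixture_matches_hand_ranks(self):
        # x has one tie at value 3 (ranks 3.5, 3.5)
        x = [1, 2, 3, 3, 5, 6, 7, 8]
        y = [2, 1, 4, 3, 6, 5, 8, 7]
        rx = [1, 2, 3.5, 3.5, 5, 6, 7, 8]
        ry = [2, 1, 4, 3, 6, 5, 8, 7]
        mx, my = np.mean(rx), np.mean(ry)
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
        )
        rho, _ = correlate(x, y)
        assert rho == pytest.approx(num / den)

    def test_too_few_pairs(self):
        with pytest.raises(AnalysisError, match=">= 4"):
            correlate([1, 2, 3], [1, 2, 3])

    def test_malignancy_levels_are_ordinal(self):
        groups = pd.Series(
            {"s1": "normal", "s2": "adenoma", "s3": "adenoma_early_ca", "s4": "crc_n0", "s5": "crc_n+"}
        )
        assert list(malignancy_levels(groups)) == [0.0, 1.0, 2.0, 3.0, 4.0]


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = [0.01, 0.02, 0.03, 0.5]
        adj = benjamini_hochberg(p)
        assert all(a >= raw for a, raw in zip(adj, p))
        assert all(0 <= a <= 1 for a in adj)
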