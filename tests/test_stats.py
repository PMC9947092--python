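"""Outcome metrics and the group-comparison cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypoclamp.exceptions import EstimationError, ValidationError
from hypoclamp.records import SampledSeries
from hypoclamp.stats import (OutcomeSpec, SymptomRating, auc_trapezoid,
                             compare_groups, iauc, paired_change_test,
                             peak_metrics, symptom_scores, window_stats)


def _series(times, values, channel="glucagon", units="pmol/l"):
    return SampledSeries(np.asarray(times, float),
                         np.asarray(values, float), channel, units)


class TestAuc:
    def test_constant(self):
        s = _series([150, 155, 160], [2.0, 2.0, 2.0])
        assert auc_trapezoid(s, (150, 160)) == pytest.approx(20.0)

    def test_triangle(self):
        s = _series([150, 160, 170], [0.0, 2.0, 0.0])
        assert auc_trapezoid(s, (150, 170)) == pytest.approx(20.0)

    def test_window_outside_span(self):
        s = _series([150, 160, 170], [1.0, 2.0, 1.0])
        with pytest.raises(EstimationError, match="outside"):
            auc_trapezoid(s, (140, 170))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_additivity_at_sample_point(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 100, 12))
        t[0], t[6], t[-1] = 0.0, 50.0, 100.0
        t = np.unique(t)
        s = _series(t, rng.normal(5, 2, len(t)))
        total = auc_trapezoid(s, (0.0, 100.0))
        split = auc_trapezoid(s, (0.0, 50.0)) + auc_trapezoid(s, (50.0, 100.0))
        assert split == pytest.approx(total, abs=1e-9)


class TestIauc:
    base = _series([85, 150, 160, 170], [5.0, 5.0, 7.0, 5.0])

    def test_constant_at_baseline_is_zero(self):
        s = _series([85, 150, 160, 170], [5.0, 5.0, 5.0, 5.0])
        assert iauc(s, (150, 170), 85.0) == pytest.approx(0.0)

    def test_hand_triangle(self):
        assert iauc(self.base, (150, 170), 85.0) == pytest.approx(20.0)

    def test_below_baseline_negative(self):
        s = _series([85, 150, 160, 170], [5.0, 5.0, 3.0, 5.0])
        assert iauc(s, (150, 170), 85.0) == pytest.approx(-20.0)

    def test_identity_with_shifted_auc(self):
        shifted = _series([85, 150, 160, 170],
                          self.base.values - self.base.value_at(85.0))
        assert iauc(self.base, (150, 170), 85.0) == \
            pytest.approx(auc_trapezoid(shifted, (150, 170)), abs=1e-12)

    def test_missing_baseline_sample(self):
        with pytest.raises(ValidationError, match="no sample"):
            iauc(self.base, (150, 170), 80.0)


class TestWindowStats:
    def test_constant_cv_zero(self):
        s = _series([150, 155, 160], [3.0, 3.0, 3.0])
        mean, sd, cv = window_stats(s, (150, 160))
        assert (mean, sd, cv) == (3.0, 0.0, 0.0)

    def test_hand_mean(self):
        s = _series([150, 160, 170], [2.4, 2.6, 2.8])
        assert window_stats(s, (150, 170))[0] == pytest.approx(2.6)

    def test_empty_window(self):
        s = _series([150, 160, 170], [1.0, 2.0, 3.0])
        with pytest.raises(EstimationError, match="no samples"):
            window_stats(s, (151, 152))


class TestPeaks:
    def test_monotone_peaks_at_end(self):
        s = _series([0, 30, 60], [1.0, 2.0, 3.0])
        assert peak_metrics(s, (0, 60)) == (3.0, 60.0)

    def test_hand_peak(self):
        s = _series([0, 30, 60], [5.0, 8.4, 6.0])
        assert peak_metrics(s, (0, 60)) == (8.4, 30.0)

    def test_tie_broken_by_earliest(self):
        s = _series([0, 30, 60], [5.0, 8.4, 8.4])
        assert peak_metrics(s, (0, 60)) == (8.4, 30.0)


class TestSymptomScores:
    def test_all_absent_hits_lower_bounds(self):
        scores = symptom_scores(SymptomRating.uniform(1))
        assert scores == {"total": 11, "autonomic": 4,
                          "neuroglycopenic": 5, "malaise": 2}

    def test_all_severe_hits_upper_bounds(self):
        scores = symptom_scores(SymptomRating.uniform(7))
        assert scores == {"total": 77, "autonomic": 28,
                          "neuroglycopenic": 35, "malaise": 14}

    def test_mixed_hand_sum(self):
        items = {i: 1 for i in SymptomRating.uniform(1).items}
        for name in ("sweating", "palpitations", "tremor", "hunger"):
            items[name] = 4
        scores = symptom_scores(SymptomRating(items))
        assert scores["autonomic"] == 16
        assert scores["total"] == 23

    @pytest.mark.parametrize("bad", [0, 8, 3.5])
    def test_out_of_range_rating_rejected(self, bad):
        items = {i: 1 for i in SymptomRating.uniform(1).items}
        items["nausea"] = bad
        with pytest.raises(ValidationError):
            SymptomRating(items)

    def test_missing_item_rejected(self):
        items = {i: 1 for i in SymptomRating.uniform(1).items}
        del items["tremor"]
        with pytest.raises(ValidationError):
            SymptomRating(items)


class TestCompareGroups:
    def test_identical_groups_null(self):
        g = {k: np.array([1.0, 2.0, 3.0, 4.0]) for k in "ABCD"}
        res = compare_groups(g)
        assert res.p_global > 0.05

    def test_degenerate_all_equal(self):
        g = {k: np.array([2.0, 2.0, 2.0]) for k in "AB"}
        res = compare_groups(g)
        assert res.test_used == "degenerate" and res.p_global == 1.0

    def test_forced_kruskal_mannwhitney_oracle(self):
        """Fully separated ranks: the two-sided exact Mann-Whitney p is
        2/C(10,5) = 2/252, by enumeration of the 252 rank splits."""
        g = {"A": np.array([1.0, 2, 3, 4, 5]),
             "B": np.array([6.0, 7, 8, 9, 10])}
        res = compare_groups(g, force="kruskal")
        assert res.test_used == "kruskal"
        assert res.pairwise[("A", "B")] == pytest.approx(2.0 / 252.0,
                                                         rel=1e-9)

    def test_anova_path_on_clean_normal_data(self):
        rng = np.random.default_rng(8)
        g = {k: rng.normal(10, 2, 8) for k in "ABCD"}
        res = compare_groups(g)
        assert res.test_used == "anova"
        assert res.posthoc_method == "tukey"
        assert len(res.pairwise) == 6
        assert all(0.0 <= p <= 1.0 for p in res.pairwise.values())

    def test_log_branch_blocked_by_nonpositive_values(self):
        # grossly skewed with a zero: raw ANOVA fails, log impossible
        g = {"A": np.array([0.0, 0.01, 0.02, 0.01, 100.0]),
             "B": np.array([5.0, 5.1, 4.9, 5.0, 5.05]),
             "C": np.array([1.0, 1.1, 0.9, 1.0, 1.05])}
        res = compare_groups(g)
        assert res.test_used == "kruskal"
        assert any(name == "log_branch_blocked_nonpositive"
                   for name, _ in res.trail)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        vals = {k: rng.normal(10, 2, 8) for k in "ABCD"}
        res1 = compare_groups(vals)
        relabel = {"A": "D", "B": "C", "C": "B", "D": "A"}
        res2 = compare_groups({relabel[k]: v for k, v in vals.items()})
        assert res1.p_global == pytest.approx(res2.p_global, rel=1e-12)
        for (a, b), p in res1.pairwise.items():
            key = tuple(sorted((relabel[a], relabel[b])))
            assert res2.pairwise[key] == pytest.approx(p, rel=1e-9)

    def test_group_size_contract(self):
        with pytest.raises(EstimationError):
            compare_groups({"A": np.array([1.0, 2.0]),
                            "B": np.array([1.0, 2.0, 3.0])})


class TestPairedChange:
    def test_no_change_maximal_p(self):
        p, used, _ = paired_change_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0 and used == "degenerate"

    def test_normal_differences_use_paired_t(self):
        rng = np.random.default_rng(2)
        before = rng.normal(100, 10, 12)
        after = before + rng.normal(2, 1, 12)
        p, used, trail = paired_change_test(before, after)
        assert used == "paired_t"
        assert trail[0][1] >= 0.05    # the recorded normality check

    def test_skewed_differences_use_wilcoxon(self):
        rng = np.random.default_rng(3)
        before = rng.normal(100, 1, 20)
        after = before + np.exp(rng.normal(0, 1.5, 20))   # heavy right skew
        p, used, trail = paired_change_test(before, after)
        assert used == "wilcoxon"
        assert trail[0][1] < 0.05


class TestOutcomeSpec:
    def test_transform_dispatch(self):
        s = _series([85, 150, 160, 170], [5.0, 5.0, 7.0, 5.0])
        spec = OutcomeSpec("glucagon_iauc", "glucagon", (150, 170), "iauc",
                           baseline_time=85.0)
        assert spec.evaluate(s) == pytest.approx(20.0)
        spec = OutcomeSpec("peak", "glucagon", (85, 170), "peak")
        assert spec.evaluate(s) == 7.0

    def test_invalid_transform(self):
        with pytest.raises(ValidationError):
            OutcomeSpec("x", "glucose", (0, 10), "integral")
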