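"""Dual-threshold optimization, three-way classification, leave-one-out."""

import numpy as np
import pytest

from ictomark.classify import (
    ClassifierError,
    LeaveOneOutClassifier,
    ThresholdPair,
    classify,
    loocv,
    optimize_thresholds,
    performance,
)


def brute_force_thresholds(values, labels, direction):
    """Independent oracle: scan every midpoint between consecutive order
    statistics (and beyond the extremes) for both objectives."""
    values = np.asarray(values, float)
    is_ige = np.asarray([str(l) in ("ige", "patient") for l in labels])
    s = 1.0 if direction == "higher_is_ige" else -1.0
    sv = s * values
    u = np.unique(sv)
    pad = 0.5 * np.median(np.diff(u)) if u.size > 1 else 1.0
    cuts = np.concatenate([[u[0] - pad], (u[:-1] + u[1:]) / 2, [u[-1] + pad]])
    best1, best2 = None, None
    for c in cuts:
        sens = (sv[is_ige] > c).mean()
        spec_ok = (sv[~is_ige] > c).sum() == 0
        if spec_ok and (best1 is None or sens > best1[1] + 1e-12):
            best1 = (c, sens)
        spec = (sv[~is_ige] < c).mean()
        sens_ok = (sv[is_ige] <= c).sum() == 0
        if sens_ok and (best2 is None or spec > best2[1] + 1e-12):
            best2 = (c, spec)
    # report the midpoint of the optimal plateau for th1 (scan from below
    # keeps the first optimal cut, which is the lower edge midpoint)
    return s * best1[0], best1[1], s * best2[0], best2[1]


class TestOptimizeThresholds:
    def test_worked_example(self):
        values = [1.0, 2.0, 3.0, 2.5, 4.0, 5.0]
        labels = ["control"] * 3 + ["ige"] * 3
        tp = optimize_thresholds(values, labels, "higher_is_ige")
        assert 3.0 < tp.th1 < 4.0
        assert tp.th1 == pytest.approx(3.5)
        assert tp.train_sensitivity == pytest.approx(2 / 3)
        assert 2.0 < tp.th2 < 2.5
        assert tp.th2 == pytest.approx(2.25)
        assert tp.train_specificity == pytest.approx(2 / 3)

    def test_perfectly_separated_cuts_fall_in_gap(self):
        values = [1.0, 2.0, 5.0, 6.0]
        labels = ["control", "control", "ige", "ige"]
        tp = optimize_thresholds(values, labels, "higher_is_ige")
        assert 2.0 < tp.th1 < 5.0 and 2.0 < tp.th2 < 5.0
        assert tp.train_sensitivity == 1.0 and tp.train_specificity == 1.0

    def test_fully_overlapping_values_give_zero_performance(self):
        values = [2.0] * 6
        labels = ["control"] * 3 + ["ige"] * 3
        tp = optimize_thresholds(values, labels, "higher_is_ige")
        assert tp.train_sensitivity == 0.0
        assert tp.train_specificity == 0.0

    def test_boundary_tie_enforces_strict_hundred_percent(self):
        # a control and an IGE subject tie at 3.0: the cut must move past it
        values = [1.0, 3.0, 3.0, 5.0]
        labels = ["control", "control", "ige", "ige"]
        tp = optimize_thresholds(values, labels, "higher_is_ige")
        assert tp.th1 > 3.0
        assert tp.train_sensitivity == pytest.approx(0.5)

    def test_lower_is_ige_direction_mirrors(self):
        values = [5.0, 4.0, 3.0, 3.5, 2.0, 1.0]
        labels = ["control"] * 3 + ["ige"] * 3
        tp = optimize_thresholds(values, labels, "lower_is_ige")
        assert 2.0 < tp.th1 < 3.0
        assert tp.train_sensitivity == pytest.approx(2 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError, match="both classes"):
            optimize_thresholds([1.0, 2.0], ["ige", "ige"], "higher_is_ige")

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("direction", ["higher_is_ige", "lower_is_ige"])
    def test_midpoint_cuts_match_brute_force_oracle(self, seed, direction):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        n_ige = int(rng.integers(2, n - 1))
        values = np.round(rng.normal(0, 1, n) + np.where(np.arange(n) < n_ige, 0.5, 0.0), 2)
        labels = ["ige"] * n_ige + ["control"] * (n - n_ige)
        tp = optimize_thresholds(values, labels, direction)
        o1, osens, o2, ospec = brute_force_thresholds(values, labels, direction)
        assert tp.train_sensitivity == pytest.approx(osens)
        assert tp.train_specificity == pytest.approx(ospec)
        assert tp.th1 == pytest.approx(o1)
        assert tp.th2 == pytest.approx(o2)


class TestClassify:
    tp = ThresholdPair(th1=3.5, th2=2.25, direction="higher_is_ige",
                       train_sensitivity=0.6, train_specificity=0.6)

    @pytest.mark.parametrize("value, outcome", [
        (5.0, "ige"), (3.0, "uncertain"), (1.0, "normal"),
    ])
    def test_three_way_rule(self, value, outcome):
        assert classify(value, self.tp) == outcome

    def test_lower_is_ige_rule(self):
        tp = ThresholdPair(th1=2.5, th2=3.75, direction="lower_is_ige",
                           train_sensitivity=0.5, train_specificity=0.5)
        assert classify(1.0, tp) == "ige"
        assert classify(3.0, tp) == "uncertain"
        assert classify(5.0, tp) == "normal"

    def test_objectives_can_use_distinct_values(self):
        assert classify(5.0, self.tp, value2=1.0) == "uncertain"
        assert classify(5.0, self.tp, value2=4.0) == "ige"

    def test_non_finite_rejected(self):
        with pytest.raises(ClassifierError):
            classify(np.nan, self.tp)


class TestLOOCV:
    def test_identical_values_all_uncertain(self):
        values = np.full(10, 1.0)
        labels = ["ige"] * 5 + ["control"] * 5
        res = loocv(values, labels, "mean_degree")
        assert res.outcomes == ["uncertain"] * 10

    def test_separable_cohorts_fully_recovered(self):
        values = np.r_[np.arange(10.0, 15.0), np.arange(1.0, 6.0)]
        labels = ["ige"] * 5 + ["control"] * 5
        res = loocv(values, labels, "mean_degree")
        perf = res.performance()
        assert perf["sensitivity"] == 1.0 and perf["specificity"] == 1.0
        assert "uncertain" not in res.outcomes

    def test_every_fold_keeps_training_guarantees(self):
        rng = np.random.default_rng(3)
        values = np.r_[rng.normal(1.0, 1.0, 8), rng.normal(0.0, 1.0, 9)]
        labels = np.array(["ige"] * 8 + ["control"] * 9)
        res = loocv(values, labels, "mean_degree")
        for fold in res.folds:
            train = np.ones(len(values), bool)
            train[fold.subject] = False
            tv, tl = values[train], labels[train] == "ige"
            # th1: no training control on the IGE side
            assert (tv[~tl] > fold.thresholds.th1).sum() == 0
            # th2: no training IGE subject on the control side
            assert (tv[tl] < fold.thresholds.th2).sum() == 0

    def test_outcomes_invariant_to_subject_ordering(self):
        rng = np.random.default_rng(4)
        values = np.r_[rng.normal(1.0, 1.0, 6), rng.normal(0.0, 1.0, 6)]
        labels = np.array(["ige"] * 6 + ["control"] * 6)
        res = loocv(values, labels, "mean_degree")
        perm = rng.permutation(12)
        res_p = loocv(values[perm], labels[perm], "mean_degree")
        assert [res.outcomes[i] for i in perm] == res_p.outcomes

    def test_parametric_table_with_single_cell_matches_scalar_path(self):
        rng = np.random.default_rng(5)
        values = np.r_[rng.normal(1.0, 1.0, 6), rng.normal(0.0, 1.0, 6)]
        labels = ["ige"] * 6 + ["control"] * 6
        scalar = loocv(values, labels, "mean_degree")
        table = values[:, None, None]
        parametric = loocv(table, labels, "local_coupling",
                           channels=("CZ",), K_grid=[1.0])
        # identical data seen through the cached table gives identical outcomes
        assert parametric.outcomes == scalar.outcomes

    def test_parametric_search_prefers_separating_cell(self):
        rng = np.random.default_rng(6)
        n = 14
        labels = ["ige"] * 7 + ["control"] * 7
        noise = rng.normal(0, 1, (n, 2, 2))
        signal = np.where(np.arange(n) < 7, 2.5, 0.0)
        table = noise.copy()
        table[:, 1, 0] = signal + rng.normal(0, 0.3, n)  # informative cell
        res = loocv(table, labels, "local_coupling",
                    channels=("C3", "C4"), K_grid=[0.5, 1.0])
        assert res.performance()["sensitivity"] >= 0.7
        assert all(f.thresholds.params1 == ("C4", 0.5) for f in res.folds)

    def test_missing_class_in_training_fold_rejected(self):
        with pytest.raises(ClassifierError):
            loocv(np.arange(4.0), ["ige", "control", "control", "control"],
                  "mean_degree")

    def test_model_object_interface(self):
        values = np.r_[np.arange(10.0, 15.0), np.arange(1.0, 6.0)]
        labels = ["patient"] * 5 + ["control"] * 5
        clf = LeaveOneOutClassifier(values, labels, "mean_degree")
        res = clf.fit()
        assert res.performance()["sensitivity"] == 1.0
        assert "sensitivity" in res.summary()


class TestPerformance:
    def test_counts_to_rates(self):
        outcomes = ["ige"] * 3 + ["uncertain"] * 2 + ["normal"] * 1 + \
                   ["normal"] * 4 + ["uncertain"] * 2
        labels = ["ige"] * 6 + ["control"] * 6
        perf = performance((outcomes, labels))
        assert perf["sensitivity"] == pytest.approx(0.5)
        assert perf["specificity"] == pytest.approx(4 / 6)
        assert perf["counts"]["ige"] == {"ige": 3, "uncertain": 2, "normal": 1}

    def test_all_uncertain_scores_zero(self):
        perf = performance((["uncertain"] * 4, ["ige", "ige", "control", "control"]))
        assert perf["sensitivity"] == 0.0 and perf["specificity"] == 0.0
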