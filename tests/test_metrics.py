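"""Miscalibration, interval LRs, win rules, binomial test, classification."""

import numpy as np
import pytest

from vepcal.evidence import posterior_from_lr
from vepcal.metrics import (
    binomial_win_test,
    classification_metrics,
    evidence_heatmap,
    interval_lr,
    miscalibration,
    win_compare,
)


def posterior_at_points(points, scale):
    """Posterior whose continuous evidence points equal ``points``."""
    return posterior_from_lr(scale.lr1 ** np.asarray(points, dtype=float),
                             scale.prior)


class TestMiscalibration:
    def test_perfect_calibration_is_zero(self, scale01):
        post = posterior_at_points([3, -2, 0.5, 1.2], scale01)
        s = miscalibration(post, post, scale01)
        assert s.mape == 0.0
        assert s.pfraction == 0.0
        assert s.bfraction == 0.0

    def test_worked_point_error(self, scale01):
        est = posterior_at_points([7.0], scale01)
        true = posterior_at_points([5.0], scale01)
        s = miscalibration(est, true, scale01)
        assert s.per_score_delta[0] == pytest.approx(2.0, abs=1e-9)
        assert s.mape == pytest.approx(2.0, abs=1e-9)

    def test_pfraction_hand_enumeration(self, scale01):
        # four scores in the pathogenic region (EP_true = 2), deltas
        # (0, 1.5, 0.5, 2.0): exactly two exceed one point
        true = posterior_at_points([2, 2, 2, 2], scale01)
        est = posterior_at_points([2.0, 3.5, 2.5, 4.0], scale01)
        s = miscalibration(est, true, scale01)
        assert s.pfraction == pytest.approx(0.5)

    def test_region_reading_switch(self, scale01):
        # away from the EP_true = 1 boundary both region readings agree
        true = posterior_at_points([2.0, 0.5], scale01)
        est = posterior_at_points([3.5, 0.5], scale01)
        strict = miscalibration(est, true, scale01, strict_regions=True)
        relaxed = miscalibration(est, true, scale01, strict_regions=False)
        assert strict.pfraction == relaxed.pfraction == pytest.approx(1.0)
        # the only divergence is at the boundary itself: EP_true slightly
        # above 1 belongs to both regions, slightly below to neither
        near = posterior_at_points([1.01, 0.99], scale01)
        est2 = posterior_at_points([2.5, 2.5], scale01)
        s = miscalibration(est2, near, scale01, strict_regions=True)
        assert s.pfraction == pytest.approx(1.0)  # only 1.01 is in-region

    def test_permutation_invariance_and_antisymmetry(self, scale01, rng):
        pts = rng.uniform(-6, 6, 40)
        est = posterior_at_points(pts + rng.normal(0, 0.5, 40), scale01)
        true = posterior_at_points(pts, scale01)
        s1 = miscalibration(est, true, scale01)
        perm = rng.permutation(40)
        s2 = miscalibration(est[perm], true[perm], scale01)
        assert s1.mape == pytest.approx(s2.mape)
        s_swap = miscalibration(true, est, scale01)
        np.testing.assert_allclose(
            np.sort(s_swap.per_score_delta), np.sort(-s1.per_score_delta),
            atol=1e-9,
        )


class TestIntervalLR:
    def test_whole_support_is_unit_lr(self, scale01, rng):
        ivs = {lv: [(0.0, 1.0)] for lv in (-4, -3, -2, -1, 1, 2, 3, 4)}
        rep = interval_lr(ivs, rng.uniform(0, 1, 10), rng.uniform(0, 1, 20),
                          scale01)
        assert all(v == pytest.approx(1.0) for v in rep.lr.values())

    def test_printed_toy_counts(self, scale01):
        path = np.concatenate([np.full(4, 0.9), np.full(6, 0.1)])
        ben = np.concatenate([np.full(2, 0.9), np.full(18, 0.1)])
        ivs = {1: [(0.8, 1.0)]}
        rep = interval_lr(ivs, path, ben, scale01)
        assert rep.lr[1] == pytest.approx(4.0)  # (4/10)/(2/20)

    def test_matches_counting_oracle_on_random_instances(self, scale01, rng):
        for _ in range(100):
            path = rng.uniform(0, 1, 30)
            ben = rng.uniform(0, 1, 30)
            ivs = {}
            for lv in (-4, -3, -2, -1, 1, 2, 3, 4):
                lo = rng.uniform(0, 0.9)
                ivs[lv] = [(lo, lo + rng.uniform(0.02, 0.1))]
            rep = interval_lr(ivs, path, ben, scale01)
            for lv, (lo, hi) in ((k, v[0]) for k, v in ivs.items()):
                n_p = sum(1 for s in path if lo <= s <= hi)
                n_b = sum(1 for s in ben if lo <= s <= hi)
                if n_p == 0 and n_b == 0:
                    assert not rep.defined[lv]
                elif n_b == 0:
                    assert np.isposinf(rep.lr[lv])
                else:
                    expected = (n_p / 30) / (n_b / 30)
                    assert rep.lr[lv] == pytest.approx(expected)

    def test_requires_controls(self, scale01):
        with pytest.raises(ValueError):
            interval_lr({1: [(0, 1)]}, [], [0.5], scale01)


class TestWinCompare:
    def _report(self, scale, lrs):
        from vepcal.metrics import IntervalLRReport

        thr = {lv: scale.lr_thresholds[lv] for lv in lrs}
        return IntervalLRReport(
            lr=lrs, threshold=thr, defined={lv: True for lv in lrs}
        )

    def test_identical_reports_tie(self, scale01):
        lrs = {lv: scale01.lr_thresholds[lv] * 1.5 for lv in (1, 2, -1, -2)}
        a = self._report(scale01, lrs)
        wins, _, _ = win_compare(a, self._report(scale01, dict(lrs)))
        assert wins["tie"] == 4 and wins["A"] == wins["B"] == 0

    def test_closest_above_wins_pathogenic(self, scale01):
        thr = scale01.lr_thresholds[1]
        a = self._report(scale01, {1: thr * 1.2})
        b = self._report(scale01, {1: thr * 3.0})
        wins, per, _ = win_compare(a, b)
        assert per[1] == "A"

    def test_conservative_side_wins_when_split(self, scale01):
        thr = scale01.lr_thresholds[1]
        a = self._report(scale01, {1: thr * 0.7})  # under-calls evidence
        b = self._report(scale01, {1: thr * 1.2})
        wins, per, _ = win_compare(a, b)
        assert per[1] == "B" if thr * 0.7 < thr else "A"
        # pathogenic level: the on-side (higher-LR) report is conservative
        assert per[1] == "B"

    def test_benign_direction_mirrors(self, scale01):
        thr = scale01.lr_thresholds[-1]
        a = self._report(scale01, {-1: thr * 0.9})  # on preferred (low) side
        b = self._report(scale01, {-1: thr * 1.2})
        _, per, _ = win_compare(a, b)
        assert per[-1] == "A"

    def test_undefined_levels_skipped(self, scale01):
        from vepcal.metrics import IntervalLRReport

        thr = {1: scale01.lr_thresholds[1]}
        a = IntervalLRReport(lr={1: 3.0}, threshold=thr, defined={1: False})
        b = IntervalLRReport(lr={1: 2.5}, threshold=thr, defined={1: True})
        wins, per, _ = win_compare(a, b)
        assert per[1] == "skipped" and wins["skipped"] == 1


class TestBinomialWinTest:
    def test_all_wins(self):
        assert binomial_win_test(10, 0, 10) == pytest.approx(0.5 ** 10)

    @pytest.mark.parametrize(
        "wins,ties,n,expected,tol",
        [
            (65, 10, 101, 3e-5, 1e-5),
            (51, 20, 105, 0.041, 0.001),
            (47, 17, 98, 0.091, 0.001),
        ],
    )
    def test_published_comparison_pvalues(self, wins, ties, n, expected, tol):
        assert binomial_win_test(wins, ties, n) == pytest.approx(expected, abs=tol)

    def test_matches_pmf_summation(self):
        from scipy.stats import binom

        n_eff = 30
        expected = sum(binom.pmf(k, n_eff, 0.5) for k in range(18, n_eff + 1))
        assert binomial_win_test(18, 5, 35) == pytest.approx(expected, abs=1e-12)

    def test_all_tied_errors(self):
        with pytest.raises(ValueError):
            binomial_win_test(0, 5, 5)


class TestClassificationMetrics:
    def test_perfect_assignment(self):
        pts = np.array([2, 1, 4, -1, -3, -2])
        labels = np.array(["P", "P", "P", "B", "B", "B"])
        m = classification_metrics(pts, labels)
        assert m["AvgTPR"] == 1.0
        assert m["AvgFPR"] == 0.0
        assert m["MCC"] == pytest.approx(1.0)
        assert m["determinate_rate"] == 1.0

    def test_all_zero_points(self):
        m = classification_metrics(np.zeros(6, dtype=int),
                                   np.array(["P"] * 3 + ["B"] * 3))
        assert m["determinate_rate"] == 0.0
        assert m["AvgTPR"] == 0.0

    def test_hand_table(self):
        pts = np.array([1, 1, 1, 1, 1, 1, 1, -1, 0, 0,
                        -1, -1, -1, -1, -1, -1, 2, 0, 0, 0])
        labels = np.array(["P"] * 10 + ["B"] * 10)
        m = classification_metrics(pts, labels)
        assert m["TPR_P"] == pytest.approx(0.7)
        assert m["FPR_P"] == pytest.approx(0.1)
        assert m["TPR_B"] == pytest.approx(0.6)
        assert m["FPR_B"] == pytest.approx(0.1)
        assert m["AvgTPR"] == pytest.approx(0.65)
        assert m["AvgFPR"] == pytest.approx(0.1)


class TestEvidenceHeatmap:
    def test_rows_sum_to_hundred(self, rng):
        pts = rng.integers(-4, 5, 200)
        strata = rng.choice(["P/LP", "B/LB", "VUS"], 200)
        heat = evidence_heatmap(pts, strata)
        np.testing.assert_allclose(heat.sum(axis=1), 100.0)

    def test_single_variant_single_cell(self):
        heat = evidence_heatmap(np.array([3]), np.array(["VUS"]))
        assert heat.loc["VUS", 3] == 100.0
        assert heat.loc["VUS"].drop(3).sum() == 0.0

    def test_difference_antisymmetric(self, rng):
        pts_a = rng.integers(-4, 5, 100)
        pts_b = rng.integers(-4, 5, 100)
        strata = np.array(["all"] * 100)
        d1 = evidence_heatmap(pts_a, strata) - evidence_heatmap(pts_b, strata)
        d2 = evidence_heatmap(pts_b, strata) - evidence_heatmap(pts_a, strata)
        np.testing.assert_allclose(d1.values, -d2.values, atol=1e-12)
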