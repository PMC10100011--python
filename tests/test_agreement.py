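"""Bland–Altman statistics, exact LoA confidence limits, Dice, paired tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from carotiq.agreement import (
    DiffSummary,
    PairedMeasurements,
    agreement_report,
    bias_confidence_interval,
    bland_altman,
    dice,
    exact_loa_confidence_limits,
    limits_of_agreement,
    paired_t_test,
    percent_volume_deviation,
    summarize_differences,
    welch_t_test,
)
from carotiq.errors import GridMismatchError, SampleSizeError
from carotiq.imagevol import BinaryMask, VoxelGrid


def pairs_from_diffs(diffs, base=10.0):
    diffs = np.asarray(diffs, float)
    b = np.full_like(diffs, base)
    return PairedMeasurements(list(range(len(diffs))), b + diffs, b)


class TestDiffSummary:
    def test_constant_differences(self):
        s = summarize_differences(pairs_from_diffs([1, 1, 1]))
        assert s.mean_diff == pytest.approx(1.0)
        assert s.sd_diff == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        s = summarize_differences(pairs_from_diffs([0, 2]))
        assert s.mean_diff == pytest.approx(1.0)
        assert s.sd_diff == pytest.approx(np.sqrt(2), rel=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2024)
        d = rng.normal(1.33, 2.06, size=1000)
        s = summarize_differences(pairs_from_diffs(d))
        assert abs(s.mean_diff - 1.33) < 0.2
        assert abs(s.sd_diff - 2.06) < 0.15

    def test_too_small_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            DiffSummary(n=1, mean_diff=0.0, sd_diff=1.0)


class TestLimitsOfAgreement:
    @pytest.mark.parametrize("mean,sd,expected", [
        (1.73, 1.59, (-1.39, 4.85)),   # interoperator volume, left carotid
        (1.28, 1.91, (-2.46, 5.02)),   # interoperator volume, right carotid
        (0.0, 1.0, (-1.96, 1.96)),
    ])
    def test_point_estimates(self, mean, sd, expected):
        lo, hi = limits_of_agreement(DiffSummary(25, mean, sd))
        assert round(lo, 2) == expected[0]
        assert round(hi, 2) == expected[1]


class TestBiasCI:
    def test_degenerate_sd(self):
        assert bias_confidence_interval(DiffSummary(10, 1.0, 0.0)) == (1.0, 1.0)

    def test_halfwidth_matches_t_quantile(self):
        s = DiffSummary(49, 1.33, 2.06)
        lo, hi = bias_confidence_interval(s)
        half = stats.t.ppf(0.975, 48) * 2.06 / 7.0
        assert (hi - lo) / 2 == pytest.approx(half, rel=1e-9)
        assert half == pytest.approx(0.5917, abs=1e-4)

    def test_large_n_normal_limit(self):
        n = 100_000
        lo, hi = bias_confidence_interval(DiffSummary(n, 0.0, 1.0))
        assert hi == pytest.approx(1.96 / np.sqrt(n), rel=1e-3)


class TestExactLoaCI:
    def test_degenerate_sd_collapses(self):
        lower, upper = exact_loa_confidence_limits(DiffSummary(20, 2.5, 0.0))
        assert lower == (2.5, 2.5)
        assert upper == (2.5, 2.5)

    def test_brackets_loa_and_bias(self):
        s = DiffSummary(25, 1.0, 2.0)
        res = bland_altman(s)
        assert res.loa_lower_ci[0] < res.loa_lower < res.loa_lower_ci[1]
        assert res.loa_upper_ci[0] < res.loa_upper < res.loa_upper_ci[1]
        assert res.loa_lower < s.mean_diff < res.loa_upper

    @pytest.mark.parametrize("n", [10, 25, 49])
    def test_at_least_as_wide_as_normal_approximation(self, n):
        s = DiffSummary(n, 0.0, 1.0)
        _, (lo, hi) = exact_loa_confidence_limits(s)
        naive_half = 1.96 * np.sqrt(1 / n + 1.96**2 / (2 * (n - 1)))
        assert (hi - lo) / 2 >= naive_half

    def test_widens_with_level(self):
        s = DiffSummary(25, 0.0, 1.0)
        _, u90 = exact_loa_confidence_limits(s, level=0.90)
        _, u95 = exact_loa_confidence_limits(s, level=0.95)
        _, u99 = exact_loa_confidence_limits(s, level=0.99)
        assert u90[1] < u95[1] < u99[1]
        assert u90[0] > u95[0] > u99[0]

    def test_equal_tails_variant_matches_quantiles(self):
        s = DiffSummary(49, 1.33, 2.06)
        _, upper = exact_loa_confidence_limits(s, tails="equal")
        k_hi = stats.nct.ppf(0.975, 48, 1.96 * 7)
        assert upper[1] == pytest.approx(1.33 + k_hi * 2.06 / 7, rel=1e-9)

    def test_coverage_close_to_nominal(self):
        # simulated coverage of the lower-LoA interval under Normal(0, 1)
        n, reps = 25, 2000
        rng = np.random.default_rng(99)
        x = rng.normal(0.0, 1.0, size=(reps, n))
        means = x.mean(axis=1)
        sds = x.std(axis=1, ddof=1)
        lower, _ = exact_loa_confidence_limits(DiffSummary(n, 0.0, 1.0))
        # reuse the k factors through the linear form of the interval
        k_lo = (0.0 - lower[1]) * np.sqrt(n)  # = -K_L (scaled)
        k_hi = (0.0 - lower[0]) * np.sqrt(n)
        lo = means - k_hi * sds / np.sqrt(n)
        hi = means - k_lo * sds / np.sqrt(n)
        covered = np.mean((lo <= -1.96) & (-1.96 <= hi))
        assert covered == pytest.approx(0.95, abs=0.015)


class TestDice:
    GRID = VoxelGrid((4, 4, 4), (1, 1, 1))

    def mask(self, coords):
        v = np.zeros(self.GRID.shape, bool)
        for c in coords:
            v[c] = True
        return BinaryMask(self.GRID, v)

    def test_identical_masks(self):
        m = self.mask([(0, 0, 0), (1, 1, 1)])
        assert dice(m, m).value == 1.0

    def test_disjoint_masks(self):
        a = self.mask([(0, 0, 0)])
        b = self.mask([(3, 3, 3)])
        assert dice(a, b).value == 0.0

    def test_half_overlap(self):
        a = self.mask([(0, 0, 0), (0, 0, 1)])
        b = self.mask([(0, 0, 1), (0, 0, 2)])
        assert dice(a, b).value == pytest.approx(0.5)

    def test_symmetry(self):
        a = self.mask([(0, 0, 0), (1, 2, 3), (2, 2, 2)])
        b = self.mask([(1, 2, 3), (3, 0, 0)])
        assert dice(a, b).value == dice(b, a).value

    def test_both_empty_flagged_as_one(self):
        e = self.mask([])
        r = dice(e, e)
        assert r.value == 1.0 and r.both_empty

    def test_grid_mismatch(self):
        other = BinaryMask(VoxelGrid((4, 4, 4), (2, 2, 2)),
                           np.zeros((4, 4, 4), bool))
        with pytest.raises(GridMismatchError):
            dice(self.mask([]), other)


class TestPairedT:
    def test_all_zero_differences(self):
        t, p = paired_t_test(pairs_from_diffs([0, 0, 0, 0]))
        assert t == 0.0 and p == 1.0

    def test_symmetric_differences(self):
        t, p = paired_t_test(pairs_from_diffs([1, -1]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_nonzero_mean_floored(self):
        t, p = paired_t_test(pairs_from_diffs([2, 2, 2]))
        assert np.isinf(t)
        assert 0 < p < 1e-300

    def test_power_at_reported_effect(self):
        # differences ~ Normal(1.89, 1.5) at n=49 should give p < 0.001
        rng = np.random.default_rng(7)
        significant = 0
        for _ in range(200):
            d = rng.normal(1.89, 1.5, size=49)
            _, p = paired_t_test(pairs_from_diffs(d))
            significant += p < 0.001
        assert significant >= 198

    def test_matches_scipy_on_generic_data(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(20), rng.random(20)
        pairs = PairedMeasurements(list(range(20)), a, b)
        t, p = paired_t_test(pairs)
        t2, p2 = stats.ttest_rel(a, b)
        assert t == pytest.approx(float(t2)) and p == pytest.approx(float(p2))


class TestPercentDeviation:
    def test_identical_methods(self):
        pairs = PairedMeasurements([0, 1], [5.0, 6.0], [5.0, 6.0])
        assert percent_volume_deviation(pairs) == 0.0

    def test_single_pair_closed_form(self):
        pairs = PairedMeasurements([0, 1], [10.0, 10.0], [8.0, 10.0])
        # subject 0: 100*2/9; subject 1: 0
        assert percent_volume_deviation(pairs) == pytest.approx(100 * 2 / 9 / 2)

    def test_against_bruteforce_loop(self):
        rng = np.random.default_rng(11)
        b = np.full(25, 8.4)
        a = b + rng.normal(-0.69, 0.98, size=25)
        pairs = PairedMeasurements(list(range(25)), a, b)
        expected = np.mean([100 * abs(x - y) / ((x + y) / 2) for x, y in zip(a, b)])
        assert percent_volume_deviation(pairs) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_volume_rejected(self):
        pairs = PairedMeasurements([0, 1], [1.0, -1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            percent_volume_deviation(pairs)


class TestAgreementReport:
    def table(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            for side in ("left", "right"):
                rows.append({"case_id": f"c{i}", "side": side,
                             "vol_ml": 5 + rng.random(), "suv_mean": 1 + 0.1 * rng.random(),
                             "suv_max": 2 + rng.random(), "suv_total": 6 + rng.random()})
        return pd.DataFrame(rows)

    def test_identical_tables_zero_bias(self):
        t = self.table()
        rep = agreement_report(t, t.copy())
        assert np.allclose(rep["bias"], 0.0)
        assert np.allclose(rep["loa_lower"], 0.0)
        assert np.allclose(rep["loa_upper"], 0.0)

    def test_shape_contract(self):
        rep = agreement_report(self.table(0), self.table(1))
        assert len(rep) == 8  # 4 quantities x 2 sides
        assert set(rep["side"]) == {"left", "right"}

    def test_composition_matches_component_calls(self):
        a, b = self.table(0), self.table(1)
        rep = agreement_report(a, b)
        row = rep[(rep.side == "left") & (rep.quantity == "vol_ml")].iloc[0]
        sel_a = a[a.side == "left"].sort_values("case_id")["vol_ml"].to_numpy()
        sel_b = b[b.side == "left"].sort_values("case_id")["vol_ml"].to_numpy()
        pairs = PairedMeasurements(list(range(len(sel_a))), sel_a, sel_b)
        s = summarize_differences(pairs)
        lo, hi = limits_of_agreement(s)
        assert row["bias"] == pytest.approx(s.mean_diff)
        assert row["loa_lower"] == pytest.approx(lo)
        assert row["loa_upper"] == pytest.approx(hi)
        t, p = paired_t_test(pairs)
        assert row["p"] == pytest.approx(p)

    def test_mismatched_ids_rejected(self):
        a, b = self.table(0), self.table(1)
        b = b[b.case_id != "c0"]
        with pytest.raises(KeyError):
            agreement_report(a, b)


def test_welch_test_on_similar_populations():
    rng = np.random.default_rng(4)
    x = rng.normal(0.72, 0.1, 49)
    y = rng.normal(0.73, 0.08, 25)
    t, p = welch_t_test(x, y)
    assert 0 <= p <= 1
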