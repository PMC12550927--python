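"""Validation statistics: CV, detection limits, linearity, percentiles, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddscreen import (
    cn_distribution_table,
    compute_cv,
    levey_jennings_flags,
    limit_of_blank,
    limit_of_detection,
    limit_of_quantification,
    linearity_fit,
    reference_interval,
    stability_recovery,
)
from ddscreen.errors import InsufficientDataError


class TestCV:
    def test_constant_values(self):
        assert compute_cv([5, 5, 5, 5]).cv_percent == 0.0

    def test_hand_arithmetic(self):
        res = compute_cv([8, 10, 12])
        assert res.mean == 10.0 and res.sd == pytest.approx(2.0)
        assert res.cv_percent == pytest.approx(20.0)

    def test_zero_mean_flags_undefined(self):
        res = compute_cv([-1.0, 1.0])
        assert res.cv_percent is None and res.sd > 0

    def test_too_few_replicates(self):
        with pytest.raises(InsufficientDataError):
            compute_cv([1.0])

    @given(
        st.lists(st.floats(1.0, 1000.0), min_size=3, max_size=20),
        st.floats(0.1, 50.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, values, c):
        base = compute_cv(values).cv_percent
        scaled = compute_cv([v * c for v in values]).cv_percent
        if base is not None:
            assert scaled == pytest.approx(base, rel=1e-9)


class TestDetectionLimits:
    def test_all_zero_blanks(self):
        assert limit_of_blank([0.0] * 20) == 0.0

    def test_identical_blanks(self):
        assert limit_of_blank([3.0] * 20) == 3.0

    def test_documented_interpolation_convention(self):
        """(n+1)p rank: for 19 zeros and one 2, rank 19.95 -> 0.95 x 2 = 1.9."""
        assert limit_of_blank([0.0] * 19 + [2.0]) == pytest.approx(1.9)

    def test_too_few_blanks(self):
        with pytest.raises(InsufficientDataError):
            limit_of_blank([0.0] * 19)

    @pytest.mark.parametrize("lob,sd,expected", [(0, 0, 0), (0, 1.25, 2.0), (0, 1.875, 3.0)])
    def test_lod_formula(self, lob, sd, expected):
        assert limit_of_detection(lob, sd) == pytest.approx(expected)

    def test_lod_never_below_lob(self):
        assert limit_of_detection(5.0, 0.7) >= 5.0

    def test_loq_single_level(self):
        assert limit_of_quantification([(10.0, [10, 11, 9])]) == 10.0

    def test_loq_picks_lowest_passing_level(self):
        levels = [
            (10.0, [10.0, 4.0, 16.0]),  # CV 60%
            (20.0, [20.0, 17.0, 23.0]),  # CV 15%
            (40.0, [40.0, 39.0, 41.0]),
        ]
        assert limit_of_quantification(levels) == 20.0

    def test_loq_not_determined(self):
        assert limit_of_quantification([(10.0, [1.0, 20.0])]) is None


class TestLinearity:
    def test_perfect_fit(self):
        fit = linearity_fit([1, 2, 3], [1, 2, 3])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_ols(self):
        fit = linearity_fit([0, 1, 2], [0, 2, 4])
        assert fit.slope == pytest.approx(2.0) and fit.r_squared == pytest.approx(1.0)

    def test_degenerate_expected_rejected(self):
        with pytest.raises(ValueError):
            linearity_fit([2, 2, 2], [1, 2, 3])


class TestReferenceInterval:
    def test_constant_data(self):
        res = reference_interval([7.0] * 200)
        assert res.cutoff_value == 7.0 and res.reliable

    def test_order_statistic_convention(self):
        """1..1000 at p=0.025: rank 25.025 -> 25 + 0.025."""
        res = reference_interval(np.arange(1.0, 1001.0))
        assert res.cutoff_value == pytest.approx(25.025)

    def test_gestational_filter(self):
        values = [10.0] * 150 + [1000.0] * 150
        weeks = [30.0] * 150 + [40.0] * 150
        res = reference_interval(values, gestational_weeks=weeks)
        assert res.n == 150 and res.cutoff_value == 1000.0

    def test_small_n_flagged_unreliable(self):
        assert not reference_interval(np.arange(50.0)).reliable

    def test_monte_carlo_consistency(self):
        """At n = 10,000 the empirical percentile is within 2% of the true
        lognormal quantile."""
        rng = np.random.default_rng(77)
        sigma, median = 0.586, 180.0
        x = median * np.exp(rng.normal(0, sigma, 10_000))
        true_q = median * np.exp(-1.959963984540054 * sigma)
        res = reference_interval(x)
        assert res.cutoff_value == pytest.approx(true_q, rel=0.02)


class TestLeveyJennings:
    def test_rule_application(self):
        flags = levey_jennings_flags([10.0, 12.6, 8.1, 10.0], mean=10.0, sd=1.0)
        assert flags["out_of_control"].tolist() == [False, True, False, False]

    def test_within_two_sd_passes(self):
        flags = levey_jennings_flags([10.0 - 1.9], mean=10.0, sd=1.0)
        assert not flags["out_of_control"].any()

    def test_consecutive_violations_advisory(self):
        flags = levey_jennings_flags([13.0, 12.5, 10.0], mean=10.0, sd=1.0)
        assert flags["advisory_22s"].tolist() == [False, True, False]


class TestStability:
    @pytest.mark.parametrize(
        "d0,dn,expected,passes",
        [
            ([100, 100], [100, 100], 100.0, True),
            ([100.0], [95.0], 95.0, True),
            ([100.0], [85.0], 85.0, False),
        ],
    )
    def test_recovery(self, d0, dn, expected, passes):
        recovery, ok = stability_recovery(d0, dn)
        assert recovery == pytest.approx(expected) and ok is passes

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            stability_recovery([0.0], [1.0])


class TestDistributionTable:
    def test_single_sample(self):
        table = cn_distribution_table({"SMN1": [2]})
        assert table.loc[0, "percent"] == 100.0

    def test_population_percentages(self):
        """Observed population counts reproduce the published one-decimal
        percentages for the benchmark cells."""
        from ddscreen.datasets import SMN_CN_DISTRIBUTION

        calls = {
            gene: sum(([cn] * count for cn, count in counts.items()), [])
            for gene, counts in SMN_CN_DISTRIBUTION.items()
        }
        table = cn_distribution_table(calls)
        smn1 = table[table.gene == "SMN1"].set_index("copy_number")
        smn2 = table[table.gene == "SMN2"].set_index("copy_number")
        assert smn1.loc[1, "percent"] == 2.3
        assert smn2.loc[4, "percent"] == 0.3

    def test_percentages_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(5)
        calls = {"SMN2": rng.integers(0, 5, size=997).tolist()}
        total = cn_distribution_table(calls)["percent"].sum()
        assert abs(total - 100.0) <= 0.3
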