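import numpy as np
import pytest
from scipy import integrate, stats

from seguq import (
    QuantityTable,
    assess_characteristic_fit,
    characteristic_cdf,
    characteristic_quantile,
    check_monotonicity,
    fit_alternative,
    fit_characteristic_normal,
    make_quantity_table,
)
from seguq.distfit import MonotonicityError


def standard_normal_table(mean, sigma, extra_percentiles=()):
    """A table following the standard-percentile convention.

    The three standard rows carry (mean - sigma, mean, mean + sigma) — the
    values those percentiles denote — while any extra rows are true Normal
    quantiles.
    """
    P = [15.9, 50.0, 84.1] + list(extra_percentiles)
    Q = [mean - sigma, mean, mean + sigma] + [
        stats.norm.ppf(p / 100, loc=mean, scale=sigma)
        for p in extra_percentiles
    ]
    return QuantityTable(percentiles=np.array(P), values=np.array(Q))


class TestCharacteristicNormal:
    def test_symmetric_half_width_rule(self):
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1],
                              values=[8.0, 10.0, 12.0])
        dist = fit_characteristic_normal(table)
        assert dist.params == {"mean": 10.0, "sigma": 2.0}
        assert dist.diagnostics["upper_half_width"] == 2.0
        assert dist.diagnostics["lower_half_width"] == 2.0

    def test_recovers_parameters_from_own_quantiles(self):
        dist = fit_characteristic_normal(standard_normal_table(3.0, 0.7))
        assert dist.params["mean"] == pytest.approx(3.0, abs=1e-12)
        assert dist.params["sigma"] == pytest.approx(0.7, abs=1e-12)

    def test_degenerate_constant_table_flagged(self):
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1],
                              values=[5.0, 5.0, 5.0])
        dist = fit_characteristic_normal(table)
        assert dist.params["sigma"] == 0.0
        assert dist.diagnostics["degenerate"]

    def test_decreasing_quantity_uses_magnitude_and_flags(self):
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1],
                              values=[12.0, 10.0, 8.0])
        dist = fit_characteristic_normal(table)
        assert dist.params["sigma"] == 2.0
        assert dist.diagnostics["decreasing_orientation"]

    def test_missing_standard_percentile_named(self):
        table = QuantityTable(percentiles=[15.9, 50.0], values=[1.0, 2.0])
        with pytest.raises(ValueError, match="84.1"):
            fit_characteristic_normal(table)

    def test_nonmonotone_table_needs_override(self):
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1],
                              values=[1.0, 5.0, 2.0])
        with pytest.raises(MonotonicityError):
            fit_characteristic_normal(table)
        dist = fit_characteristic_normal(table, allow_nonmonotone=True)
        assert dist.params["mean"] == 5.0


class TestCdfQuantile:
    def test_normal_cdf_at_mean_is_half(self):
        dist = fit_characteristic_normal(standard_normal_table(10.0, 2.0))
        assert characteristic_cdf(dist, 10.0) == 0.5

    def test_quantile_cdf_inverse_identity(self):
        dist = fit_characteristic_normal(standard_normal_table(10.0, 2.0))
        for p in (0.01, 0.159, 0.5, 0.841, 0.99):
            assert characteristic_cdf(dist, characteristic_quantile(dist, p)) \
                == pytest.approx(p, abs=1e-10)

    def test_cdf_matches_density_quadrature(self):
        """The Normal CDF agrees with direct quadrature of its density."""
        dist = fit_characteristic_normal(standard_normal_table(10.0, 2.0))
        q = characteristic_quantile(dist, 0.841)

        def density(x):
            return np.exp(-((x - 10.0) ** 2) / (2 * 4.0)) / np.sqrt(8 * np.pi)

        integral, _ = integrate.quad(density, -np.inf, q)
        assert integral == pytest.approx(0.841, abs=1e-8)

    def test_degenerate_cdf_is_a_step(self):
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1],
                              values=[5.0, 5.0, 5.0])
        dist = fit_characteristic_normal(table)
        assert characteristic_cdf(dist, 4.999) == 0.0
        assert characteristic_cdf(dist, 5.0) == 1.0

    def test_quantile_level_outside_unit_interval_rejected(self):
        dist = fit_characteristic_normal(standard_normal_table(0.0, 1.0))
        with pytest.raises(ValueError):
            characteristic_quantile(dist, 1.2)


class TestAssessFit:
    def test_self_generated_table_has_negligible_discrepancy(self):
        table = standard_normal_table(3.0, 0.7,
                                      extra_percentiles=[5, 30, 70, 95])
        dist = fit_characteristic_normal(table)
        report = assess_characteristic_fit(dist, table)
        assert report["max_discrepancy"] < 1e-10
        assert report["passed"]

    def test_beta_table_fitted_as_normal_fails_in_tails(self):
        # a strongly skewed bounded quantity: the Normal approximation must
        # overshoot in the tails beyond the 0.05 default tolerance
        percentiles = [2, 5, 10, 15.9, 30, 50.0, 70, 84.1, 95, 98]
        table = make_quantity_table("beta", {"a": 0.8, "b": 6.0, "scale": 4.0},
                                    percentiles)
        dist = fit_characteristic_normal(table)
        report = assess_characteristic_fit(dist, table)
        assert not report["passed"]
        # the failure concentrates in the tails, not near the median
        disc = dict(zip(report["held_out_percentiles"],
                        report["discrepancies"]))
        assert max(disc[2.0], disc[98.0]) > disc[70.0]

    def test_point_on_curve_has_zero_discrepancy(self):
        dist = fit_characteristic_normal(standard_normal_table(0.0, 1.0))
        extra_P = 70.0
        q = stats.norm.ppf(extra_P / 100)
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1, extra_P],
                              values=[-1.0, 0.0, 1.0, q])
        report = assess_characteristic_fit(dist, table)
        assert report["max_discrepancy"] == pytest.approx(0.0, abs=1e-14)

    def test_no_held_out_rows_rejected(self):
        table = standard_normal_table(0.0, 1.0)
        dist = fit_characteristic_normal(table)
        with pytest.raises(ValueError, match="held-out"):
            assess_characteristic_fit(dist, table)


class TestAlternativeFamilies:
    def test_half_cauchy_self_recovery(self):
        table = make_quantity_table("half_cauchy", {"loc": 2.0, "scale": 0.5},
                                    [5, 15.9, 30, 50, 70, 84.1, 95])
        dist = fit_alternative(table, "half_cauchy")
        assert dist.params["loc"] == pytest.approx(2.0, rel=1e-6)
        assert dist.params["scale"] == pytest.approx(0.5, rel=1e-6)

    def test_beta_self_recovery_with_known_support(self):
        table = make_quantity_table("beta", {"a": 2.0, "b": 5.0, "scale": 3.0},
                                    [5, 15.9, 30, 50, 70, 84.1, 95])
        dist = fit_alternative(table, "beta", support=(0.0, 3.0))
        assert dist.params["a"] == pytest.approx(2.0, rel=1e-4)
        assert dist.params["b"] == pytest.approx(5.0, rel=1e-4)

    def test_empirical_interpolates_tabulated_points_exactly(self):
        table = QuantityTable(percentiles=[10, 30, 50, 70, 90],
                              values=[1.0, 2.0, 4.0, 7.0, 11.0])
        dist = fit_alternative(table, "empirical")
        for P, Q in zip(table.percentiles, table.values):
            assert characteristic_quantile(dist, P / 100) == Q
            assert characteristic_cdf(dist, Q) == P / 100

    def test_empirical_cdf_is_nondecreasing(self):
        table = QuantityTable(percentiles=[10, 30, 50, 70, 90],
                              values=[1.0, 2.0, 2.0, 7.0, 11.0])
        dist = fit_alternative(table, "empirical")
        grid = np.linspace(0.0, 12.0, 200)
        assert np.all(np.diff(dist.cdf(grid)) >= 0)

    def test_three_row_beta_rejected(self):
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1],
                              values=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="rows"):
            fit_alternative(table, "beta", support=(0.0, 4.0))

    def test_nonmonotone_empirical_rejected(self):
        table = QuantityTable(percentiles=[10, 30, 50, 70],
                              values=[1.0, 3.0, 2.0, 4.0])
        with pytest.raises(MonotonicityError):
            fit_alternative(table, "empirical")


class TestMonotonicityGuard:
    def test_strictly_increasing_table_clean(self):
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1, 90],
                              values=[1.0, 2.0, 3.0, 4.0])
        report = check_monotonicity(table)
        assert report.monotone
        assert report.direction == "nondecreasing"
        assert report.band_escapes == []

    def test_median_outside_band_is_flagged(self):
        # Q(50) escapes the [Q(15.9), Q(84.1)] band — bound failure
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1],
                              values=[1.0, 5.0, 3.0])
        report = check_monotonicity(table)
        assert not report.monotone
        assert report.band_escapes == [50.0]

    def test_agrees_with_pairwise_scan_oracle(self, rng):
        values = rng.permutation([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        table = QuantityTable(percentiles=[10, 25, 40, 55, 70, 85],
                              values=values)
        report = check_monotonicity(table)
        increasing = all(values[i] <= values[j]
                         for i in range(6) for j in range(i + 1, 6))
        decreasing = all(values[i] >= values[j]
                         for i in range(6) for j in range(i + 1, 6))
        assert report.monotone == (increasing or decreasing)

    def test_too_few_rows_rejected(self):
        table = QuantityTable(percentiles=[10, 90], values=[1.0, 2.0])
        with pytest.raises(ValueError):
            check_monotonicity(table)


class TestQuantityTable:
    def test_csv_roundtrip(self, tmp_path):
        table = QuantityTable(percentiles=[15.9, 50.0, 84.1],
                              values=[0.1, 0.2, 0.3], quantity="vf")
        table.to_csv(tmp_path / "t.csv")
        back = QuantityTable.from_csv(tmp_path / "t.csv")
        np.testing.assert_array_equal(back.percentiles, table.percentiles)
        np.testing.assert_array_equal(back.values, table.values)

    def test_duplicate_percentiles_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            QuantityTable(percentiles=[50.0, 50.0], values=[1.0, 2.0])

    def test_rows_sorted_by_percentile(self):
        table = QuantityTable(percentiles=[84.1, 15.9, 50.0],
                              values=[3.0, 1.0, 2.0])
        np.testing.assert_array_equal(table.percentiles, [15.9, 50.0, 84.1])
        np.testing.assert_array_equal(table.values, [1.0, 2.0, 3.0])
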