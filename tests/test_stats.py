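"""Trial statistics: routed tests, effect sizes, chi-square, screening, power."""

import numpy as np
import pytest
from scipy import stats as sps

from capen.stats import (
    benjamini_hochberg,
    chi_square,
    cohens_d_pooled,
    paired_t_power,
    route_and_compare,
    screen_then_model,
    two_sample_t_power,
)

# Printed effect-size cells from the trial's report tables:
# (mean1, sd1, mean2, sd2, printed d)
PRINTED_D_CELLS = [
    # speech subtests, post vs baseline within arm
    (7.25, 3.02, 3.58, 4.17, 1.008),
    (10.50, 3.85, 4.88, 3.00, 1.628),
    (9.08, 4.03, 2.58, 3.45, 1.733),
    (6.00, 3.28, 1.00, 2.37, 1.747),
    (4.75, 2.70, 2.00, 3.05, 0.955),
    # speech subtest change scores between arms
    (5.63, 2.41, 1.21, 2.10, 1.955),
    (5.00, 3.10, 1.75, 1.91, 1.262),
    (3.92, 2.81, 1.42, 1.88, 1.046),
    (3.83, 3.30, 3.67, 2.96, 0.051),
    # connectivity difference values, post vs baseline within arm
    (0.12, 0.09, 0.03, 0.05, 1.236),
    (0.12, 0.08, 0.05, 0.04, 1.107),
    (0.04, 0.06, -0.01, 0.05, 0.905),
    (0.03, 0.05, -0.02, 0.05, 1.000),
    # connectivity change scores between arms
    (0.09, 0.10, 0.00, 0.06, 1.091),
    (0.06, 0.08, -0.01, 0.04, 1.107),
    (0.07, 0.08, 0.00, 0.06, 0.990),
    (0.05, 0.09, 0.00, 0.04, 0.718),
]


class TestCohensD:
    @pytest.mark.parametrize("m1,s1,m2,s2,expected", PRINTED_D_CELLS)
    def test_reproduces_printed_cells(self, m1, s1, m2, s2, expected):
        """Root-mean-variance pooling reproduces the published values."""
        assert cohens_d_pooled(m1, s1, m2, s2) == pytest.approx(expected, abs=1e-3)

    def test_zero_for_equal_means(self):
        assert cohens_d_pooled(2.0, 1.0, 2.0, 3.0) == 0.0

    def test_signed_option(self):
        assert cohens_d_pooled(1.0, 1.0, 2.0, 1.0, signed=True) == pytest.approx(-1.0)

    def test_both_zero_sds_error(self):
        with pytest.raises(ValueError, match="effect size undefined"):
            cohens_d_pooled(1.0, 0.0, 2.0, 0.0)


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, expected_p",
        [
            ([[10, 2], [9, 3]], 0.615),     # sex
            ([[2, 10], [1, 11]], 0.537),    # insula lesion
            ([[5, 5, 2], [6, 4, 2]], 0.904),  # severity grades
            ([[12, 0], [11, 1]], 0.307),    # etiology
            ([[6, 4, 2], [6, 4, 2]], 1.000),  # identical distributions
        ],
    )
    def test_reproduces_printed_p(self, table, expected_p):
        res = chi_square(table)
        assert res.p_value == pytest.approx(expected_p, abs=1e-3)

    def test_identical_rows_statistic_zero(self):
        res = chi_square([[6, 4, 2], [6, 4, 2]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_column_errors(self):
        with pytest.raises(ValueError, match="zero row or column"):
            chi_square([[5, 0], [3, 0]])

    def test_non_integer_errors(self):
        with pytest.raises(ValueError, match="integer"):
            chi_square([[1.5, 2], [3, 4]])


class TestRouting:
    def test_identical_paired_samples(self):
        res = route_and_compare([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], paired=True)
        assert res.p_value == 1.0
        assert res.effect_size == 0.0

    def test_separated_normals(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(5, 1, 12)
        res = route_and_compare(a, b)
        assert res.p_value < 1e-3
        assert res.test_name == "independent t-test"

    def test_skewed_data_routes_to_rank_test(self, rng):
        a = rng.exponential(1.0, 40) ** 3
        b = rng.exponential(1.0, 40) ** 3
        assert sps.shapiro(a).pvalue < 0.05  # routing premise
        res = route_and_compare(a, b)
        assert res.test_name == "Mann-Whitney U"

    def test_paired_routing_uses_differences(self, rng):
        base = rng.exponential(1.0, 30) ** 2  # skewed levels ...
        a = base + rng.normal(0.5, 0.1, 30)  # ... but normal differences
        res = route_and_compare(a, base, paired=True)
        assert res.test_name == "paired t-test"

    def test_rank_route_invariant_under_monotone_transform(self, rng):
        """When both versions route to the rank test, p is unchanged."""
        a = rng.exponential(1.0, 25) ** 3
        b = 2.0 * rng.exponential(1.0, 25) ** 3
        res_raw = route_and_compare(a, b)
        res_log = route_and_compare(np.log(a) ** 3, np.log(b) ** 3)
        assert res_raw.test_name == res_log.test_name == "Mann-Whitney U"
        assert res_raw.p_value == pytest.approx(res_log.p_value, abs=1e-12)

    def test_small_samples_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            route_and_compare([1, 2], [1, 2, 3])

    def test_all_tied_unpaired_handled(self):
        res = route_and_compare([1.0] * 6, [1.0] * 6)
        assert res.p_value == pytest.approx(1.0)


class TestPower:
    def test_reproduces_planning_value(self):
        """dz=1.0, n=11 at alpha 0.05 gives the published 0.924 (one-sided)."""
        assert paired_t_power(1.0, 11, 0.05, alternative="larger") == pytest.approx(
            0.924, abs=0.005
        )

    def test_null_limit_equals_alpha(self):
        assert paired_t_power(0.0, 11, 0.05) == pytest.approx(0.05, abs=1e-9)
        assert paired_t_power(0.0, 11, 0.05, "larger") == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_dz_and_n(self):
        grid = [paired_t_power(dz, 11) for dz in (0.2, 0.5, 1.0, 1.5)]
        assert all(a < b for a, b in zip(grid, grid[1:]))
        grid_n = [paired_t_power(1.0, n) for n in (5, 11, 20, 40)]
        assert all(a < b for a, b in zip(grid_n, grid_n[1:]))

    def test_against_monte_carlo(self):
        """Analytic power matches simulation of repeated paired t-tests."""
        n, dz = 30, 1.0
        rng = np.random.default_rng(3)
        diffs = rng.normal(dz, 1.0, size=(100_000, n))
        t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(n))
        crit = sps.t.ppf(0.975, n - 1)
        emp = np.mean(np.abs(t) > crit)
        assert paired_t_power(dz, n, 0.05) == pytest.approx(emp, abs=0.01)

    def test_invalid_domain(self):
        for bad in ({"dz": -1.0}, {"n": 1}, {"alpha": 0.0}):
            kw = {"dz": 1.0, "n": 11, "alpha": 0.05}
            kw.update(bad)
            with pytest.raises(ValueError):
                paired_t_power(**kw)

    def test_two_sample_reference_point(self):
        assert two_sample_t_power(1.0, 12) == pytest.approx(0.649, abs=0.005)


class TestScreening:
    @staticmethod
    def _frame(rng, n=24, k=4, signal=None):
        import pandas as pd

        data = {f"x{i}": rng.standard_normal(n) for i in range(k)}
        data["group"] = np.repeat([0.0, 1.0], n // 2)
        y = rng.standard_normal(n)
        if signal is not None:
            y = y + signal * data["group"]
        data["y"] = y
        return pd.DataFrame(data)

    def test_exact_linear_relationship(self, rng):
        import pandas as pd

        x = rng.standard_normal(24)
        df = pd.DataFrame({"x0": x, "y": 2.0 * x + 1.0})
        uni, _ = screen_then_model(df, "y", ["x0"])
        assert uni.table.loc["x0", "R2"] == pytest.approx(1.0, abs=1e-10)
        assert uni.table.loc["x0", "B"] == pytest.approx(2.0, abs=1e-8)

    def test_group_term_always_retained(self, rng):
        df = self._frame(rng)
        _, multi = screen_then_model(df, "y", [f"x{i}" for i in range(4)], group="group")
        assert "group" in multi.table.index

    def test_standardized_coefficients_bounded(self, rng):
        df = self._frame(rng, signal=2.0)
        uni, multi = screen_then_model(df, "y", [f"x{i}" for i in range(4)], group="group")
        assert (multi.table["b"].abs() <= 1.5).all()
        assert 0.0 <= multi.r_squared <= 1.0

    def test_group_effect_detected(self, rng):
        df = self._frame(rng, signal=3.0)
        _, multi = screen_then_model(df, "y", [f"x{i}" for i in range(4)], group="group")
        assert multi.table.loc["group", "p"] < 0.01

    def test_collinear_retained_set_errors(self, rng):
        import pandas as pd

        x = rng.standard_normal(24)
        y = x + rng.normal(0, 0.1, 24)
        df = pd.DataFrame({"a": x, "b": 2.0 * x, "y": y})
        with pytest.raises(ValueError, match="collinear"):
            screen_then_model(df, "y", ["a", "b"])

    def test_retention_frequency_near_screening_level(self):
        """Pure-noise candidates are retained at close to the p<0.2 rate."""
        rng = np.random.default_rng(77)
        n_rep = 400
        kept = 0
        crit = sps.t.ppf(0.9, 22)  # two-tailed p<0.2 for simple OLS, df=22
        for _ in range(n_rep):
            x = rng.standard_normal(24)
            y = rng.standard_normal(24)
            r = np.corrcoef(x, y)[0, 1]
            t = r * np.sqrt(22 / (1 - r * r))
            kept += abs(t) > crit
        freq = kept / n_rep
        assert 0.2 - 3 * np.sqrt(0.2 * 0.8 / n_rep) < freq < 0.2 + 3 * np.sqrt(0.2 * 0.8 / n_rep)


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8, np.nan]
    adj = benjamini_hochberg(p)
    assert np.isnan(adj[4])
    assert (adj[:4] >= np.array(p[:4]) - 1e-12).all()
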