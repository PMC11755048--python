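"""Cohort FF analytics: summaries, group comparisons, GA trend, weight
regression and inverse prediction."""

import math

import numpy as np
import pandas as pd
import pytest

from niptsim import (
    CohortParams,
    ConfigurationError,
    FFLaw,
    FFLawStratum,
    SampleRecord,
    TruncNormal,
    compare_low_ff_group,
    ga_trend,
    generate_cohort,
    generate_nonpregnant_cohort,
    nonpregnant_correlations,
    summarize_ff,
    weight_at_ff,
    weight_ff_regression,
)
from niptsim.cohort import RegressionFit


def rec(ff, ga=16.0, age=30.0, weight=56.0, sid="s"):
    return SampleRecord(
        sample_id=sid,
        ff=ff,
        gestational_age_weeks=ga,
        maternal_age_years=age,
        maternal_weight_kg=weight,
    )


class TestSummarizeFF:
    def test_hand_counted_summary(self):
        s = summarize_ff([rec(0.03), rec(0.11), rec(0.12)], threshold=0.05)
        assert s.median_ff_pct == pytest.approx(11.0)
        assert s.n_below == 1
        assert s.pct_below == pytest.approx(100.0 / 3.0)

    def test_printed_count_arithmetic(self):
        # the share corresponding to 214 low-FF samples out of 4827
        assert round(100.0 * 214 / 4827, 2) == 4.43

    def test_all_above_threshold(self):
        s = summarize_ff([rec(0.10), rec(0.12)], threshold=0.05)
        assert s.pct_below == 0.0

    def test_percentage_is_integer_exact(self):
        records = [rec(0.01)] * 3 + [rec(0.2)] * 13
        s = summarize_ff(records)
        assert s.pct_below == 100.0 * 3 / 16

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize_ff([])


class TestCompareLowFF:
    def test_identical_groups_give_t0_p1(self):
        records = [
            rec(0.030, ga=15, age=28, weight=60),
            rec(0.040, ga=17, age=32, weight=70),
            rec(0.100, ga=15, age=28, weight=60),
            rec(0.105, ga=17, age=32, weight=70),
            rec(0.200, ga=16, age=30, weight=65),
        ]
        # median is 0.10; near-median group = {0.100, 0.105} matches the
        # low-FF group {0.030, 0.040} covariate-for-covariate
        for comparison in compare_low_ff_group(records):
            assert comparison.t_statistic == pytest.approx(0.0, abs=1e-12)
            assert comparison.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_weight_effect_significant_at_scale(self, seed):
        records = generate_cohort(CohortParams(n_samples=4827, seed=seed))
        by_var = {c.variable: c for c in compare_low_ff_group(records)}
        weight = by_var["maternal_weight"]
        assert weight.mean_low_ff > weight.mean_near_median
        assert weight.p_value < 0.0001
        assert weight.significance_mark == "****"

    def test_ga_p_values_uniform_under_null(self):
        # single-stratum law: GA does not enter the FF model at all
        law = FFLaw(strata=(FFLawStratum(0.0, math.inf, 16.52, -0.12),))
        p_values = []
        for seed in range(200):
            records = generate_cohort(
                CohortParams(n_samples=400, seed=seed, ff_law=law)
            )
            by_var = {c.variable: c for c in compare_low_ff_group(records)}
            p_values.append(by_var["gestational_age"].p_value)
        from scipy.stats import kstest

        assert kstest(p_values, "uniform").pvalue > 0.01

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_low_ff_group([rec(0.03), rec(0.10), rec(0.11)])


class TestGATrend:
    def test_recovers_piecewise_shape(self):
        # default law: flat 12-19, slight dip 20-22, strong rise >= 23
        params = CohortParams(
            n_samples=6000, seed=3, ga_law=TruncNormal(19.0, 5.0, 12.0, 32.0)
        )
        trend = ga_trend(generate_cohort(params))
        means = trend["mean_ff_pct"].tolist()
        assert means[1] < means[0] < means[2]

    def test_single_week_cohort_fills_one_bin(self):
        trend = ga_trend([rec(0.1, ga=15.0)] * 5, week_edges=(12, 20, 23, math.inf))
        assert trend["n"].tolist() == [5, 0, 0]
        assert math.isnan(trend["mean_ff_pct"].iloc[1])

    def test_half_open_bins_partition_samples(self):
        records = [rec(0.1, ga=g) for g in (12.0, 19.99, 20.0, 22.99, 23.0, 30.0)]
        trend = ga_trend(records, week_edges=(12, 20, 23, math.inf))
        assert trend["n"].tolist() == [2, 2, 2]
        assert trend["n"].sum() == len(records)


class TestWeightRegression:
    def test_noise_free_line_fits_exactly(self):
        records = [
            rec(ff=(16.52 - 0.12 * w) / 100.0, weight=w) for w in (50, 60, 70, 80)
        ]
        fit = weight_ff_regression(records, stratum=(12, 20))
        assert fit.slope_pct_per_kg == pytest.approx(-0.12, rel=1e-9)
        assert fit.intercept_pct == pytest.approx(16.52, rel=1e-9)
        assert fit.pearson_r == pytest.approx(-1.0)

    def test_slope_recovery_within_10pct(self):
        # per-seed OLS slope SE at n = 2000 is ~7.5% relative (3% residual SD,
        # ~8 kg weight spread), so recovery is judged on the median over seeds
        slopes = []
        for seed in range(10):
            records = generate_cohort(CohortParams(n_samples=2000, seed=seed + 100))
            fit = weight_ff_regression(records, stratum=(12, 20))
            slopes.append(fit.slope_pct_per_kg)
        assert all(s < 0 for s in slopes)
        assert np.median(slopes) == pytest.approx(-0.12, rel=0.10)

    def test_r_sign_matches_slope_sign(self):
        rng = np.random.default_rng(0)
        for sign in (+1, -1):
            w = rng.uniform(40, 90, 50)
            ffs = np.clip((10 + sign * 0.1 * w + rng.normal(0, 1, 50)) / 100, 0, 0.5)
            records = [rec(ff=f, weight=x) for f, x in zip(ffs, w)]
            fit = weight_ff_regression(records, stratum=(12, 20))
            assert np.sign(fit.pearson_r) == np.sign(fit.slope_pct_per_kg)

    def test_constant_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            weight_ff_regression([rec(0.1), rec(0.2), rec(0.3)], stratum=(12, 20))


class TestWeightAtFF:
    def fit(self, intercept, slope, wmin=45.0, wmax=90.0):
        return RegressionFit(
            ga_lo_weeks=12,
            ga_hi_weeks=20,
            intercept_pct=intercept,
            slope_pct_per_kg=slope,
            pearson_r=-0.5 if slope < 0 else 0.5,
            p_value=0.001,
            n=100,
            residual_sd_pct=3.0,
            weight_min_kg=wmin,
            weight_max_kg=wmax,
        )

    def test_hand_inverse_prediction(self):
        with pytest.warns(UserWarning, match="extrapolation"):
            w = weight_at_ff(self.fit(16.52, -0.12), target_ff=0.05)
        assert w == pytest.approx(96.0, rel=1e-9)

    def test_target_at_intercept_gives_zero_weight(self):
        with pytest.warns(UserWarning, match="extrapolation"):
            assert weight_at_ff(self.fit(5.0, -0.12), target_ff=0.05) == 0.0

    def test_positive_slope_flagged(self):
        with pytest.warns(UserWarning, match="positive"):
            weight_at_ff(self.fit(2.0, 0.05, wmin=0.0, wmax=100.0), target_ff=0.05)

    def test_zero_slope_rejected(self):
        with pytest.raises(ConfigurationError):
            weight_at_ff(self.fit(16.52, 0.0))

    def test_crossing_recovered_within_2kg(self):
        from niptsim.reproduce import crossing_weight_recovery

        estimate = crossing_weight_recovery(seed=202, n_seeds=20)
        assert estimate == pytest.approx(96.0, abs=2.0)


class TestNonpregnant:
    def test_perfectly_anticorrelated_pair(self):
        frame = pd.DataFrame(
            {"cfdna_ng_ml": [3.0, 2.0, 1.0], "age_years": [20.0, 30.0, 40.0]}
        )
        out = nonpregnant_correlations(frame, covariates=["age_years"])
        assert out["pearson_r"].iloc[0] == pytest.approx(-1.0)

    def test_age_effect_recovered_in_most_seeds(self):
        negative = sum(
            nonpregnant_correlations(generate_nonpregnant_cohort(71, seed=s))
            .set_index("covariate")["pearson_r"]["age_years"]
            < 0
            for s in range(100)
        )
        assert negative >= 80

    def test_independent_covariate_has_small_r(self):
        small = sum(
            abs(
                nonpregnant_correlations(generate_nonpregnant_cohort(71, seed=s))
                .set_index("covariate")["pearson_r"]["height_cm"]
            )
            < 0.25
            for s in range(100)
        )
        assert small >= 95

    def test_constant_covariate_skipped_with_warning(self):
        frame = generate_nonpregnant_cohort(20, seed=1)
        frame["height_cm"] = 160.0
        with pytest.warns(UserWarning, match="height_cm"):
            out = nonpregnant_correlations(frame)
        assert "height_cm" not in set(out["covariate"])


class TestAgainstStatsOracle:
    """Textbook-formula checks via statsmodels on random datasets."""

    @pytest.mark.parametrize("seed", range(5))
    def test_regression_matches_statsmodels(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        w = rng.uniform(40, 100, 200)
        ffs = np.clip((17 - 0.1 * w + rng.normal(0, 2, 200)) / 100, 0.001, 0.5)
        records = [rec(ff=f, weight=x) for f, x in zip(ffs, w)]
        fit = weight_ff_regression(records, stratum=(12, 20))
        oracle = sm.OLS(ffs * 100, sm.add_constant(w)).fit()
        assert fit.intercept_pct == pytest.approx(oracle.params[0], rel=1e-9)
        assert fit.slope_pct_per_kg == pytest.approx(oracle.params[1], rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_t_test_matches_statsmodels(self, seed):
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        rng = np.random.default_rng(seed + 50)
        low = [rec(0.03, weight=w, ga=16) for w in rng.normal(70, 8, 30)]
        near = [rec(0.10 + i * 1e-4, weight=w, ga=16) for i, w in enumerate(rng.normal(60, 8, 40))]
        records = low + near + [rec(0.30, weight=60.0)]
        comparison = {
            c.variable: c for c in compare_low_ff_group(records)
        }["maternal_weight"]
        t, p, _ = sm_ttest(
            [r.maternal_weight_kg for r in low],
            [r.maternal_weight_kg for r in near],
            usevar="unequal",
        )
        assert comparison.t_statistic == pytest.approx(t, rel=1e-9)
        assert comparison.p_value == pytest.approx(p, rel=1e-6)
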