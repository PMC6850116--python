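"""Statistical core: exact CIs, the detection rule, calibration, concordance."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddmosaic import (
    AlleleCounts,
    DropletCounts,
    MAFEstimate,
    binomial_ci,
    classify_sample,
    concordance,
    detection_limit_curve,
    estimate_maf,
    pool_error_rate,
)
from ddmosaic.errors import EstimationError, ParameterError

from _oracles import cp_bounds_bisect, ols_r_squared


class TestBinomialCI:
    def test_zero_count_lower_bound_is_exactly_zero(self):
        lo, hi = binomial_ci(0, 1000)
        assert lo == 0.0
        assert 0.0 < hi < 1.0

    def test_zero_count_upper_matches_closed_form(self):
        # P(X = 0 | p) = (1-p)^n = alpha/2  =>  upper = 1 - (alpha/2)^(1/n)
        _, hi = binomial_ci(0, 30000)
        assert hi == pytest.approx(1.0 - 0.025 ** (1.0 / 30000), abs=1e-12)

    def test_full_count_upper_bound_is_exactly_one(self):
        lo, hi = binomial_ci(50, 50)
        assert hi == 1.0
        assert lo > 0.0

    @pytest.mark.parametrize("k,n", [(5, 10000), (50, 10000), (1, 50), (250, 500)])
    def test_matches_tail_inversion_oracle(self, k, n):
        lo, hi = binomial_ci(k, n)
        olo, ohi = cp_bounds_bisect(k, n)
        assert lo == pytest.approx(float(olo[0]), abs=1e-9)
        assert hi == pytest.approx(float(ohi[0]), abs=1e-9)

    @pytest.mark.parametrize("bad", [(-1, 10), (11, 10)])
    def test_out_of_range_k_rejected(self, bad):
        with pytest.raises(ParameterError):
            binomial_ci(*bad)

    def test_zero_n_rejected(self):
        with pytest.raises(ParameterError):
            binomial_ci(0, 0)

    @given(st.integers(0, 400), st.integers(1, 400), st.sampled_from([0.01, 0.05, 0.1]))
    def test_bounds_bracket_point_estimate(self, k, n, alpha):
        k = min(k, n)
        lo, hi = binomial_ci(k, n, alpha)
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_upper_bound_decreasing_in_n_at_zero_count(self):
        uppers = [binomial_ci(0, n)[1] for n in (100, 1000, 10000, 100000)]
        assert all(b < a for a, b in zip(uppers, uppers[1:]))


class TestEstimateMAF:
    def test_zero_mutants_give_zero_maf(self):
        est = estimate_maf(DropletCounts(mu=0, wt=10000, na=40000))
        assert est.maf == 0.0 and est.ci_low == 0.0
        assert est.n == 10000  # NA droplets excluded from the denominator

    def test_low_fraction_counts_match_oracle(self):
        est = estimate_maf(DropletCounts(mu=50, wt=9950))
        assert est.maf == pytest.approx(0.005)
        olo, ohi = cp_bounds_bisect(50, 10000)
        assert est.ci_low == pytest.approx(float(olo[0]), abs=1e-9)
        assert est.ci_high == pytest.approx(float(ohi[0]), abs=1e-9)

    def test_amplicon_counts_reproduce_published_point_value(self):
        # 3250 alt / 10000 reads reproduces a published deep-amplicon
        # estimate of 32.5%
        est = estimate_maf(AlleleCounts(alt_reads=3250, ref_reads=6750))
        assert est.maf == pytest.approx(0.325)
        assert est.platform == "PASM"

    def test_zero_informative_is_an_error_not_zero(self):
        with pytest.raises(EstimationError):
            estimate_maf(DropletCounts(mu=0, wt=0, na=1000))


class TestDetectionRule:
    @pytest.mark.parametrize(
        "pcts,expected",
        [
            ((18.82, 18.51, 19.14), "mosaic"),
            ((49.98, 49.60, 50.35), "het_consistent"),
            ((0.01, 0.00, 0.03), "negative"),
            ((0.02, 0.01, 0.04), "negative"),  # lower bound == cutoff: strict
            ((0.03, 0.03, 0.04), "mosaic"),
        ],
    )
    def test_rule_on_printed_bounds(self, pcts, expected):
        est = MAFEstimate.from_percent(*pcts)
        assert classify_sample(est).call == expected

    def test_call_is_pure_function_of_bounds(self):
        a = classify_sample(MAFEstimate.from_percent(7.53, 7.33, 7.74))
        b = classify_sample(MAFEstimate(maf=0.0753, ci_low=0.0733, ci_high=0.0774))
        assert a.call == b.call == "mosaic"

    @given(st.integers(1, 200000))
    def test_zero_count_never_called_mosaic(self, n):
        est = estimate_maf(DropletCounts(mu=0, wt=n))
        assert classify_sample(est).call != "mosaic"

    def test_rule_inputs_recorded(self):
        sc = classify_sample(MAFEstimate.from_percent(1.0, 0.9, 1.1))
        assert sc.rule_inputs["lower_cut"] == pytest.approx(1e-4)
        assert sc.rule_inputs["upper_cut"] == pytest.approx(0.5)


class TestErrorRatePooling:
    def test_clean_control_gives_zero_rate(self):
        est = pool_error_rate([DropletCounts(mu=0, wt=50000)])
        assert est.pooled_rate == 0.0 and est.ci[0] == 0.0

    def test_single_event_arithmetic(self):
        est = pool_error_rate([DropletCounts(mu=1, wt=49999)])
        assert est.pooled_rate == pytest.approx(2e-5)
        assert est.total_informative == 50000

    def test_pooling_sums_across_controls(self):
        est = pool_error_rate(
            [DropletCounts(mu=1, wt=9999), DropletCounts(mu=2, wt=9998)]
        )
        assert est.total_mu == 3
        assert est.pooled_rate == pytest.approx(3 / 20000)

    def test_empty_or_degenerate_rejected(self):
        with pytest.raises(ParameterError):
            pool_error_rate([])
        with pytest.raises(ParameterError):
            pool_error_rate([DropletCounts(mu=0, wt=0, na=10)])


class TestDetectionLimitCurve:
    def test_zero_rate_matches_closed_form(self):
        curve = detection_limit_curve(0.0, [10000])
        row = curve.table.iloc[0]
        assert row["expected_k"] == 0
        assert row["upper_bound"] == pytest.approx(1 - 0.025 ** (1 / 10000), abs=1e-12)

    def test_upper_bound_non_increasing_at_zero_rate(self):
        curve = detection_limit_curve(0.0, [1000, 10000, 100000, 1000000])
        ub = curve.table["upper_bound"].to_numpy()
        assert np.all(np.diff(ub) <= 0)

    def test_empirical_rate_curve_against_oracle(self):
        rate = 2.15664e-05
        grid = [10**3, 10**4, 10**5, 10**6]
        curve = detection_limit_curve(rate, grid)
        for _, row in curve.table.iterrows():
            n, ek = int(row["n"]), int(row["expected_k"])
            assert ek == round(rate * n)
            _, ohi = cp_bounds_bisect(ek, n)
            assert row["upper_bound"] == pytest.approx(float(ohi[0]), abs=1e-9)
        # the cutoff crossing reported by the curve is where the bound first
        # drops under 0.01%
        assert curve.min_n_below_cutoff == next(
            int(r["n"]) for _, r in curve.table.iterrows() if r["below_cutoff"]
        )

    def test_grid_must_increase(self):
        with pytest.raises(ParameterError):
            detection_limit_curve(0.0, [100, 100])


class TestConcordance:
    def test_identity_line(self):
        stats = concordance([(0.1, 0.1), (0.2, 0.2), (0.3, 0.3)])
        assert stats.r_squared == pytest.approx(1.0)
        assert stats.slope == pytest.approx(1.0)
        assert stats.intercept == pytest.approx(0.0, abs=1e-12)

    def test_two_points_fit_perfectly(self):
        stats = concordance([(0.0, 0.1), (0.5, 0.2)])
        assert stats.r_squared == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 0.5, 25)
        y = 0.9 * x + rng.normal(0, 0.02, 25)
        stats = concordance(list(zip(x, y)))
        r2, slope, intercept = ols_r_squared(x, y)
        assert stats.r_squared == pytest.approx(r2, abs=1e-12)
        assert stats.slope == pytest.approx(slope, abs=1e-12)
        assert stats.intercept == pytest.approx(intercept, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            concordance([(0.1, 0.2)])
        with pytest.raises(ParameterError):
            concordance([(0.1, 0.2), (0.1, 0.3)])


class TestCoverageAndOperatingCharacteristics:
    """Simulation checks of the rule's statistical behaviour."""

    def test_exact_interval_coverage_is_conservative(self, rng):
        n = 20000
        for p in (0.0005, 0.005, 0.05, 0.5):
            ks = rng.binomial(n, p, size=1000)
            uniq = np.unique(ks)
            lo, hi = binomial_ci(uniq, n)
            covered = {k: (l <= p <= h) for k, l, h in zip(uniq, lo, hi)}
            coverage = np.mean([covered[k] for k in ks])
            assert 0.93 <= coverage <= 0.98, (p, coverage)

    def test_power_at_five_percent_maf(self, rng):
        n, fcr = 20000, 2.15664e-05
        p = 0.05 + 0.95 * fcr
        ks = rng.binomial(n, p, size=500)
        uniq = np.unique(ks)
        lo, hi = binomial_ci(uniq, n)
        call = {
            k: classify_sample(MAFEstimate(k / n, l, h)).call
            for k, l, h in zip(uniq, lo, hi)
        }
        frac_mosaic = np.mean([call[k] == "mosaic" for k in ks])
        assert frac_mosaic >= 0.99

    def test_specificity_at_zero_maf(self, rng):
        n, fcr = 20000, 2.15664e-05
        ks = rng.binomial(n, fcr, size=500)
        uniq = np.unique(ks)
        lo, hi = binomial_ci(uniq, n)
        call = {
            k: classify_sample(MAFEstimate(k / n, l, h)).call
            for k, l, h in zip(uniq, lo, hi)
        }
        frac_mosaic = np.mean([call[k] == "mosaic" for k in ks])
        assert frac_mosaic <= 0.05

    def test_heterozygote_rarely_called_negative(self, rng):
        n = 50000
        ks = rng.binomial(n, 0.5, size=300)
        uniq = np.unique(ks)
        lo, hi = binomial_ci(uniq, n)
        call = {
            k: classify_sample(MAFEstimate(k / n, l, h)).call
            for k, l, h in zip(uniq, lo, hi)
        }
        calls = np.array([call[k] for k in ks])
        assert np.mean(calls == "negative") <= 0.10
        assert np.mean(calls == "het_consistent") >= 0.90
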