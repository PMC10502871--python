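"""The core penetrance estimator: exact binomial CIs, log-scale delta-method
moments, the Bayes-ratio point estimate and its confidence interval."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penetrax import (CountPair, DegeneracyError, PrevalenceEstimate,
                      ValidationError, aggregate_penetrance, binom_ci_exact,
                      estimate_penetrance, log_prop_moments)
from penetrax.estimator import degeneracy_adjust, penetrance_ci_array
from penetrax.prevalence import z_from_level


@pytest.fixture(scope="module")
def prev():
    return PrevalenceEstimate.from_ci(0.0018, 0.0015, 0.0023)


class TestBinomCiExact:
    def test_lvh_concordance_interval(self):
        """4 of 37 genotype-positive individuals with hypertrophy gives the
        3.0%-25.4% exact interval."""
        lo, hi = binom_ci_exact(4, 37)
        assert round(lo, 3) == 0.030
        assert round(hi, 3) == 0.254

    def test_vus_concordance_upper_bound(self):
        lo, hi = binom_ci_exact(2, 353)
        assert round(hi, 4) == 0.0203

    def test_boundaries(self):
        assert binom_ci_exact(0, 100)[0] == 0.0
        assert binom_ci_exact(100, 100)[1] == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            binom_ci_exact(0, 0)


class TestLogPropMoments:
    def test_variance_closed_form_at_half(self):
        n = 1000
        _, var = log_prop_moments(n / 2, n)
        assert var == pytest.approx(1 / n)

    def test_z_interval_close_to_clopper_pearson(self):
        """At x=100, n=1e6 the exponentiated normal interval agrees with the
        exact interval within 2% relative on both ends."""
        x, n = 100, 10**6
        mean, var = log_prop_moments(x, n)
        z = z_from_level(0.95)
        lo = math.exp(mean - z * math.sqrt(var))
        hi = math.exp(mean + z * math.sqrt(var))
        cp_lo, cp_hi = binom_ci_exact(x, n)
        assert lo == pytest.approx(cp_lo, rel=0.02)
        assert hi == pytest.approx(cp_hi, rel=0.02)

    def test_bias_correction_improves_log_mean(self):
        """Monte Carlo at p=0.001, n=1e5: the corrected log estimate is less
        biased for ln p than the raw log proportion."""
        rng = np.random.default_rng(11)
        p, n, reps = 0.001, 10**5, 100_000
        x = rng.binomial(n, p, size=reps)
        x = x[x > 0]
        raw = np.log(x / n)
        corrected = raw + (1 - x / n) / (2 * x)
        truth = math.log(p)
        assert abs(corrected.mean() - truth) < abs(raw.mean() - truth)

    def test_zero_count_degenerate(self):
        with pytest.raises(DegeneracyError):
            log_prop_moments(0, 100)


class TestDegeneracyPolicy:
    def test_adjustment_only_for_sparse_counts(self):
        assert degeneracy_adjust(1, 100) == (1.5, 101)
        assert degeneracy_adjust(2, 100) == (2.5, 101)
        assert degeneracy_adjust(3, 100) == (3, 100)
        assert degeneracy_adjust(84.1, 46722.4) == (84.1, 46722.4)

    def test_population_zero_never_estimated(self, prev):
        with pytest.raises(DegeneracyError):
            estimate_penetrance(prev, CountPair(3, 1000), CountPair(0, 10**6))

    def test_population_singleton_flagged_unreliable(self, prev):
        est = estimate_penetrance(prev, CountPair(3, 20_800),
                                  CountPair(1, 586_452))
        assert not est.reliable

    def test_case_zero_is_domain_error(self, prev):
        with pytest.raises(ValidationError):
            estimate_penetrance(prev, CountPair(0, 1000), CountPair(5, 10**6))


class TestEstimatePenetrance:
    def test_splice_variant_rounds_to_one_percent(self, prev):
        """Case 4/20,800 vs population 20/586,452 at 0.18% prevalence."""
        est = estimate_penetrance(prev, CountPair(4, 20_800),
                                  CountPair(20, 586_452))
        assert est.as_percent()[0] == 1.0
        assert est.reliable and not est.clamped

    def test_afr_missense_rounds_to_0_6_percent(self, prev):
        est = estimate_penetrance(prev, CountPair(5, 984),
                                  CountPair(33, 21_310))
        assert est.as_percent()[0] == 0.6

    def test_equal_frequencies_give_prevalence_exactly(self, prev):
        est = estimate_penetrance(prev, CountPair(50, 10_000),
                                  CountPair(500, 100_000))
        assert est.point == pytest.approx(prev.p)

    def test_huge_ratio_clamps_at_one(self, prev):
        est = estimate_penetrance(prev, CountPair(400, 1000),
                                  CountPair(2, 10**7))
        assert est.point == 1.0
        assert est.clamped
        assert est.ci_low <= 1.0 == est.ci_high

    def test_components_recorded(self, prev):
        est = estimate_penetrance(prev, CountPair(4, 20_800),
                                  CountPair(20, 586_452))
        assert est.components == ((prev.x_eff, prev.n_eff),
                                  (4, 20_800), (20, 586_452))

    @settings(derandomize=True, max_examples=100)
    @given(delta=st.integers(min_value=1, max_value=50))
    def test_monotone_in_case_count(self, prev, delta):
        base = estimate_penetrance(prev, CountPair(20, 100_000),
                                   CountPair(40, 10**6))
        more = estimate_penetrance(prev, CountPair(20 + delta, 100_000),
                                   CountPair(40, 10**6))
        assert more.point > base.point

    @settings(derandomize=True, max_examples=100)
    @given(delta=st.integers(min_value=1, max_value=50))
    def test_monotone_decreasing_in_pop_count(self, prev, delta):
        base = estimate_penetrance(prev, CountPair(20, 100_000),
                                   CountPair(40, 10**6))
        more = estimate_penetrance(prev, CountPair(20, 100_000),
                                   CountPair(40 + delta, 10**6))
        assert more.point < base.point

    def test_monotone_in_prevalence(self):
        lo = PrevalenceEstimate.from_ci(0.0010, 0.0008, 0.0013)
        hi = PrevalenceEstimate.from_ci(0.0020, 0.0016, 0.0026)
        case, pop = CountPair(20, 100_000), CountPair(40, 10**6)
        assert (estimate_penetrance(hi, case, pop).point
                > estimate_penetrance(lo, case, pop).point)

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_population_scale_invariance(self, prev, k):
        """Scaling population ac and an together leaves the point unchanged
        and narrows the CI (more information, same frequency)."""
        base = estimate_penetrance(prev, CountPair(20, 100_000),
                                   CountPair(40, 10**6))
        scaled = estimate_penetrance(prev, CountPair(20, 100_000),
                                     CountPair(40 * k, k * 10**6))
        assert scaled.point == pytest.approx(base.point)
        assert scaled.width < base.width

    def test_clopper_pearson_oracle_with_known_prevalence_and_pop_af(self):
        """When prevalence and population AF carry effectively no
        uncertainty, the CI converges to prev.p/popAF times the exact
        binomial interval of the case proportion (within 5% relative)."""
        sharp_prev = PrevalenceEstimate.from_counts(1.8e6, 1e9)
        case = CountPair(60, 50_000)
        pop = CountPair(10**6, 10**10)
        est = estimate_penetrance(sharp_prev, case, pop)
        cp_lo, cp_hi = binom_ci_exact(case.ac, case.an)
        factor = sharp_prev.p / pop.af
        assert est.ci_low == pytest.approx(factor * cp_lo, rel=0.05)
        assert est.ci_high == pytest.approx(factor * cp_hi, rel=0.05)


class TestAggregate:
    def test_single_variant_identity(self, prev, make_record):
        rec = make_record()
        est = aggregate_penetrance(prev, [rec], 20_800, 586_452)
        direct = estimate_penetrance(prev, rec.case_counts, rec.pop_counts)
        assert est.point == direct.point
        assert (est.ci_low, est.ci_high) == (direct.ci_low, direct.ci_high)

    def test_pooled_counts_are_additive(self, prev, make_record):
        a = [make_record(variant_id=f"a{i}", case_ac=3, pop_ac=8)
             for i in range(3)]
        b = [make_record(variant_id=f"b{i}", case_ac=2, pop_ac=5)
             for i in range(2)]
        est = aggregate_penetrance(prev, a + b, 20_800, 586_452)
        assert est.components[1][0] == 3 * 3 + 2 * 2
        assert est.components[2][0] == 3 * 8 + 2 * 5

    def test_mixed_diseases_rejected(self, prev, make_record):
        hcm = make_record(variant_id="h")
        dcm = make_record(variant_id="d", gene="TTN", disease="DCM")
        with pytest.raises(ValidationError, match="mixed"):
            aggregate_penetrance(prev, [hcm, dcm], 20_800, 586_452)

    def test_empty_list_rejected(self, prev):
        with pytest.raises(ValidationError):
            aggregate_penetrance(prev, [], 100, 100)

    def test_aggregate_ci_recovers_known_truth(self, prev):
        """A synthetic variant set with true aggregate penetrance 0.20 is
        recovered inside the 95% CI in at least 93% of 500 replicates."""
        rng = np.random.default_rng(20)
        true_pen, pop_af, n_var = 0.20, 2e-5, 50
        case_an, pop_an = 20_000, 600_000
        case_af = true_pen * pop_af / prev.p
        reps = 500
        ca = rng.binomial(case_an, case_af, size=(reps, n_var)).sum(axis=1)
        pa = rng.binomial(pop_an, pop_af, size=(reps, n_var)).sum(axis=1)
        _, lo, hi = penetrance_ci_array(
            prev, ca, np.full(reps, case_an), pa, np.full(reps, pop_an))
        inside = (lo <= true_pen) & (true_pen <= hi)
        assert np.nanmean(inside) >= 0.93


class TestVectorisedPath:
    def test_agrees_with_scalar_estimates(self, prev):
        cases = [(4, 20_800, 20, 586_452), (5, 984, 33, 21_310),
                 (2, 20_800, 2, 586_452), (100, 20_800, 60, 586_452)]
        ca, can, pa, pan = (np.array(v) for v in zip(*cases))
        point, lo, hi = penetrance_ci_array(prev, ca, can, pa, pan)
        for i, (x1, n1, x2, n2) in enumerate(cases):
            est = estimate_penetrance(prev, CountPair(x1, n1),
                                      CountPair(x2, n2))
            assert point[i] == pytest.approx(est.point)
            assert lo[i] == pytest.approx(est.ci_low)
            assert hi[i] == pytest.approx(est.ci_high)

    def test_degenerate_entries_are_nan(self, prev):
        point, lo, hi = penetrance_ci_array(
            prev, np.array([0, 3]), np.array([100, 100]),
            np.array([5, 0]), np.array([1000, 1000]))
        assert np.isnan(point[0]) and np.isnan(point[1])
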