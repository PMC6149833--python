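"""Score intervals, MOVER ratio intervals, and the hierarchical gate."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from serotrial import (
    LogStats,
    NIConfig,
    NoninferiorityResult,
    assess_hierarchy,
    gmc_ratio_ci_mover,
    gmc_ratio_point,
    newcombe_hybrid_ci,
    rate_difference_ci,
)


def _oracle_score_ci(x1, n1, x2, n2, level=0.95):
    """Independent score-interval inversion.

    The restricted MLE under p1 - p2 = d is found by numeric likelihood
    maximisation (no closed form), and the bounds by root search on the
    corrected score statistic — an implementation path disjoint from the
    package's cubic solution.
    """
    z = stats.norm.ppf(1 - (1 - level) / 2)
    p1h, p2h = x1 / n1, x2 / n2

    def zstat(d):
        lo, hi = max(0.0, d) + 1e-12, min(1.0, 1.0 + d) - 1e-12
        if hi <= lo:  # |d| ~ 1: the restricted parameter space is a point
            lo = hi = (max(0.0, d) + min(1.0, 1.0 + d)) / 2

        def nll(p1):
            p2 = p1 - d
            eps = 1e-300
            return -(
                x1 * math.log(max(p1, eps))
                + (n1 - x1) * math.log(max(1 - p1, eps))
                + x2 * math.log(max(p2, eps))
                + (n2 - x2) * math.log(max(1 - p2, eps))
            )

        if hi > lo:
            res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                           options={"xatol": 1e-13})
            p1 = res.x
        else:
            p1 = lo
        p2 = p1 - d
        var = (p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2) * (n1 + n2) / (n1 + n2 - 1)
        if var <= 0:
            return 0.0 if p1h - p2h - d == 0 else math.inf * math.copysign(1, p1h - p2h - d)
        return (p1h - p2h - d) / math.sqrt(var)

    diff = p1h - p2h
    lo = -1.0 if diff <= -1 + 1e-9 else optimize.brentq(
        lambda d: zstat(d) - z, -1 + 1e-9, diff, xtol=1e-12
    )
    hi = 1.0 if diff >= 1 - 1e-9 else optimize.brentq(
        lambda d: zstat(d) + z, diff, 1 - 1e-9, xtol=1e-12
    )
    return 100 * lo, 100 * hi


class TestRateDifference:
    def test_reproduces_published_degenerate_case(self):
        """100% vs 100% at n=115 vs 35: the corrected score interval."""
        diff, lo, hi = rate_difference_ci(115, 115, 35, 35)
        assert diff == pytest.approx(0.0)
        assert round(lo, 2) == -3.25
        assert round(hi, 2) == 9.95

    def test_symmetric_inputs_give_symmetric_ci(self):
        _, lo, hi = rate_difference_ci(12, 20, 12, 20)
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_all_small_outcomes_match_numeric_oracle(self):
        """Every (x1, x2) outcome at n1=n2=5 agrees with the independent
        likelihood-based inversion to 1e-6 on the proportion scale."""
        for x1 in range(6):
            for x2 in range(6):
                _, lo, hi = rate_difference_ci(x1, 5, x2, 5)
                olo, ohi = _oracle_score_ci(x1, 5, x2, 5)
                assert lo == pytest.approx(olo, abs=1e-4)
                assert hi == pytest.approx(ohi, abs=1e-4)

    def test_cross_check_statsmodels_score(self):
        """statsmodels inverts a score statistic with a slightly different
        variance evaluation; agreement is to ~0.05 percentage points, a
        family-level sanity check (the exact oracle is the likelihood-based
        inversion above)."""
        from statsmodels.stats.proportion import confint_proportions_2indep

        _, lo, hi = rate_difference_ci(40, 115, 10, 35, corrected=False)
        sm_lo, sm_hi = confint_proportions_2indep(
            40, 115, 10, 35, method="score", compare="diff", correction=False
        )
        assert lo == pytest.approx(100 * sm_lo, abs=0.1)
        assert hi == pytest.approx(100 * sm_hi, abs=0.2)

    def test_newcombe_alternative(self):
        diff, lo, hi = newcombe_hybrid_ci(115, 115, 35, 35)
        assert diff == pytest.approx(0.0)
        # close to, but distinct from, the score interval
        assert lo == pytest.approx(-3.23, abs=0.02)
        assert hi == pytest.approx(9.89, abs=0.02)

    def test_input_errors(self):
        with pytest.raises(ValueError):
            rate_difference_ci(1, 0, 1, 5)
        with pytest.raises(ValueError):
            rate_difference_ci(6, 5, 1, 5)


class TestMoverRatio:
    def test_identical_groups(self):
        g = LogStats(1.2, 0.4, 40)
        ratio, lo, hi = gmc_ratio_ci_mover(g, g)
        assert ratio == pytest.approx(1.0)
        assert math.log10(hi) == pytest.approx(-math.log10(lo), rel=1e-9)

    def test_contains_point_and_widens_with_smaller_n(self):
        g1, g2 = LogStats(1.5, 0.5, 30), LogStats(1.0, 0.3, 100)
        ratio, lo, hi = gmc_ratio_ci_mover(g1, g2)
        assert lo < ratio < hi
        _, lo_s, hi_s = gmc_ratio_ci_mover(LogStats(1.5, 0.5, 10), g2)
        assert lo_s < lo and hi_s > hi

    def test_equal_variance_limit_is_two_sample_t(self):
        """With equal variances and large equal n the MOVER interval
        coincides with the pooled two-sample t interval, anti-logged."""
        m1, m2, s, n = 2.0, 1.6, 0.5, 10_000
        ratio, lo, hi = gmc_ratio_ci_mover(LogStats(m1, s, n), LogStats(m2, s, n))
        tq = stats.t.ppf(0.975, 2 * n - 2)
        half = tq * s * math.sqrt(2.0 / n)
        assert lo == pytest.approx(10 ** (m1 - m2 - half), rel=1e-3)
        assert hi == pytest.approx(10 ** (m1 - m2 + half), rel=1e-3)

    def test_point_ratio_examples(self):
        assert round(gmc_ratio_point(285.5, 47.2), 2) == 6.05
        assert round(gmc_ratio_point(442.6, 113.0), 2) == 3.92
        assert round(gmc_ratio_point(7.7, 7.7), 2) == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            gmc_ratio_ci_mover(LogStats(1, 0.5, 1), LogStats(1, 0.5, 10))
        with pytest.raises(ValueError):
            gmc_ratio_ci_mover(LogStats(1, 0.0, 10), LogStats(1, 0.5, 10))
        with pytest.raises(ValueError):
            gmc_ratio_point(-1.0, 2.0)


def _published_results():
    """Component results with the published lower limits."""
    return [
        NoninferiorityResult("rate_differences", "diphtheria", 0.0, -3.25, 9.95, -10.0),
        NoninferiorityResult("rate_differences", "tetanus", 0.0, -3.25, 9.95, -10.0),
        NoninferiorityResult("gmc_ratios", "PT", 2.00, 1.69, 2.37, 0.67),
        NoninferiorityResult("gmc_ratios", "FHA", 6.05, 5.14, 7.11, 0.67),
        NoninferiorityResult("gmc_ratios", "PRN", 3.92, 3.22, 4.76, 0.67),
    ]


class TestHierarchy:
    def test_published_limits_pass_both_objectives(self):
        report = assess_hierarchy(_published_results())
        assert report.objective1_pass
        assert report.objective2_evaluated and report.objective2_pass
        assert report.overall_pass

    def test_margin_boundary_inclusive(self):
        results = _published_results()
        results[0] = NoninferiorityResult(
            "rate_differences", "diphtheria", 0.0, -10.0, 9.95, -10.0
        )
        assert assess_hierarchy(results).objective1_pass

    def test_failed_gate_blocks_objective_two(self):
        results = _published_results()
        results[1] = NoninferiorityResult(
            "rate_differences", "tetanus", -8.0, -12.0, 1.0, -10.0
        )
        report = assess_hierarchy(results)
        assert not report.objective1_pass
        assert not report.objective2_evaluated
        assert report.objective2_pass is None
        assert "not evaluated" in report.describe()

    def test_any_ratio_below_margin_fails_objective_two_only(self):
        for i in (2, 3, 4):
            results = _published_results()
            r = results[i]
            results[i] = NoninferiorityResult(
                r.objective, r.component, r.estimate, 0.66, r.ci_high, r.margin
            )
            report = assess_hierarchy(results)
            assert report.objective1_pass
            assert report.objective2_evaluated and not report.objective2_pass
            assert not report.overall_pass

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            assess_hierarchy(_published_results()[:2])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NIConfig(rate_margin=10.0)
        with pytest.raises(ValueError):
            NIConfig(ratio_margin=1.5)
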