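"""Core serology estimators: exact CIs, GMCs, imputation, fold-rise."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats
from scipy.optimize import brentq

from serotrial import (
    DEFAULT_ASSAYS,
    clopper_pearson_ci,
    fold_rise,
    gmc_with_ci,
    impute_censored,
    rate_above_threshold,
)
from serotrial.serology import summarize_serology

from conftest import serology_frame


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (35, 35, (90.0, 100.0)),
            (115, 115, (96.8, 100.0)),
            (0, 36, (0.0, 9.7)),
            (0, 37, (0.0, 9.5)),
            (0, 128, (0.0, 2.8)),
            (14, 35, (23.9, 57.9)),
            (21, 36, (40.8, 74.5)),
            (2, 36, (0.7, 18.7)),
            (23, 35, (47.8, 80.9)),
        ],
    )
    def test_printed_one_decimal(self, x, n, expected):
        lo, hi = clopper_pearson_ci(x, n)
        assert (round(lo, 1), round(hi, 1)) == expected

    def test_brute_force_tail_inversion(self):
        """Bounds solve the binomial tail equations to 1e-9 for all n <= 10."""
        alpha = 0.05
        for n in range(1, 11):
            for x in range(n + 1):
                lo, hi = clopper_pearson_ci(x, n)
                if x == 0:
                    assert lo == 0.0
                else:
                    f = lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2
                    assert abs(lo / 100 - brentq(f, 1e-15, 1 - 1e-15, xtol=1e-13)) < 1e-9
                if x == n:
                    assert hi == 100.0
                else:
                    f = lambda p: stats.binom.cdf(x, n, p) - alpha / 2
                    assert abs(hi / 100 - brentq(f, 1e-15, 1 - 1e-15, xtol=1e-13)) < 1e-9

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160, 640):
            lo, hi = clopper_pearson_ci(n // 4, n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_input_errors(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(0, 0)
        with pytest.raises(ValueError):
            clopper_pearson_ci(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson_ci(-1, 4)


class TestGMC:
    def test_hand_oracle_decade_values(self):
        """{1, 10, 100}: mean 1, sd 1 on log10; CI from the t_2 quantile."""
        res = gmc_with_ci([1.0, 10.0, 100.0])
        assert res.gmc == pytest.approx(10.0)
        t2 = stats.t.ppf(0.975, 2)
        half = t2 * 1.0 / math.sqrt(3)
        assert res.lower == pytest.approx(10 ** (1 - half))
        assert res.upper == pytest.approx(10 ** (1 + half))

    def test_zero_variance(self):
        res = gmc_with_ci([4.2, 4.2, 4.2])
        assert res.gmc == pytest.approx(4.2)
        assert res.lower == pytest.approx(4.2)
        assert res.upper == pytest.approx(4.2)

    def test_single_observation_ci_undefined(self):
        res = gmc_with_ci([7.0])
        assert res.gmc == pytest.approx(7.0)
        assert not res.ci_defined

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gmc_with_ci([1.0, 0.0])
        with pytest.raises(ValueError):
            gmc_with_ci([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st_.lists(st_.floats(0.01, 1e4), min_size=2, max_size=30),
        k=st_.floats(0.001, 1000.0),
    )
    def test_scaling_equivariance(self, values, k):
        base = gmc_with_ci(values)
        scaled = gmc_with_ci([v * k for v in values])
        assert scaled.gmc == pytest.approx(base.gmc * k, rel=1e-9)
        assert scaled.lower == pytest.approx(base.lower * k, rel=1e-9)
        assert scaled.upper == pytest.approx(base.upper * k, rel=1e-9)

    def test_order_invariance(self):
        vals = [0.3, 7.1, 2.2, 55.0, 1.0]
        a, b = gmc_with_ci(vals), gmc_with_ci(vals[::-1])
        assert (a.gmc, a.lower, a.upper) == pytest.approx((b.gmc, b.lower, b.upper))


class TestImputation:
    def test_censored_pt_to_half_cutoff(self):
        df = serology_frame([2.693], antigen="PT", censored=[1])
        out = impute_censored(df, DEFAULT_ASSAYS["PT"])
        assert out["concentration_IU_ml"].iloc[0] == pytest.approx(1.3465)

    def test_uncensored_unchanged_and_count(self):
        df = serology_frame(
            [2.693, 2.693, 2.693, 5.0, 8.0], antigen="PT", censored=[1, 1, 1, 0, 0]
        )
        out = impute_censored(df, DEFAULT_ASSAYS["PT"])
        changed = (out["concentration_IU_ml"] != df["concentration_IU_ml"]).sum()
        assert changed == 3
        assert out["concentration_IU_ml"].iloc[3:].tolist() == [5.0, 8.0]
        assert list(out.index) == list(df.index)

    def test_antigen_mismatch_rejected(self):
        df = serology_frame([1.0], antigen="FHA")
        with pytest.raises(ValueError):
            impute_censored(df, DEFAULT_ASSAYS["PT"])


class TestRates:
    def test_all_above(self):
        r = rate_above_threshold([0.5] * 115, 0.1)
        assert (r.x, r.n, r.pct) == (115, 115, 100.0)
        assert (round(r.lower, 1), round(r.upper, 1)) == (96.8, 100.0)

    def test_boundary_inclusive(self):
        r = rate_above_threshold([0.1, 0.0999], 0.1)
        assert r.x == 1

    def test_printed_partial_rate(self):
        conc = [1.0] * 23 + [0.5] * 12
        r = rate_above_threshold(conc, 1.0)
        assert r.pct == pytest.approx(65.7, abs=0.05)
        assert (round(r.lower, 1), round(r.upper, 1)) == (47.8, 80.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rate_above_threshold([], 0.1)


class TestFoldRise:
    @pytest.mark.parametrize(
        "pre, post, expected",
        [(1.8, 9.9, 5.5), (21.7, 336.2, 15.5), (3.0, 3.0, 1.0)],
    )
    def test_examples(self, pre, post, expected):
        assert round(fold_rise(pre, post), 1) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_rise(0.0, 1.0)


class TestSummarize:
    def test_thresholds_per_antigen(self, assays):
        import pandas as pd

        dt = serology_frame([0.05, 0.5, 2.0], antigen="diphtheria")
        pt = serology_frame([1.0, 5.0, 9.0], antigen="PT", censored=[1, 0, 0])
        out = summarize_serology(pd.concat([dt, pt], ignore_index=True), assays)
        d_rows = out[out["antigen"] == "diphtheria"]
        assert set(d_rows["threshold"]) == {0.1, 1.0}
        pt_rows = out[out["antigen"] == "PT"]
        # pertussis antigens are rated at the assay cut-off only
        assert set(pt_rows["threshold"]) == {2.693}
        assert pt_rows["x"].iloc[0] == 2  # imputed 1.3465 stays below cut-off
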