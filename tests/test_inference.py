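"""Two-sample binomial inference: closed forms, published reproductions,
independent oracles for the score and exact intervals, and symmetry
properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from carealert.errors import DataError, ResourceError
from carealert.inference import (
    TwoSampleCounts,
    chan_zhang_ci,
    cohen_h,
    compare,
    exact_unconditional_pvalues,
    mcnemar_two_group,
    mn_score_ci,
    mn_score_stat,
    pooled_z_test,
    wald_unpooled_ci,
)
from carealert.scoring import PairedChangeCounts
from helpers import mn_grid_inversion


class TestCohenH:
    @pytest.mark.parametrize(
        "x1,n1,x2,n2,expected",
        [
            (385, 2620, 212, 2380, 0.18),
            (103, 385, 113, 212, 0.55),
            (67, 263, 44, 83, 0.57),
        ],
    )
    def test_published_effect_sizes(self, x1, n1, x2, n2, expected):
        assert round(cohen_h(TwoSampleCounts(x1, n1, x2, n2)), 2) == expected

    def test_closed_form_quarters(self):
        # asin(sqrt(3/4)) = pi/3, asin(sqrt(1/4)) = pi/6
        h = cohen_h(TwoSampleCounts(75, 100, 25, 100))
        assert h == pytest.approx(math.pi / 3, abs=1e-12)

    def test_equal_proportions_give_zero(self):
        assert cohen_h(TwoSampleCounts(3, 10, 30, 100)) == pytest.approx(0.0)

    def test_defined_at_the_endpoints(self):
        assert cohen_h(TwoSampleCounts(10, 10, 0, 10)) == pytest.approx(math.pi)

    def test_monotone_in_the_gap(self):
        hs = [cohen_h(TwoSampleCounts(x, 100, 20, 100)) for x in range(21, 90, 7)]
        assert all(b > a for a, b in zip(hs, hs[1:]))


class TestPooledZ:
    @pytest.mark.parametrize(
        "x1,n1,x2,n2,expected,places",
        [
            (235, 443, 332, 1269, 10.35, 2),
            (71, 107, 68, 110, 0.696, 3),
            (443, 5750, 1269, 8810, -12.27, 2),
        ],
    )
    def test_published_statistics(self, x1, n1, x2, n2, expected, places):
        z, p = pooled_z_test(TwoSampleCounts(x1, n1, x2, n2))
        assert round(z, places) == expected
        assert p < 0.001 if abs(expected) > 5 else p > 0.05

    def test_equal_proportions_give_zero(self):
        z, p = pooled_z_test(TwoSampleCounts(5, 10, 50, 100))
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_pooled_proportion_raises(self):
        with pytest.raises(DataError):
            pooled_z_test(TwoSampleCounts(0, 10, 0, 10))


class TestWaldCI:
    def test_published_threshold_interval(self):
        lo, hi = wald_unpooled_ci(TwoSampleCounts(443, 5750, 1269, 8810))
        assert round(lo, 3) == -0.077
        assert round(hi, 3) == -0.057

    def test_zero_variance_endpoints(self):
        assert wald_unpooled_ci(TwoSampleCounts(0, 10, 0, 10)) == (0.0, 0.0)

    def test_contains_the_point_estimate(self):
        c = TwoSampleCounts(7, 19, 3, 11)
        lo, hi = wald_unpooled_ci(c)
        assert lo <= c.diff <= hi


class TestMNScoreCI:
    def test_matches_grid_inversion_oracle(self):
        lo, hi = mn_score_ci(TwoSampleCounts(5, 10, 2, 10))
        glo, ghi = mn_grid_inversion(5, 10, 2, 10)
        assert lo == pytest.approx(glo, abs=1e-4)
        assert hi == pytest.approx(ghi, abs=1e-4)

    def test_cubic_restricted_mle_matches_numerical_likelihood(self):
        """The closed-form constrained MLE behind the score statistic agrees
        with direct numerical maximization of the binomial likelihood."""
        c = TwoSampleCounts(5, 10, 2, 10)
        for delta in (-0.4, -0.1, 0.0, 0.2, 0.55):
            lo = max(0.0, -delta) + 1e-12
            hi = min(1.0, 1.0 - delta) - 1e-12

            def nll(p2):
                p1 = p2 + delta
                return -(
                    c.x1 * np.log(p1)
                    + (c.n1 - c.x1) * np.log1p(-p1)
                    + c.x2 * np.log(p2)
                    + (c.n2 - c.x2) * np.log1p(-p2)
                )

            p2_num = minimize_scalar(
                nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-14}
            ).x
            N = c.n1 + c.n2
            var = (
                (p2_num + delta) * (1 - p2_num - delta) / c.n1
                + p2_num * (1 - p2_num) / c.n2
            ) * N / (N - 1)
            z_num = (c.diff - delta) / math.sqrt(var)
            assert float(mn_score_stat(c, delta)) == pytest.approx(z_num, abs=1e-7)

    def test_statsmodels_score_interval_is_close(self):
        """Loose cross-check against an external score-interval routine;
        its inversion differs slightly from the faithful construction, so the
        sharp oracles are the grid inversion and the numerical MLE above."""
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        for c in (
            TwoSampleCounts(235, 443, 332, 1269),
            TwoSampleCounts(50, 120, 30, 110),
        ):
            lo, hi = mn_score_ci(c)
            slo, shi = statsmodels.confint_proportions_2indep(
                c.x1, c.n1, c.x2, c.n2, method="score", compare="diff"
            )
            assert lo == pytest.approx(slo, abs=5e-3)
            assert hi == pytest.approx(shi, abs=5e-3)

    def test_large_sample_agreement_with_wald(self):
        c = TwoSampleCounts(235, 443, 332, 1269)
        mn = mn_score_ci(c)
        wald = wald_unpooled_ci(c)
        assert mn[0] == pytest.approx(wald[0], abs=0.003)
        assert mn[1] == pytest.approx(wald[1], abs=0.003)

    def test_defined_for_all_zero_counts(self):
        lo, hi = mn_score_ci(TwoSampleCounts(0, 10, 0, 10))
        assert -1 < lo < 0 < hi < 1
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_defined_at_perfect_separation(self):
        lo, hi = mn_score_ci(TwoSampleCounts(10, 10, 0, 10))
        assert hi == 1.0
        assert 0 < lo < 1


class TestChanZhangCI:
    def test_perfect_separation_sign(self):
        lo, hi = chan_zhang_ci(TwoSampleCounts(10, 10, 0, 10))
        assert hi == pytest.approx(1.0, abs=1e-6)
        assert lo > 0

    def test_contains_the_score_interval_at_small_n(self):
        c = TwoSampleCounts(5, 10, 2, 10)
        mlo, mhi = mn_score_ci(c)
        clo, chi = chan_zhang_ci(c)
        assert clo <= mlo + 1e-9
        assert chi >= mhi - 1e-9

    def test_enumeration_guard(self):
        with pytest.raises(ResourceError, match="Miettinen"):
            chan_zhang_ci(TwoSampleCounts(100, 500, 80, 500))

    def test_observed_difference_is_never_rejected(self):
        c = TwoSampleCounts(4, 12, 9, 15)
        pl, pu = exact_unconditional_pvalues(c, c.diff)
        assert pl > 0.025 and pu > 0.025


class TestMcNemarTwoGroup:
    def test_identical_change_tables_give_zero(self):
        t = PairedChangeCounts(5, 8, 8, 30)
        z, p = mcnemar_two_group(t, t)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_extreme_one_way_discordance(self):
        one_way = PairedChangeCounts(0, 40, 0, 60)
        balanced = PairedChangeCounts(0, 20, 20, 60)
        z, p = mcnemar_two_group(balanced, one_way)
        assert z >= 5
        assert p < 0.001

    def test_sign_convention_alert_shift_toward_fewer_is_positive(self):
        control = PairedChangeCounts(5, 2, 2, 41)
        alert = PairedChangeCounts(2, 9, 1, 38)
        z, _ = mcnemar_two_group(control, alert)
        assert z > 0

    def test_one_sample_reduction(self):
        empty = PairedChangeCounts(0, 0, 0, 0)
        t = PairedChangeCounts(3, 9, 4, 34)
        z, _ = mcnemar_two_group(empty, t)
        b, c, N = 9, 4, 50
        d = (b - c) / N
        v = (b + c - (b - c) ** 2 / N) / N**2
        assert z == pytest.approx(d / math.sqrt(v))

    def test_no_discordance_raises(self):
        t = PairedChangeCounts(5, 0, 0, 45)
        with pytest.raises(DataError):
            mcnemar_two_group(t, t)


class TestCompare:
    def test_bundles_published_month2_improvement(self):
        res = compare(TwoSampleCounts(103, 385, 113, 212), methods=("wald", "mn"))
        assert round(res.h, 2) == 0.55
        lo, hi = res.cis["wald"]
        assert lo <= res.diff <= hi

    def test_symmetric_counts(self):
        res = compare(TwoSampleCounts(6, 20, 6, 20))
        assert res.diff == 0 and res.h == pytest.approx(0) and res.z == pytest.approx(0)

    @given(
        x1=st.integers(0, 25),
        n1=st.integers(1, 25),
        x2=st.integers(0, 25),
        n2=st.integers(1, 25),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_swapping_groups_negates_diff_and_reflects_cis(self, x1, n1, x2, n2):
        if x1 > n1 or x2 > n2:
            return
        c = TwoSampleCounts(x1, n1, x2, n2)
        a = compare(c, methods=("wald", "mn"))
        b = compare(c.swapped(), methods=("wald", "mn"))
        assert a.diff == pytest.approx(-b.diff)
        assert a.h == pytest.approx(b.h)
        if a.z is not None:
            assert a.z == pytest.approx(-b.z)
            assert a.p_value == pytest.approx(b.p_value)
        for m in ("wald", "mn"):
            assert a.cis[m][0] == pytest.approx(-b.cis[m][1], abs=1e-6)
            assert a.cis[m][1] == pytest.approx(-b.cis[m][0], abs=1e-6)

    def test_ci_bounds_are_ordered(self):
        for c in (TwoSampleCounts(1, 3, 2, 5), TwoSampleCounts(0, 4, 4, 4)):
            res = compare(c, methods=("wald", "mn", "cz"))
            for lo, hi in res.cis.values():
                assert lo <= hi
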