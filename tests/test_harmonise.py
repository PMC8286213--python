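"""Ensemble aggregation, specification limits and compliance checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petharm as ph
from petharm.errors import (
    IncompatibleResultsError,
    IncompleteLimitsError,
    InsufficientDataError,
    InvalidReferenceError,
)
from petharm.harmonise import LimitsTable
from petharm.metrics import IQResult, RC_METRICS

DIAMS = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)


def iq_from_values(values_by_diam: dict[float, float]) -> IQResult:
    spheres = {
        d: {m: v for m in RC_METRICS + ("CRC_max", "CRC_mean", "CRC_peak")}
        for d, v in values_by_diam.items()
    }
    return IQResult(spheres, {}, labels={})


class TestAggregate:
    def test_identical_results_have_zero_sd(self):
        r = iq_from_values({d: 0.9 for d in DIAMS})
        summary = ph.aggregate([r, r, r])
        assert (summary.table.sd == 0).all()

    def test_hand_computed_mean_and_sd(self):
        results = [iq_from_values({37.0: v}) for v in (0.8, 0.9, 1.0)]
        s = ph.aggregate(results)
        assert s.value(37.0, "RC_mean") == pytest.approx(0.9)
        assert s.value(37.0, "RC_mean", "sd") == pytest.approx(0.1)

    def test_single_result_rejected(self):
        with pytest.raises(InsufficientDataError):
            ph.aggregate([iq_from_values({37.0: 1.0})])

    def test_mismatched_sphere_sets_rejected(self):
        with pytest.raises(IncompatibleResultsError):
            ph.aggregate([iq_from_values({37.0: 1.0}), iq_from_values({28.0: 1.0})])


class TestDeriveLimits:
    def test_two_sd_bounds(self):
        s = ph.aggregate([iq_from_values({37.0: v}) for v in (0.85, 0.90, 0.95)])
        sd = s.value(37.0, "RC_mean", "sd")
        limits = ph.derive_limits(s, k=2.0)
        lo, hi = limits.bounds("advanced", "RC_mean", 37.0)
        assert lo == pytest.approx(0.9 - 2 * sd)
        assert hi == pytest.approx(0.9 + 2 * sd)
        assert hi - lo == pytest.approx(4 * sd)

    def test_k_zero_collapses_to_mean(self):
        s = ph.aggregate([iq_from_values({37.0: v}) for v in (0.8, 1.0)])
        limits = ph.derive_limits(s, k=0.0)
        lo, hi = limits.bounds("advanced", "RC_mean", 37.0)
        assert lo == hi == pytest.approx(0.9)

    def test_zero_sd_warns_degenerate(self):
        r = iq_from_values({37.0: 0.9})
        s = ph.aggregate([r, r])
        with pytest.warns(UserWarning, match="degenerate"):
            ph.derive_limits(s)


@pytest.fixture(scope="module")
def limits():
    return LimitsTable.shipped_ga68()


class TestShippedLimits:
    def test_full_coverage(self, limits):
        assert len(limits.table) == 36  # 2 families x 3 metrics x 6 spheres
        assert limits.families() == ["advanced", "conventional"]

    @pytest.mark.parametrize(
        "family, metric, d, lo, hi",
        [
            ("conventional", "RC_max", 37.0, 0.91, 1.14),
            ("conventional", "RC_mean", 10.0, 0.20, 0.34),
            ("advanced", "RC_max", 13.0, 0.65, 0.99),
            ("advanced", "RC_peak", 17.0, 0.62, 0.84),
        ],
    )
    def test_spot_values(self, limits, family, metric, d, lo, hi):
        assert limits.bounds(family, metric, d) == (lo, hi)

    def test_midpoints_pass_everywhere(self, limits):
        for family in limits.families():
            mids = {}
            for d in DIAMS:
                spheres = {}
                for m in RC_METRICS:
                    lo, hi = limits.bounds(family, m, d)
                    spheres[m] = 0.5 * (lo + hi)
                mids[d] = spheres
            result = IQResult(mids, {}, labels={})
            report = ph.check_compliance(result, limits, family)
            assert report.passed.all()

    def test_values_above_upper_fail_everywhere(self, limits):
        for family in limits.families():
            high = {}
            for d in DIAMS:
                high[d] = {
                    m: limits.bounds(family, m, d)[1] * 1.01 for m in RC_METRICS
                }
            report = ph.check_compliance(IQResult(high, {}, labels={}), limits, family)
            assert not report.passed.any()
            assert (report.deviation_pct > 0).all()

    def test_boundary_value_passes_closed_interval(self, limits):
        lo, hi = limits.bounds("conventional", "RC_mean", 37.0)
        res = iq_from_values({37.0: lo})
        report = ph.check_compliance(res, limits, "conventional", metrics=("RC_mean",))
        assert report.passed.all()

    def test_five_percent_below_lower_reports_deviation(self, limits):
        lo, _ = limits.bounds("conventional", "RC_mean", 37.0)
        res = iq_from_values({37.0: lo * 0.95})
        report = ph.check_compliance(res, limits, "conventional", metrics=("RC_mean",))
        assert not report.passed.iloc[0]
        assert report.deviation_pct.iloc[0] == pytest.approx(-5.0)

    def test_missing_entry_rejected(self, limits):
        res = iq_from_values({99.0: 1.0})
        with pytest.raises(IncompleteLimitsError):
            ph.check_compliance(res, limits, "conventional")


class TestPctDifference:
    @pytest.mark.parametrize(
        "a, b, expected", [(1.08, 1.00, 8.0), (0.92, 1.00, -8.0), (0.73, 0.73, 0.0)]
    )
    def test_examples(self, a, b, expected):
        assert ph.pct_difference(a, b) == pytest.approx(expected)

    def test_invalid_reference(self):
        with pytest.raises(InvalidReferenceError):
            ph.pct_difference(1.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 10), b=st.floats(0.1, 10), c=st.floats(0.1, 10))
    def test_rescale_invariance(self, a, b, c):
        assert ph.pct_difference(a * c, b * c) == pytest.approx(
            ph.pct_difference(a, b), rel=1e-9
        )


class TestWelchTTest:
    def test_identical_groups(self):
        t, df, p = ph.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_widely_separated_groups(self):
        t, df, p = ph.welch_t_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert p < 1e-6

    def test_against_naive_formula(self):
        a = np.array([2.1, 1.9, 2.0, 2.2])
        b = np.array([1.0, 1.1, 0.9, 1.2])
        t, df, p = ph.welch_t_test(a, b)
        # second, independent coding of the unequal-variance statistic
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = math.sqrt(va / a.size + vb / b.size)
        t_naive = (a.mean() - b.mean()) / se
        df_naive = (va / a.size + vb / b.size) ** 2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
        assert t == pytest.approx(t_naive, abs=1e-6)
        assert df == pytest.approx(df_naive, abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100))
    def test_rescale_invariance(self, scale):
        a = np.array([2.1, 1.9, 2.0, 2.2])
        b = np.array([1.0, 1.1, 0.9, 1.2])
        t1, _, p1 = ph.welch_t_test(a, b)
        t2, _, p2 = ph.welch_t_test(a * scale, b * scale)
        assert t1 == pytest.approx(t2, rel=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            ph.welch_t_test([1.0], [1.0, 2.0])


def test_limits_table_schema_validation():
    import pandas as pd

    bad = pd.DataFrame({"family": ["x"], "metric": ["RC_max"],
                        "diameter_mm": [37.0], "lower": [1.2], "upper": [0.8]})
    with pytest.raises(IncompleteLimitsError):
        LimitsTable(bad)
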