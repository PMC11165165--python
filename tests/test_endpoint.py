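import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teratoassay._format import round_sig
from teratoassay.assay_io import IncidenceSeries
from teratoassay.endpoint import (
    Td50Estimate,
    reed_muench,
    spearman_karber,
    td50_series,
    minimum_positive_dose,
)
from teratoassay.errors import InsufficientDesignError, SpacingError
from teratoassay.synthetic_data import AssaySimConfig, simulate_assay

from conftest import make_arm


def sk_area_oracle(doses, proportions):
    """Independent mean-of-tolerance-distribution computation.

    Assign probability mass p_{i+1} - p_i to the midpoint of consecutive
    log10 doses, with the conventional closure that the dose below the
    ladder is fully negative and the dose above fully positive.  The mean of
    that discrete distribution is the Spearman-Karber estimate.
    """
    x = list(np.log10(doses))
    d = x[1] - x[0]
    x = [x[0] - d] + x + [x[-1] + d]
    p = [0.0] + list(proportions) + [1.0]
    mean = 0.0
    for i in range(len(p) - 1):
        mean += (p[i + 1] - p[i]) * (x[i] + x[i + 1]) / 2.0
    return mean


# (doses, n, counts, expected TD50 at sig figs, sig figs)
STEP_CASES = [
    ((1e2, 1e3), 5, (0, 5), 316.0, 3),
    ((1e1, 1e2, 1e3), 7, (3, 7, 7), 11.8, 3),
    ((1e5, 1e6, 1e7), 5, (0, 0, 5), 3.16e6, 3),
    ((1e6, 1e7), 4, (0, 3), 5.62e6, 3),
]


class TestSpearmanKarber:
    @pytest.mark.parametrize("doses,n,counts,expected,sf", STEP_CASES)
    def test_point_estimates(self, doses, n, counts, expected, sf):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = spearman_karber(make_arm(doses, n, counts))
        assert round_sig(est.td50, sf) == expected
        assert est.td50 == pytest.approx(10**est.log10_td50)

    def test_clean_step_midpoint(self, clean_step_arm):
        est = spearman_karber(clean_step_arm)
        assert est.log10_td50 == pytest.approx(2.5)
        assert not est.extrapolated_top and not est.extrapolated_bottom
        lo, hi = est.ci95_log10
        assert lo <= est.log10_td50 <= hi
        assert est.se_log10 == pytest.approx(0.0)  # both proportions are 0 or 1

    def test_partial_top_sets_extrapolated_flag(self):
        with pytest.warns(UserWarning, match="top dose"):
            est = spearman_karber(make_arm((1e6, 1e7), 4, (0, 3)))
        assert est.extrapolated_top
        assert est.log10_td50 == pytest.approx(6.75)

    def test_partial_bottom_sets_extrapolated_flag(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = spearman_karber(make_arm((1e1, 1e2, 1e3), 7, (3, 7, 7)))
        assert est.extrapolated_bottom and not est.extrapolated_top

    def test_standard_error_convention(self):
        # only the 3/7 group contributes: se = d * sqrt((3/7)(4/7)/6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = spearman_karber(make_arm((1e1, 1e2, 1e3), 7, (3, 7, 7)))
        assert est.se_log10 == pytest.approx(0.2020305089, abs=1e-9)
        assert est.ci95_log10[1] - est.ci95_log10[0] == pytest.approx(
            2 * 1.96 * est.se_log10
        )

    def test_singleton_group_contributes_zero_with_warning(self):
        arm = make_arm((1e1, 1e2, 1e3), (5, 1, 5), (0, 1, 5))
        with pytest.warns(UserWarning, match="single animal"):
            est = spearman_karber(arm)
        assert est.se_log10 == pytest.approx(0.0)

    def test_all_negative_is_not_applicable(self, all_negative_arm):
        est = spearman_karber(all_negative_arm)
        assert not est.applicable
        assert math.isnan(est.log10_td50)

    def test_unequal_spacing_rejected(self):
        with pytest.raises(SpacingError):
            spearman_karber(make_arm((1e1, 1e2, 1e4), 5, (0, 1, 5)))

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDesignError):
            spearman_karber(make_arm((1e3,), 5, (3,)))

    def test_isotonic_smooths_non_monotone_table(self):
        arm = make_arm((1e1, 1e2, 1e3, 1e4), 5, (0, 3, 1, 5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = spearman_karber(arm)
            iso = spearman_karber(arm, isotonic=True)
        # PAV pools the (3/5, 1/5) violation to (2/5, 2/5): same mass, same estimate
        assert iso.log10_td50 == pytest.approx(raw.log10_td50)

    @given(
        n=st.integers(2, 10),
        counts=st.lists(st.integers(0, 10), min_size=2, max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_on_monotone_tables(self, n, counts):
        """SK equals the independent area-under-CDF oracle to 1e-12."""
        k = sorted(min(c, n) for c in counts)
        k[0], k[-1] = 0, n  # reach 0 at the bottom and 1 at the top
        doses = tuple(10.0 ** (i + 1) for i in range(len(k)))
        arm = make_arm(doses, n, k)
        est = spearman_karber(arm)
        assert est.log10_td50 == pytest.approx(
            sk_area_oracle(arm.doses, arm.proportions), abs=1e-12
        )

    @given(
        n=st.integers(2, 8),
        counts=st.lists(st.integers(0, 8), min_size=2, max_size=5),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_padding_invariance_and_positive_increment(self, n, counts, data):
        k = [min(c, n) for c in counts]
        if sum(k) == 0:
            k[-1] = 1
        doses = tuple(10.0 ** (i + 2) for i in range(len(k)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = spearman_karber(make_arm(doses, n, k))

            # padding: p=0 group below and p=1 group above leave the estimate unchanged
            padded = make_arm(
                (doses[0] / 10,) + doses + (doses[-1] * 10,), n, [0] + k + [n]
            )
            assert spearman_karber(padded).log10_td50 == pytest.approx(
                base.log10_td50, abs=1e-12
            )

            # adding one positive lowers the estimate by exactly d/n
            i = data.draw(st.integers(0, len(k) - 1), label="group")
            if k[i] < n:
                bumped = list(k)
                bumped[i] += 1
                est2 = spearman_karber(make_arm(doses, n, bumped))
                assert base.log10_td50 - est2.log10_td50 == pytest.approx(
                    1.0 / n, abs=1e-12
                )


class TestReedMuench:
    def test_symmetric_step_agrees_with_sk(self, clean_step_arm):
        rm = reed_muench(clean_step_arm)
        sk = spearman_karber(clean_step_arm)
        assert rm.log10_td50 == pytest.approx(2.5) == pytest.approx(sk.log10_td50)
        assert rm.se_log10 is None

    def test_hand_worked_cumulative_table(self):
        # worksheet for (0/5, 1/5, 4/5, 5/5) at 10^1..10^4:
        #   cumulative positives (up):    0, 1, 5, 10
        #   cumulative negatives (down): 10, 5, 1,  0
        #   pooled % positive:            0, 16.67, 83.33, 100
        # 50% is bracketed between 10^2 and 10^3,
        # PD = (50 - 16.67)/(83.33 - 16.67) = 0.5  ->  log10 TD50 = 2.5
        est = reed_muench(make_arm((1e1, 1e2, 1e3, 1e4), 5, (0, 1, 4, 5)))
        assert est.log10_td50 == pytest.approx(2.5)

    def test_all_negative_not_applicable(self, all_negative_arm):
        assert not reed_muench(all_negative_arm).applicable

    def test_unbracketed_incidence_not_applicable(self):
        est = reed_muench(make_arm((1e2, 1e3), 5, (4, 5)))
        assert not est.applicable
        assert "bracket" in est.note

    def test_agrees_with_sk_on_simulated_monotone_tables(self):
        """RM and SK stay within 0.25 log10 on simulated monotone tables, n>=5."""
        checked = 0
        for seed in range(60):
            arm = simulate_assay(AssaySimConfig(seed=seed, n_per_group=5)).arm
            p = arm.proportions
            if not (np.all(np.diff(p) >= 0) and p[0] == 0.0 and p[-1] == 1.0):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rm, sk = reed_muench(arm), spearman_karber(arm)
            if not rm.applicable:
                continue
            checked += 1
            assert abs(rm.log10_td50 - sk.log10_td50) <= 0.25
        assert checked >= 20


class TestTd50Series:
    def _series(self):
        arm = make_arm((1e2, 1e3, 1e4), 5, (0, 3, 5))
        cum = np.array([[0, 0, 0, 0], [1, 3, 3, 3], [2, 5, 5, 5]])
        return IncidenceSeries(arm=arm, weeks=(2.0, 4.0, 8.0, 12.0), cumulative_positive=cum)

    def test_final_week_equals_endpoint(self):
        series = self._series()
        per_week = td50_series(series)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            endpoint_est = spearman_karber(series.arm)
        assert per_week[-1][1].log10_td50 == pytest.approx(endpoint_est.log10_td50)

    def test_constant_after_events_stop(self):
        series = self._series()
        per_week = td50_series(series)
        # positives all appear by week 4; estimates identical thereafter
        assert per_week[1][1].log10_td50 == pytest.approx(per_week[2][1].log10_td50)

    def test_non_increasing_in_week(self):
        for seed in range(10):
            series = simulate_assay(AssaySimConfig(seed=seed))
            values = [
                est.log10_td50 for _, est in td50_series(series) if est.applicable
            ]
            assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_zero_positive_weeks_not_applicable(self):
        arm = make_arm((1e2, 1e3), 5, (0, 2))
        cum = np.array([[0, 0], [0, 2]])
        series = IncidenceSeries(arm=arm, weeks=(2.0, 4.0), cumulative_positive=cum)
        per_week = td50_series(series)
        assert not per_week[0][1].applicable
        assert per_week[1][1].applicable


class TestMinimumPositiveDose:
    def test_smallest_dose_with_a_positive(self):
        assert minimum_positive_dose(make_arm((1e2, 1e3, 1e4), 5, (0, 1, 5))) == 1000

    def test_all_negative_returns_none(self, all_negative_arm):
        assert minimum_positive_dose(all_negative_arm) is None


def test_not_applicable_constructor_round_trip():
    est = Td50Estimate.not_applicable("spearman_karber", "no positives")
    assert not est.applicable and math.isnan(est.log10_td50)
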