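"""Tumor volumes, growth times, delay metrics, Bliss rate and combination index."""

import math

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from radsyn.assay_io import RunConfig
from radsyn.growth import (
    EXACT_ELLIPSOID_CONSTANT,
    TumorTrajectory,
    bliss_expected_rate,
    classify_combination_index,
    combination_index,
    growth_summaries,
    growth_time,
    summarize_growth_times,
    tumor_volume,
    volume_inhibition_rate,
)


class TestTumorVolume:
    def test_printed_constant(self):
        assert tumor_volume(10, 10, 10) == pytest.approx(523.0)

    def test_zero_dimension_gives_zero(self):
        assert tumor_volume(0, 5, 5) == 0.0

    def test_exact_ellipsoid_constant(self):
        # (4/3)*pi*5^3 for a 10 mm sphere
        v = tumor_volume(10, 10, 10, EXACT_ELLIPSOID_CONSTANT)
        assert v == pytest.approx(4.0 / 3.0 * math.pi * 125.0, rel=1e-12)

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError):
            tumor_volume(-1, 5, 5)


def _traj(days, volumes, group="control", animal="a1"):
    return TumorTrajectory(
        animal_id=animal, group=group, days=tuple(days),
        volumes_mm3=tuple(volumes),
    )


class TestGrowthTime:
    def test_first_observation_at_threshold_returns_its_day(self):
        res = growth_time(_traj([0, 7], [500, 900]), 400)
        assert res.days == 0 and not res.censored

    def test_log_linear_interpolation_hand_value(self):
        res = growth_time(_traj([7, 14], [200, 800]), 400)
        assert res.days == pytest.approx(10.5)

    def test_never_reaching_threshold_is_censored(self):
        res = growth_time(_traj([0, 7, 14], [100, 150, 200]), 400)
        assert res.censored

    @given(
        thr_pair=st.tuples(
            st.floats(150, 3000), st.floats(150, 3000)
        )
    )
    def test_monotone_in_threshold(self, thr_pair):
        lo, hi = sorted(thr_pair)
        traj = _traj([0, 5, 10, 15], [100, 300, 900, 2700])
        t_lo = growth_time(traj, lo)
        t_hi = growth_time(traj, hi)
        assume(not t_lo.censored and not t_hi.censored)
        assert t_lo.days <= t_hi.days


class TestGrowthSummaries:
    GROUP_TIMES = {
        "control": [9.0],
        "drug": [12.0],
        "radiation": [16.0],
        "combination": [25.0],
    }

    def test_printed_mode_reproduces_delay_table(self):
        s = summarize_growth_times(self.GROUP_TIMES, "printed")
        assert s["drug"].delay_time == 3
        assert s["radiation"].delay_time == 7
        assert s["combination"].delay_time == 16
        assert s["drug"].time_ratio_rate == 1.33
        assert s["radiation"].time_ratio_rate == 1.78
        assert s["combination"].time_ratio_rate == 2.78
        assert s["combination"].enhancement_ratios["drug"] == 2.09
        assert s["combination"].enhancement_ratios["radiation"] == 1.56

    def test_full_precision_close_to_printed(self):
        """Full-precision outputs differ from printed ones by <= 0.02."""
        printed = summarize_growth_times(self.GROUP_TIMES, "printed")
        full = summarize_growth_times(self.GROUP_TIMES, "full")
        for g in ("drug", "radiation", "combination"):
            assert abs(
                full[g].time_ratio_rate - printed[g].time_ratio_rate
            ) <= 0.02
        for comparator, er in full["combination"].enhancement_ratios.items():
            assert abs(
                er - printed["combination"].enhancement_ratios[comparator]
            ) <= 0.02

    def test_control_vs_itself_is_null(self):
        s = summarize_growth_times({"control": [9.0, 11.0]})
        assert s["control"].delay_time is None
        assert s["control"].time_ratio_rate == 1.0

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            summarize_growth_times({"drug": [12.0]})

    def test_censored_animals_excluded_from_means(self):
        trajs = [
            _traj([0, 20], [100, 800], "control", "c1"),
            _traj([0, 20], [100, 900], "drug", "d1"),
            _traj([0, 20], [100, 200], "drug", "d2"),  # never reaches 400
        ]
        s = growth_summaries(trajs, RunConfig())
        assert s["drug"].n == 1
        assert s["drug"].n_censored == 1


class TestVolumeInhibition:
    def test_day26_volumes_give_78_percent(self):
        assert volume_inhibition_rate(490, 2200, "printed") == 78

    def test_equal_volumes_give_zero(self):
        assert volume_inhibition_rate(1000, 1000) == 0.0

    def test_growth_promotion_is_negative(self):
        assert volume_inhibition_rate(1200, 1000) < 0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            volume_inhibition_rate(100, 0)


class TestBlissExpectedRate:
    def test_printed_mode_table_value(self):
        assert bliss_expected_rate(33, 54, "printed") == 69

    def test_null_agent_identity(self):
        assert bliss_expected_rate(0, 37.5) == pytest.approx(37.5)

    def test_saturation(self):
        assert bliss_expected_rate(100, 42) == pytest.approx(100.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bliss_expected_rate(-1, 50)
        with pytest.raises(ValueError):
            bliss_expected_rate(50, 101)

    @given(ra=st.floats(0, 100), rb=st.floats(0, 100))
    def test_symmetric_and_equal_to_complement_product(self, ra, rb):
        e1 = bliss_expected_rate(ra, rb)
        e2 = bliss_expected_rate(rb, ra)
        assert e1 == pytest.approx(e2, abs=1e-9)
        fa, fb = ra / 100.0, rb / 100.0
        assert e1 / 100.0 == pytest.approx(1 - (1 - fa) * (1 - fb), abs=1e-12)


class TestCombinationIndex:
    def test_printed_mode_table_value(self):
        assert combination_index(78, 69, "printed") == 0.71

    def test_observed_equal_expected_is_unity(self):
        assert combination_index(42.0, 42.0) == pytest.approx(1.0)

    def test_antagonistic_hand_value(self):
        ci = combination_index(50, 75)
        assert ci == pytest.approx(2.0)
        assert classify_combination_index(ci) == "antagonism"

    def test_expected_100_percent_undefined(self):
        with pytest.raises(ValueError):
            combination_index(90, 100)

    def test_verdict_tiers(self):
        assert classify_combination_index(0.71) == "synergism"
        assert classify_combination_index(1.0) == "additivity"
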