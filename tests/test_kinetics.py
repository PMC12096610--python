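"""Release-curve validation, interval rates and unit handling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnsync import (
    ReleaseCurve,
    convert_units,
    interval_rate,
    rate_series,
    summarize_replicates,
    validate_curve,
)
from cnsync.kinetics import CurveError, NegativeRateWarning
from cnsync.units import UnitConversionError
from conftest import make_curve


class TestValidateCurve:
    def test_monotone_curve_passes_without_warnings(self, simple_curve):
        curve, warnings_out = validate_curve(simple_curve)
        assert curve is simple_curve
        assert warnings_out == []

    def test_fluctuating_curve_warns_naming_the_interval(self):
        curve = make_curve([0, 12, 30, 30, 28],
                           times=(0, 20, 60, 240, 360))
        _, warnings_out = validate_curve(curve)
        assert len(warnings_out) == 1
        assert "240-360" in warnings_out[0]

    @pytest.mark.parametrize("values,times,message", [
        ([0, -1, 5], (0, 20, 60), "negative cumulative"),
        ([0, 5, 6], (0, 60, 20), "strictly increasing"),
        ([0, 5, 6], (0, 20, 20), "strictly increasing"),
    ])
    def test_structural_defects_are_hard_errors(self, values, times, message):
        with pytest.raises(CurveError, match=message):
            validate_curve(make_curve(values, times=times))

    def test_unknown_nutrient_rejected(self):
        with pytest.raises(CurveError, match="nutrient"):
            validate_curve(make_curve([0, 1, 2], nutrient="starch"))


class TestIntervalRate:
    def test_hand_computed_rate(self, simple_curve):
        assert interval_rate(simple_curve, 0, 20) == pytest.approx(0.6)

    def test_flat_segment_gives_zero(self):
        curve = make_curve([5.0, 5.0], times=(20, 60))
        assert interval_rate(curve, 20, 60) == 0.0

    def test_negative_rate_flagged_not_clipped(self):
        curve = make_curve([0, 30, 28], times=(0, 240, 360))
        with pytest.warns(NegativeRateWarning):
            k = interval_rate(curve, 240, 360)
        assert k == pytest.approx(-2 / 120)

    def test_baseline_is_measured_not_assumed_zero(self):
        # D at the interval start is whatever was measured there
        curve = make_curve([10.0, 22.0], times=(0, 20))
        assert interval_rate(curve, 0, 20) == pytest.approx(0.6)

    def test_unsampled_time_errors_unless_interpolating(self, simple_curve):
        with pytest.raises(CurveError, match="not sampled"):
            interval_rate(simple_curve, 0, 30)
        k = interval_rate(simple_curve, 0, 30, interpolate=True)
        # linear between 20 and 60: D(30) = 12 + 18/4 = 16.5
        assert k == pytest.approx(16.5 / 30)

    def test_reversed_interval_errors(self, simple_curve):
        with pytest.raises(CurveError, match="t1 < t2"):
            interval_rate(simple_curve, 20, 20)

    def test_cross_phase_rate_disallowed(self):
        curve = ReleaseCurve(
            substrate_id="d", nutrient="soluble_nitrogen", replicate=1,
            phases=("gastric", "gastric", "intestinal", "intestinal"),
            times=np.array([60.0, 120.0, 0.0, 20.0]),
            cumulative=np.array([1.0, 2.0, 2.5, 4.0]), unit="g/kg",
        )
        # each phase runs on its own clock; only within-phase rates exist
        assert interval_rate(curve, 60, 120, phase="gastric") == pytest.approx(
            1 / 60)
        with pytest.raises(CurveError):
            interval_rate(curve, 120, 20, phase="intestinal")

    @given(d1=st.floats(0, 1e3), d2=st.floats(0, 1e3))
    def test_swapping_endpoint_values_negates_rate(self, d1, d2):
        a = make_curve([d1, d2], times=(0, 20))
        b = make_curve([d2, d1], times=(0, 20))
        ka = interval_rate(a, 0, 20, warn_negative=False)
        kb = interval_rate(b, 0, 20, warn_negative=False)
        assert ka == pytest.approx(-kb, abs=1e-12)


class TestRateSeries:
    def test_consecutive_rates_in_order(self, simple_curve):
        rs = rate_series(simple_curve, [0, 20, 60])
        assert rs.rates == pytest.approx([0.6, 0.45])
        assert rs.intervals == ((0, 20), (20, 60))

    def test_single_interval_and_constant_curve(self):
        rs = rate_series(make_curve([3.0, 7.0], times=(0, 20)), [0, 20])
        assert len(rs) == 1
        rs2 = rate_series(make_curve([5.0] * 3), [0, 20, 60])
        assert np.all(rs2.rates == 0)

    def test_grid_not_subset_errors(self, simple_curve):
        with pytest.raises(CurveError, match="not sampled"):
            rate_series(simple_curve, [0, 30, 60])

    def test_telescoping_identity(self, full_schedule_curve):
        curve = full_schedule_curve
        grid = curve.times.tolist()
        rs = rate_series(curve, grid)
        widths = np.diff(grid)
        total = float(np.sum(rs.rates * widths))
        expected = curve.cumulative[-1] - curve.cumulative[0]
        assert total == pytest.approx(expected, rel=1e-12)

    def test_negative_rates_flagged_in_series(self):
        curve = make_curve([0, 30, 28], times=(0, 240, 360))
        rs = rate_series(curve, [0, 240, 360])
        assert rs.negative_flags.tolist() == [False, True]


class TestSummarizeReplicates:
    def test_identical_replicates_have_zero_sem(self):
        reps = [make_curve([10, 10, 10], replicate=i) for i in (1, 2, 3)]
        summary = summarize_replicates(reps)
        assert np.all(summary.sem == 0)
        assert summary.curve.cumulative == pytest.approx([10, 10, 10])

    def test_hand_computed_sem(self):
        reps = [make_curve([0, v, 30], replicate=i)
                for i, v in enumerate((9, 10, 11), start=1)]
        summary = summarize_replicates(reps)
        assert summary.curve.cumulative[1] == pytest.approx(10.0)
        assert summary.sem[1] == pytest.approx(1 / np.sqrt(3), rel=1e-6)

    def test_single_replicate_errors(self, simple_curve):
        with pytest.raises(CurveError, match="at least two"):
            summarize_replicates([simple_curve])

    def test_mismatched_grids_error(self, simple_curve):
        other = make_curve([0, 12, 30], times=(0, 20, 90), replicate=2)
        with pytest.raises(CurveError, match="sampling grid"):
            summarize_replicates([simple_curve, other])


class TestConvertUnits:
    def test_per_100g_to_per_kg_is_factor_ten(self):
        curve = make_curve([5.0, 8.0], times=(0, 20), unit="g/100g")
        converted = convert_units(curve, "g/kg")
        assert converted.cumulative == pytest.approx([50.0, 80.0])
        assert converted.unit == "g/kg"

    def test_round_trip_identity_is_exact(self, simple_curve):
        back = convert_units(convert_units(simple_curve, "g/100g"), "g/kg")
        assert np.array_equal(back.cumulative, simple_curve.cumulative)

    def test_undefined_pair_errors(self):
        curve = make_curve([1.0, 2.0], times=(0, 20), unit="mmol/kg",
                           nutrient="total_amino_acids")
        with pytest.raises(UnitConversionError):
            convert_units(curve, "g/kg")

    def test_conversion_commutes_with_rate(self, simple_curve):
        k_then_scale = interval_rate(simple_curve, 0, 20) / 10
        scale_then_k = interval_rate(
            convert_units(simple_curve, "g/100g"), 0, 20)
        assert k_then_scale == pytest.approx(scale_then_k, rel=1e-12)
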