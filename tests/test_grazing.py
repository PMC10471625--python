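"""Consumption-based pasture allocation versus the full-flow baseline."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from emfarm.grazing import (
    GrazingParameters,
    grazed_area,
    grazing_emergy,
    natural_pastures_emergy,
    standard_pastures_emergy,
)
from emfarm.natural import GIBBS_RAIN_J_G, HA_TO_M2, WATER_DENSITY_G_M3


class TestGrazedArea:
    def test_survey_mean_herd(self):
        assert grazed_area(72.8, 0.2) == pytest.approx(364.0)

    def test_zero_herd(self):
        assert grazed_area(0.0, 0.2) == 0.0

    def test_unit_case(self):
        assert grazed_area(1.2, 1.2) == pytest.approx(1.0)

    def test_zero_stocking_rate_rejected(self):
        with pytest.raises(ValueError):
            grazed_area(10.0, 0.0)


class TestGrazingEmergy:
    def test_no_grazing_no_allocation(self, grazing_params):
        assert grazing_emergy(1e16, 0.0, grazing_params, "meadows_forests") == 0.0

    def test_half_year_meadows(self, grazing_params):
        allocated = grazing_emergy(1e16, 182.5, grazing_params, "meadows_forests")
        assert allocated == pytest.approx(1e16 * 0.5 * 0.5 * 0.65)
        assert allocated == pytest.approx(1.625e15)

    def test_full_allocation_upper_bound(self):
        params = GrazingParameters(
            anpp_fraction=1.0,
            consumed_fraction_meadows_forests=1.0,
            consumed_fraction_mountain=1.0,
        )
        assert grazing_emergy(1e16, 365.0, params, "mountain") == pytest.approx(1e16)

    def test_days_beyond_year_rejected(self, grazing_params):
        with pytest.raises(ValueError):
            grazing_emergy(1e16, 400.0, grazing_params, "mountain")

    def test_division_form_inflates(self, grazing_params):
        """The published divided form awards more emergy for less grazing —
        the reason it is audit-only."""
        short = grazing_emergy(1e16, 36.5, grazing_params, "mountain", division_form=True)
        long = grazing_emergy(1e16, 365.0, grazing_params, "mountain", division_form=True)
        assert short > long > 1e16

    @given(days=st.floats(min_value=0.1, max_value=364.9))
    def test_monotone_in_days(self, days):
        params = GrazingParameters()
        lo = grazing_emergy(1e16, days, params, "meadows_forests")
        hi = grazing_emergy(1e16, days + 0.1, params, "meadows_forests")
        assert hi > lo


class TestNaturalPasturesEmergy:
    def test_zero_grazing_days_allocates_nothing(self, worked_farm, climate, grazing_params, uev):
        farm = worked_farm.model_copy(
            update={
                "calendar": worked_farm.calendar.model_copy(
                    update={"days_meadows_forests": 0.0, "days_mountain_pastures": 0.0}
                )
            }
        )
        pe = natural_pastures_emergy(farm, climate, grazing_params, uev)
        assert pe.total_allocated == 0.0

    def test_symmetric_farm_equal_allocations(self, worked_farm, climate, uev):
        params = GrazingParameters(
            stocking_rate_meadows_forests=1.0,
            stocking_rate_mountain=1.0,
            consumed_fraction_meadows_forests=0.5,
            consumed_fraction_mountain=0.5,
        )
        farm = worked_farm.model_copy(
            update={
                "calendar": worked_farm.calendar.model_copy(
                    update={"days_meadows_forests": 120.0, "days_mountain_pastures": 120.0}
                )
            }
        )
        pe = natural_pastures_emergy(farm, climate, params, uev)
        assert pe.allocated_meadows_forests == pytest.approx(pe.allocated_mountain)

    def test_fixture_farm_matches_hand_recomputation(
        self, worked_farm, climate, grazing_params, uev
    ):
        """Brute-force recomputation of both allocation terms outside the
        pipeline, from the raw constants."""
        lu = 74.0  # 50 + 1 + 10*0.7 + 40*0.4
        rain_sej_per_ha = (
            HA_TO_M2
            * climate.rainfall_m
            * WATER_DENSITY_G_M3
            * GIBBS_RAIN_J_G
            * uev["rain_chemical_potential"].uev_value
        )
        e_mf = (lu / 0.2) * rain_sej_per_ha
        e_mp = (lu / 1.2) * rain_sej_per_ha
        expected = (
            e_mf * (150.0 / 365.0) * 0.5 * 0.65
            + e_mp * (100.0 / 365.0) * 0.5 * 0.40
        )
        pe = natural_pastures_emergy(worked_farm, climate, grazing_params, uev)
        assert pe.e_meadows_forests == pytest.approx(e_mf, rel=1e-9)
        assert pe.e_mountain == pytest.approx(e_mp, rel=1e-9)
        assert pe.total_allocated == pytest.approx(expected, rel=1e-9)


class TestStandardBaseline:
    def test_standard_bounds_allocated(self, worked_farm, climate, grazing_params, uev):
        pe = natural_pastures_emergy(worked_farm, climate, grazing_params, uev)
        standard = standard_pastures_emergy(worked_farm, climate, grazing_params, uev)
        assert pe.total_allocated <= standard

    def test_ratio_is_scale_invariant_identity(
        self, worked_farm, climate, grazing_params, uev
    ):
        """allocated/standard equals the day-length x ANPP x consumption
        factors combined across areas, independent of E's magnitude."""
        pe = natural_pastures_emergy(worked_farm, climate, grazing_params, uev)
        standard = standard_pastures_emergy(worked_farm, climate, grazing_params, uev)
        w_mf = pe.e_meadows_forests / standard
        w_mp = pe.e_mountain / standard
        expected_ratio = (
            w_mf * (150.0 / 365.0) * 0.5 * 0.65 + w_mp * (100.0 / 365.0) * 0.5 * 0.40
        )
        assert pe.total_allocated / standard == pytest.approx(expected_ratio, rel=1e-9)
        # and under a doubled-rainfall climate the ratio is unchanged
        wetter = climate.model_copy(update={"rainfall_m": 2 * climate.rainfall_m})
        pe2 = natural_pastures_emergy(worked_farm, wetter, grazing_params, uev)
        standard2 = standard_pastures_emergy(worked_farm, wetter, grazing_params, uev)
        assert pe2.total_allocated / standard2 == pytest.approx(
            pe.total_allocated / standard, rel=1e-9
        )

    def test_zero_herd_farm_is_zero(self, worked_farm, climate, grazing_params, uev):
        farm = worked_farm.model_copy(
            update={"herd": worked_farm.herd.model_copy(
                update={"cows": 0, "bulls": 0, "heifers": 0, "calves": 0}
            )}
        )
        assert standard_pastures_emergy(farm, climate, grazing_params, uev) == 0.0

    def test_unused_area_excluded_from_baseline(
        self, worked_farm, climate, grazing_params, uev
    ):
        """An area enters the comparison baseline only when the calendar
        actually uses it."""
        farm = worked_farm.model_copy(
            update={
                "calendar": worked_farm.calendar.model_copy(
                    update={"days_mountain_pastures": 0.0}
                )
            }
        )
        pe = natural_pastures_emergy(farm, climate, grazing_params, uev)
        standard = standard_pastures_emergy(farm, climate, grazing_params, uev)
        assert standard == pytest.approx(pe.e_meadows_forests)
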