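"""Daily/seasonal/annual N-budget upscaling and zero-rate screening."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crustfix import (
    BudgetConfig,
    annual_budget,
    daily_rate,
    fertilizer_fraction,
    percent_of_annual_n,
    screen_active,
)
from crustfix.errors import BudgetError

SEASONS = ("Summer", "Fall", "Winter", "Spring")


class TestDailyRate:
    def test_lower_endpoint(self):
        assert daily_rate(0.6, 10.0) == pytest.approx(6.0)

    def test_upper_endpoint(self):
        # 137 umol / 1.2 x 28/1000 x 10 h -> ~32 mg N m-2 d-1
        hourly = 137.0 / 1.2 * 28.0 / 1000.0
        assert daily_rate(hourly, 10.0) == pytest.approx(32.0, abs=0.1)

    def test_zero(self):
        assert daily_rate(0.0, 10.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(BudgetError):
            daily_rate(-1.0, 10.0)


class TestAnnualBudget:
    def test_constant_rate_oracle(self):
        # 17.53 mg m-2 d-1 x 365 d x 1e-2 = 63.98 kg ha-1 yr-1 at full coverage
        budget = annual_budget({s: 17.53 for s in SEASONS})
        assert budget.annual_full_coverage_kg_ha_yr == pytest.approx(63.98, abs=0.02)

    def test_all_zero_seasons(self):
        budget = annual_budget({s: 0.0 for s in SEASONS})
        assert budget.annual_full_coverage_kg_ha_yr == 0.0

    def test_coverage_scaling_reproduces_field_scale(self):
        # 39 kg at full coverage x 0.125 -> 4.875 ~ 4.9 kg N ha-1 yr-1
        rate = 39.0 / 365.0 * 100.0  # mg m-2 d-1 giving 39 kg/yr
        budget = annual_budget({s: rate for s in SEASONS})
        assert budget.annual_at_coverage_kg_ha_yr == pytest.approx(4.875, abs=0.001)
        assert round(budget.annual_at_coverage_kg_ha_yr, 1) == 4.9

    def test_coverage_ratio_exact(self):
        budget = annual_budget({s: 5.0 for s in SEASONS}, BudgetConfig(coverage_fraction=0.2))
        ratio = budget.annual_at_coverage_kg_ha_yr / budget.annual_full_coverage_kg_ha_yr
        assert ratio == pytest.approx(0.2, rel=1e-12)

    def test_missing_season_errors_by_default(self):
        with pytest.raises(BudgetError):
            annual_budget({"Summer": 5.0})

    def test_missing_season_zero_policy(self):
        budget = annual_budget(
            {"Summer": 4.0}, BudgetConfig(missing_season_policy="zero")
        )
        assert budget.annual_full_coverage_kg_ha_yr == pytest.approx(4.0 * 91.25 * 1e-2)

    def test_missing_season_carry_nearest(self):
        budget = annual_budget(
            {"Summer": 4.0, "Winter": 2.0},
            BudgetConfig(missing_season_policy="carry-nearest"),
        )
        # Fall takes Summer's 4 (nearer), Spring takes Winter's 2
        assert budget.seasonal_daily_mg_m2_d["Fall"] == 4.0
        assert budget.seasonal_daily_mg_m2_d["Spring"] == 2.0

    def test_negative_rate_rejected(self):
        with pytest.raises(BudgetError):
            annual_budget({"Summer": -1.0}, BudgetConfig(missing_season_policy="zero"))

    def test_season_lengths_must_sum_to_year(self):
        with pytest.raises(ValueError):
            BudgetConfig(season_length_days=80.0)

    @settings(deadline=None, derandomize=True)
    @given(
        rate=st.floats(0.0, 50.0),
        coverage=st.floats(0.01, 1.0),
        light=st.floats(1.0, 24.0),
        scale=st.floats(0.1, 5.0),
    )
    def test_linearity_in_coverage_and_light_hours(self, rate, coverage, light, scale):
        config = BudgetConfig(coverage_fraction=coverage, light_hours_per_day=light)
        daily = {s: daily_rate(rate, light) for s in SEASONS}
        budget = annual_budget(daily, config)
        scaled_daily = {s: daily_rate(rate * scale, light) for s in SEASONS}
        scaled = annual_budget(scaled_daily, config)
        assert scaled.annual_at_coverage_kg_ha_yr == pytest.approx(
            budget.annual_at_coverage_kg_ha_yr * scale, rel=1e-9, abs=1e-12
        )
        # linear in light hours at fixed hourly rate
        assert daily_rate(rate, light) == pytest.approx(rate * light, rel=1e-12)


class TestFertilizerComparison:
    def test_daily_vs_application(self):
        assert fertilizer_fraction(32.0, 4.0) == pytest.approx(0.8)

    def test_zero_input(self):
        assert fertilizer_fraction(0.0, 4.0) == 0.0

    def test_boundary_one_percent(self):
        assert fertilizer_fraction(40.0, 4.0) == pytest.approx(1.0)

    def test_percent_of_annual(self):
        assert percent_of_annual_n(4.9, 35.0) == pytest.approx(14.0)
        assert percent_of_annual_n(7.0, 7.0) == 100.0
        assert percent_of_annual_n(0.0, 10.0) == 0.0


class TestScreenActive:
    @staticmethod
    def frame(rates, site="Grape"):
        return pd.DataFrame({"site": site, "areal_rate_umol_m2_h": rates})

    def test_zero_filter_counts(self):
        records = self.frame([0.0, 0.0, 0.0] + [1.0] * 21)
        kept, counts = screen_active(records)
        assert len(kept) == 21 and counts == {"Grape": 21}

    def test_no_zeros_is_identity(self):
        records = self.frame([1.0, 2.0])
        kept, counts = screen_active(records)
        assert len(kept) == 2 and counts == {"Grape": 2}

    def test_all_zeros_empty(self):
        kept, counts = screen_active(self.frame([0.0, 0.0]))
        assert len(kept) == 0 and counts == {"Grape": 0}

    def test_below_detection_flag_respected(self):
        records = self.frame([1.0, 2.0])
        records["below_detection"] = [False, True]
        kept, counts = screen_active(records)
        assert len(kept) == 1
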