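"""Fumigation-extraction pools, stoichiometric ratios, and moisture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crustfix import (
    ExtractPair,
    extract_to_soil_basis,
    gravimetric_moisture,
    microbial_pool,
    pool_moisture_for_comparison,
    stoichiometric_ratios,
)
from crustfix.errors import CrustfixError


class TestSoilBasis:
    def test_worked_example(self):
        # 10 mg/L x 25 mL on 1 g soil -> 250 mg/kg
        assert extract_to_soil_basis(10.0, 25.0, 1.0) == pytest.approx(250.0)

    def test_zero_concentration(self):
        assert extract_to_soil_basis(0.0, 25.0, 1.0) == 0.0

    def test_soil_mass_halves_result(self):
        assert extract_to_soil_basis(10.0, 25.0, 2.0) == pytest.approx(125.0)


def pair(analyte, flush_mg_kg, unfum_mg_kg=100.0, volume=25.0, mass=1.0, **kw):
    """Build an ExtractPair from soil-basis flush/unfumigated values."""
    conc = mass / volume  # mg/kg -> mg/L for this extraction ratio
    return ExtractPair(
        analyte=analyte,
        fumigated_conc_mg_l=(unfum_mg_kg + flush_mg_kg) * conc,
        unfumigated_conc_mg_l=unfum_mg_kg * conc,
        extract_volume_ml=volume,
        soil_dry_mass_g=mass,
        **kw,
    )


class TestMicrobialPool:
    def test_carbon_efficiency(self):
        # 500 mg/kg flush / 0.37 = 1351.35 mg/kg MBC
        result = microbial_pool(pair("C", 500.0))
        assert result.microbial_pool_mg_kg == pytest.approx(1351.35, abs=0.01)
        assert result.efficiency_used == 0.37

    def test_nitrogen_efficiency(self):
        # 54 mg/kg flush / 0.54 = 100 mg/kg MBN
        result = microbial_pool(pair("N", 54.0))
        assert result.microbial_pool_mg_kg == pytest.approx(100.0)

    def test_phosphorus_no_adjustment(self):
        result = microbial_pool(pair("P", 30.0))
        assert result.microbial_pool_mg_kg == pytest.approx(30.0)
        assert result.efficiency_used == 1.0

    def test_equal_pair_is_zero_pool(self):
        result = microbial_pool(pair("N", 0.0))
        assert result.microbial_pool_mg_kg == 0.0
        assert not result.microbial_not_detected

    def test_negative_flush_not_detected(self):
        result = microbial_pool(pair("C", -50.0))
        assert np.isnan(result.microbial_pool_mg_kg)
        assert result.microbial_not_detected

    def test_flush_below_detection_limit_not_detected(self):
        p = pair("P", 0.1)  # flush conc = 0.004 mg/L < 0.01 mg/L limit
        result = microbial_pool(p)
        assert result.microbial_not_detected

    def test_unknown_analyte_rejected(self):
        with pytest.raises(CrustfixError):
            ExtractPair(analyte="S", fumigated_conc_mg_l=1.0, unfumigated_conc_mg_l=0.5)

    def test_extractable_pool_is_unfumigated(self):
        result = microbial_pool(pair("C", 500.0, unfum_mg_kg=420.0))
        assert result.extractable_pool_mg_kg == pytest.approx(420.0)

    @settings(deadline=None, derandomize=True)
    @given(flush=st.floats(10.0, 5000.0), scale=st.floats(0.5, 10.0))
    def test_linearity_and_k_inversion(self, flush, scale):
        """Pool is linear in the flush, and multiplying the pool back by k
        recovers the flush exactly."""
        one = microbial_pool(pair("C", flush)).microbial_pool_mg_kg
        scaled = microbial_pool(pair("C", flush * scale)).microbial_pool_mg_kg
        assert scaled == pytest.approx(one * scale, rel=1e-9)
        assert one * 0.37 == pytest.approx(flush, rel=1e-9)


def make_pools(n=10, n_p_bdl=0):
    """A pools frame with identical values and a chosen number of MBP BDLs."""
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "site": "Grape",
            "season": "Summer",
            "sample_type": "biocrust",
            "mbc": 1800.0,
            "mbn": 100.0,
            "mbp": 20.0,
            "ec": 400.0,
            "en": 50.0,
            "ep": 100.0,
        }
    )
    for col in ("mbc", "mbn", "mbp", "ec", "en", "ep"):
        df[f"{col}_bdl"] = False
    df.loc[: n_p_bdl - 1, "mbp_bdl"] = n_p_bdl > 0
    return df


class TestRatios:
    def test_simple_division(self):
        report = stoichiometric_ratios(make_pools())
        assert report.per_sample["MBC:MBN"].iloc[0] == pytest.approx(18.0)

    def test_family_excluded_above_threshold(self):
        # 4 of 10 MBP below detection > 30% threshold
        report = stoichiometric_ratios(make_pools(10, n_p_bdl=4), bdl_threshold=0.30)
        excluded = {e["family"] for e in report.excluded_ratio_families}
        assert excluded == {"MBC:MBP", "MBN:MBP"}
        assert "MBC:MBP" not in report.per_sample.columns

    def test_exclusion_strictly_greater_than_threshold(self):
        report = stoichiometric_ratios(make_pools(10, n_p_bdl=3), bdl_threshold=0.30)
        assert report.excluded_ratio_families == []

    def test_group_summary_of_identical_samples(self):
        report = stoichiometric_ratios(make_pools())
        row = report.summary.iloc[0]
        assert row["EC:EN_mean"] == pytest.approx(8.0)
        assert row["EC:EN_std"] == pytest.approx(0.0)

    def test_bdl_denominator_sample_omitted(self):
        pools = make_pools(10, n_p_bdl=2)  # 20%: family kept, samples dropped
        report = stoichiometric_ratios(pools)
        assert report.per_sample["MBC:MBP"].isna().sum() == 2


class TestMoisture:
    def test_per_dry_basis(self):
        assert gravimetric_moisture(1.5, 1.0) == pytest.approx(50.0)

    def test_equal_masses_zero(self):
        assert gravimetric_moisture(1.0, 1.0) == 0.0

    def test_reported_maximum(self):
        assert gravimetric_moisture(1.78, 1.0) == pytest.approx(78.0)

    def test_per_wet_basis(self):
        assert gravimetric_moisture(2.0, 1.0, basis="wet") == pytest.approx(50.0)

    def test_wet_below_dry_rejected(self):
        with pytest.raises(ValueError):
            gravimetric_moisture(0.9, 1.0)


class TestMoisturePooling:
    def test_seasonal_pools_both_types(self):
        pooled = pool_moisture_for_comparison([1.0] * 6, [2.0] * 6, mode="seasonal")
        assert len(pooled) == 12
        assert pooled.mean() == pytest.approx(1.5)

    def test_multivariate_is_biocrust_only(self):
        series = pool_moisture_for_comparison([1.0] * 6, [2.0] * 6, mode="multivariate")
        assert len(series) == 6 and set(series) == {1.0}

    def test_all_equal_inputs(self):
        pooled = pool_moisture_for_comparison([3.0] * 4, [3.0] * 4)
        assert pooled.mean() == 3.0

    def test_unpaired_warns_but_pools(self):
        with pytest.warns(UserWarning):
            pooled = pool_moisture_for_comparison([1.0] * 6, [2.0] * 5)
        assert len(pooled) == 11
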