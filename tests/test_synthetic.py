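"""Synthetic campaign generator: determinism, mean recovery, censoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from crustfix import CampaignConfig, default_params, generate_campaign, noiseless
from crustfix.ara import rates_from_tables
from crustfix.errors import ConfigurationError
from crustfix.synthetic import CALIBRATION_DESIGN, Normal

TABLES = ("samples", "jars", "gc", "isotope", "extracts", "environment")


class TestDefaultParams:
    def test_grape_summer_ep_mean(self):
        assert default_params()[("Grape", "Summer")].ep.mean == 156.33

    def test_citrus_winter_soil_temp(self):
        assert default_params()[("Citrus", "Winter")].soil_temp_c.mean == 24.45

    def test_all_sds_nonnegative(self):
        for params in default_params().values():
            for name, value in params:
                if isinstance(value, Normal):
                    assert value.sd >= 0.0

    def test_every_site_season_covered(self):
        assert set(default_params()) == {
            (site, season)
            for site in ("Grape", "Citrus")
            for season in ("Summer", "Fall", "Winter", "Spring")
        }

    def test_grape_rates_decrease_citrus_increase(self):
        params = default_params()
        grape = [params[("Grape", s)].areal_ethylene_umol_m2_h
                 for s in ("Summer", "Fall", "Winter", "Spring")]
        assert grape == sorted(grape, reverse=True)
        citrus = params[("Citrus", "Spring")].areal_ethylene_umol_m2_h
        assert citrus > params[("Citrus", "Summer")].areal_ethylene_umol_m2_h


class TestDeterminism:
    def test_same_seed_bitwise_identical(self, tmp_path):
        a = generate_campaign(CampaignConfig(seed=1)).to_dir(tmp_path / "a")
        b = generate_campaign(CampaignConfig(seed=1)).to_dir(tmp_path / "b")
        for name in TABLES:
            assert (a / f"{name}.csv").read_bytes() == (b / f"{name}.csv").read_bytes()

    def test_different_seed_differs(self):
        one = generate_campaign(CampaignConfig(seed=1))
        two = generate_campaign(CampaignConfig(seed=2))
        assert not one.gc["sample_peak"].equals(two.gc["sample_peak"])


class TestStructure:
    def test_design_dimensions(self):
        camp = generate_campaign(CampaignConfig(seed=0))
        # 2 sites x 4 seasons x 6 plots x 2 types x 3 cores = 288 jars
        assert len(camp.jars) == 288
        assert len(camp.gc) == 288
        assert len(camp.environment) == 48
        # extracts: 96 pooled samples x 3 analytes
        assert len(camp.extracts) == 288

    def test_isotope_only_in_calibration_seasons(self):
        camp = generate_campaign(CampaignConfig(seed=0))
        iso = camp.isotope.merge(camp.samples, on="sample_id")
        cells = set(zip(iso["site"], iso["season"]))
        assert cells == set(CALIBRATION_DESIGN)
        grape = iso[(iso.site == "Grape")]
        assert (grape.sample_type == "biocrust").sum() == 3
        assert (grape.sample_type == "bare").sum() == 3
        citrus = iso[(iso.site == "Citrus")]
        assert (citrus.sample_type == "biocrust").sum() == 2 and len(citrus) == 2

    def test_every_jar_links_to_a_sample(self):
        camp = generate_campaign(CampaignConfig(seed=0))
        assert camp.jars["sample_id"].isin(camp.samples["sample_id"]).all()

    def test_empty_campaign(self, tmp_path):
        camp = generate_campaign(CampaignConfig(seed=0, plots_per_site=0))
        for name in TABLES:
            df = getattr(camp, name)
            assert len(df) == 0 and len(df.columns) > 0
        path = camp.to_dir(tmp_path / "empty")
        assert pd.read_csv(path / "jars.csv", comment="#").empty

    def test_missing_site_season_params_named(self):
        params = default_params()
        del params[("Citrus", "Winter")]
        with pytest.raises(ConfigurationError, match="Citrus"):
            generate_campaign(CampaignConfig(seed=0), params)


class TestNoiseless:
    def test_rates_equal_configured_mean(self):
        config = CampaignConfig(
            seed=5, gc_noise_cv=0.0,
            dry_mass_g=Normal(mean=4.9, sd=0.0), blank_nmol=Normal(mean=0.4, sd=0.0),
        )
        camp = generate_campaign(config, noiseless(default_params()))
        rates = rates_from_tables(camp.gc, camp.jars, camp.samples)
        grape_summer = rates[
            (rates.site == "Grape") & (rates.season == "Summer")
            & (rates.sample_type == "biocrust")
        ]
        assert np.allclose(grape_summer["areal_rate_umol_m2_h"], 260.0)


@pytest.fixture(scope="module")
def big():
    """A 200-plot campaign (fixed seed) with its jar rates."""
    camp = generate_campaign(CampaignConfig(seed=7, plots_per_site=200))
    rates = rates_from_tables(camp.gc, camp.jars, camp.samples)
    return camp, rates


class TestStatisticalStructure:
    """Recovery and censoring checks on a 200-plot campaign (fixed seed)."""

    def test_environment_and_nutrient_mean_recovery(self, big):
        """Each site-season generated mean within 3 SE of its configured mean."""
        camp, _rates = big
        params = default_params()
        env = camp.environment
        pooled = camp.samples[camp.samples.role == "pooled"]
        from crustfix.nutrients import pools_from_tables

        pools = pools_from_tables(camp.extracts, camp.samples)
        bio = pools[pools.sample_type == "biocrust"]
        for (site, season), p in params.items():
            grp = env[(env.site == site) & (env.season == season)]
            for col, target in (
                ("soil_temp_c", p.soil_temp_c),
                ("light_umol_m2_s", p.light_umol_m2_s),
            ):
                if target is None:
                    continue
                values = grp[col]
                se = values.std() / np.sqrt(len(values))
                assert abs(values.mean() - target.mean) <= 3 * max(se, 1e-12), (site, season, col)
            sub = bio[(bio.site == site) & (bio.season == season)]
            for col in ("mbc", "mbn", "ec", "en", "ep"):
                target = getattr(p, col).mean
                values = sub[col]
                se = values.std() / np.sqrt(len(values))
                assert abs(values.mean() - target) <= 3 * max(se, 1e-12), (site, season, col)
            # moisture via wet/dry masses
            moist = (pooled.wet_mass_g / pooled.dry_mass_g - 1) * 100
            sub_m = moist[(pooled.site == site) & (pooled.season == season)]
            se = sub_m.std() / np.sqrt(len(sub_m))
            assert abs(sub_m.mean() - p.moisture_pct.mean) <= 3 * max(se, 1e-9)

    def test_rate_mean_recovery(self, big):
        _camp, rates = big
        params = default_params()
        bio = rates[rates.sample_type == "biocrust"]
        for (site, season), grp in bio.groupby(["site", "season"]):
            target = params[(site, season)].areal_ethylene_umol_m2_h
            values = grp["areal_rate_umol_m2_h"]
            se = values.std() / np.sqrt(len(values))
            assert abs(values.mean() - target) <= 3 * se, (site, season)

    def test_bare_rates_far_below_biocrust(self, big):
        _camp, rates = big
        bare = rates[rates.sample_type == "bare"]["areal_rate_umol_m2_h"].mean()
        bio = rates[rates.sample_type == "biocrust"]["areal_rate_umol_m2_h"].mean()
        assert bare / bio <= 0.05

    def test_mbp_censoring_within_binomial_bounds(self, big):
        camp, _ = big
        p_flags = camp.extracts[camp.extracts.analyte == "P"]["fumigated_bdl"]
        n = len(p_flags)
        k = int(p_flags.sum())
        assert binom.ppf(0.005, n, 0.30) <= k <= binom.ppf(0.995, n, 0.30)

    def test_zero_rates_at_configured_probability(self, big):
        _camp, rates = big
        grape = rates[(rates.site == "Grape") & (rates.sample_type == "biocrust")]
        n = len(grape)
        k = int((grape["areal_rate_umol_m2_h"] == 0).sum())
        # zero-inflation 3/24 plus the GC detection floor can only add zeros
        assert binom.ppf(0.005, n, 3 / 24) <= k <= binom.ppf(0.9999, n, 0.2)
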