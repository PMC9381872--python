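"""Upscaling hourly N2-fixation rates to daily, seasonal and annual budgets.

Hourly N-mass rates (mg N m^-2 h^-1) are extrapolated to daily inputs by
assuming phototrophic diazotrophs fix only during daylight (default 10
light hours, no dark fixation), summed over seasons to a full-coverage
annual input per hectare of biocrust, and scaled by the fraction of field
surface biocrusts can occupy (default 12.5%). Unit chain, documented once:
1 mg N m^-2 d^-1 = 1e-2 kg N ha^-1 d^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .constants import MG_M2_DAY_TO_KG_HA_DAY
from .errors import BudgetError

__all__ = [
    "BudgetConfig",
    "SeasonalBudget",
    "daily_rate",
    "annual_budget",
    "fertilizer_fraction",
    "percent_of_annual_n",
    "screen_active",
    "budget_from_rates",
]


class BudgetConfig(BaseModel):
    """Upscaling assumptions for the annual N budget."""

    seasons: tuple[str, ...] = ("Summer", "Fall", "Winter", "Spring")
    light_hours_per_day: float = Field(default=10.0, gt=0, le=24)
    #: Days per season; a scalar applies uniformly (365/4 = 91.25 by default).
    season_length_days: float | dict[str, float] = 91.25
    coverage_fraction: float = Field(default=0.125, gt=0, le=1)
    fertilizer_n_per_application_g: float = Field(default=4.0, gt=0)
    total_annual_fertilizer_n_kg_ha: float | None = None
    #: What to do when a season has no rate data: "error", "zero", or
    #: "carry-nearest". Silent imputation would fabricate budget mass, so
    #: the default refuses to proceed.
    missing_season_policy: str = "error"

    @model_validator(mode="after")
    def _check(self) -> "BudgetConfig":
        if self.missing_season_policy not in ("error", "zero", "carry-nearest"):
            raise ValueError("missing_season_policy must be error|zero|carry-nearest")
        total = sum(self.length_of(s) for s in self.seasons)
        if abs(total - 365.0) > 1.0:
            raise ValueError(f"season lengths sum to {total}, expected 365 ± 1 days")
        return self

    def length_of(self, season: str) -> float:
        if isinstance(self.season_length_days, dict):
            return self.season_length_days[season]
        return self.season_length_days


@dataclass(frozen=True)
class SeasonalBudget:
    """Per-site seasonal rates and the annual per-hectare N input."""

    site: str
    seasonal_hourly_mg_m2_h: dict[str, float]
    seasonal_daily_mg_m2_d: dict[str, float]
    annual_full_coverage_kg_ha_yr: float
    annual_at_coverage_kg_ha_yr: float
    coverage_fraction: float
    percent_of_fertilizer_application: float = float("nan")
    percent_of_annual_n: float = float("nan")


def daily_rate(hourly_mg_m2_h: float, light_hours: float) -> float:
    """Daily N input (mg N m^-2 d^-1) from an hourly rate over the light hours."""
    if hourly_mg_m2_h < 0:
        raise BudgetError(f"hourly rate must be >= 0, got {hourly_mg_m2_h!r}")
    if not 0 < light_hours <= 24:
        raise BudgetError(f"light hours must be in (0, 24], got {light_hours!r}")
    return hourly_mg_m2_h * light_hours


def _fill_missing(
    daily: Mapping[str, float], config: BudgetConfig
) -> dict[str, float]:
    present = dict(daily)
    missing = [s for s in config.seasons if s not in present]
    if not missing:
        return present
    if config.missing_season_policy == "error":
        raise BudgetError(f"missing seasons {missing}; set missing_season_policy to impute")
    if config.missing_season_policy == "zero":
        for s in missing:
            present[s] = 0.0
        return present
    # carry-nearest: use the closest season (by index) that has data
    have = [i for i, s in enumerate(config.seasons) if s in daily]
    if not have:
        raise BudgetError("no seasons present at all")
    for i, s in enumerate(config.seasons):
        if s not in present:
            nearest = min(have, key=lambda j: abs(j - i))
            present[s] = daily[config.seasons[nearest]]
    return present


def annual_budget(
    seasonal_daily_mg_m2_d: Mapping[str, float],
    config: BudgetConfig | None = None,
    site: str = "",
) -> SeasonalBudget:
    """Sum seasonal daily rates into an annual per-hectare N input.

    ``annual_full = sum(daily_s x days_s) x 1e-2`` kg N ha^-1 yr^-1 at 100%
    biocrust coverage; the field-scale estimate multiplies by the coverage
    fraction. Negative rates are an error; missing seasons follow the
    configured policy.
    """
    config = config or BudgetConfig()
    for season, rate in seasonal_daily_mg_m2_d.items():
        if rate < 0:
            raise BudgetError(f"negative daily rate for {season}: {rate!r}")
    daily = _fill_missing(seasonal_daily_mg_m2_d, config)
    annual_full = sum(
        daily[s] * config.length_of(s) for s in config.seasons
    ) * MG_M2_DAY_TO_KG_HA_DAY
    annual_at = annual_full * config.coverage_fraction
    max_daily = max(daily.values()) if daily else 0.0
    pct_fert = fertilizer_fraction(max_daily, config.fertilizer_n_per_application_g)
    pct_annual = float("nan")
    if config.total_annual_fertilizer_n_kg_ha:
        pct_annual = percent_of_annual_n(annual_at, config.total_annual_fertilizer_n_kg_ha)
    hourly = {s: d / config.light_hours_per_day for s, d in daily.items()}
    return SeasonalBudget(
        site=site,
        seasonal_hourly_mg_m2_h=hourly,
        seasonal_daily_mg_m2_d=daily,
        annual_full_coverage_kg_ha_yr=annual_full,
        annual_at_coverage_kg_ha_yr=annual_at,
        coverage_fraction=config.coverage_fraction,
        percent_of_fertilizer_application=pct_fert,
        percent_of_annual_n=pct_annual,
    )


def fertilizer_fraction(daily_mg: float, application_g: float) -> float:
    """Daily biocrust N input as a percentage of one fertigation application."""
    if application_g <= 0:
        raise BudgetError(f"application must be > 0 g N, got {application_g!r}")
    return daily_mg / (application_g * 1000.0) * 100.0


def percent_of_annual_n(annual_at_coverage: float, total_fertilizer: float) -> float:
    """Annual biocrust N input as a percentage of total yearly fertilizer N."""
    if total_fertilizer <= 0:
        raise BudgetError(f"total fertilizer must be > 0, got {total_fertilizer!r}")
    return 100.0 * annual_at_coverage / total_fertilizer


def screen_active(
    records: pd.DataFrame,
    rate_col: str = "areal_rate_umol_m2_h",
    site_col: str = "site",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop zero / below-detection rate records, as done before ordination.

    Returns the retained records and the per-site retained counts.
    """
    mask = records[rate_col] > 0
    if "below_detection" in records.columns:
        mask &= ~records["below_detection"].astype(bool)
    kept = records[mask]
    counts = kept.groupby(site_col, sort=False)[rate_col].count().to_dict() if len(kept) else {}
    # sites that lost every record still deserve an explicit zero
    for site in records[site_col].unique():
        counts.setdefault(site, 0)
    return kept, {k: int(v) for k, v in counts.items()}


def budget_from_rates(
    nfix_rates: pd.DataFrame, config: BudgetConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site budgets from plot-level N-mass rates (mg N m^-2 h^-1).

    Seasonal means include zero-rate plots (an inactive plot is a true zero
    for the budget, unlike for ordination). Returns (per-site budget table,
    per-site-season detail table).
    """
    config = config or BudgetConfig()
    budget_rows, season_rows = [], []
    for site, grp in nfix_rates.groupby("site", sort=False):
        seasonal_hourly = grp.groupby("season", sort=False)["n_mass_rate_mg_m2_h"].mean()
        daily = {
            s: daily_rate(v, config.light_hours_per_day) for s, v in seasonal_hourly.items()
        }
        budget = annual_budget(daily, config, site=site)
        budget_rows.append(
            {
                "site": site,
                "annual_full_coverage_kg_ha_yr": budget.annual_full_coverage_kg_ha_yr,
                "annual_at_coverage_kg_ha_yr": budget.annual_at_coverage_kg_ha_yr,
                "coverage_fraction": budget.coverage_fraction,
                "max_daily_mg_n_m2_d": max(budget.seasonal_daily_mg_m2_d.values()),
                "percent_of_fertilizer_application": budget.percent_of_fertilizer_application,
                "percent_of_annual_n": budget.percent_of_annual_n,
            }
        )
        for season in config.seasons:
            if season in budget.seasonal_daily_mg_m2_d:
                season_rows.append(
                    {
                        "site": site,
                        "season": season,
                        "mean_hourly_mg_n_m2_h": budget.seasonal_hourly_mg_m2_h[season],
                        "daily_mg_n_m2_d": budget.seasonal_daily_mg_m2_d[season],
                        "season_length_days": config.length_of(season),
                    }
                )
    budget_cols = [
        "site",
        "annual_full_coverage_kg_ha_yr",
        "annual_at_coverage_kg_ha_yr",
        "coverage_fraction",
        "max_daily_mg_n_m2_d",
        "percent_of_fertilizer_application",
        "percent_of_annual_n",
    ]
    season_cols = ["site", "season", "mean_hourly_mg_n_m2_h", "daily_mg_n_m2_d", "season_length_days"]
    return (
        pd.DataFrame(budget_rows, columns=budget_cols),
        pd.DataFrame(season_rows, columns=season_cols),
    )
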