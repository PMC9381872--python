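"""Empirical C2H4:N2 conversion factors and ethylene-to-N-mass conversion.

The acetylene-reduction assay measures nitrogenase activity as ethylene
production; turning it into an N2-fixation rate requires a conversion
factor (mol C2H4 per mol N2). The factor is estimated per site as the
ratio of the *mean* biocrust acetylene-reduction rate to the *mean*
15N2-derived fixation rate (ratio of means — robust to small individual
N2 denominators), with its SD propagated by the delta method. The
theoretical stoichiometric value of 3 is available as an alternative basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import N2_G_N_PER_MOL, THEORETICAL_C2H4_N2_RATIO
from .errors import EstimationError

__all__ = [
    "ConversionFactor",
    "theoretical_factor",
    "estimate_conversion_factor",
    "ethylene_to_n_mass",
    "conversion_from_tables",
    "convert_rates",
]


@dataclass(frozen=True)
class ConversionFactor:
    """A C2H4:N2 conversion factor (mol ethylene per mol N2 fixed)."""

    value: float
    sd: float = float("nan")
    basis: str = "experimental"  # "experimental" or "theoretical"
    site_season: str = ""
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.basis not in ("experimental", "theoretical"):
            raise ValueError(f"basis must be experimental|theoretical, got {self.basis!r}")
        if self.value <= 0:
            raise ValueError(f"conversion factor must be > 0, got {self.value!r}")
        if self.basis == "theoretical" and self.value != THEORETICAL_C2H4_N2_RATIO:
            raise ValueError("theoretical basis implies a factor of exactly 3")


def theoretical_factor() -> ConversionFactor:
    """The theoretical 3:1 mol C2H4 : mol N2 stoichiometric factor."""
    return ConversionFactor(value=THEORETICAL_C2H4_N2_RATIO, sd=0.0, basis="theoretical")


def estimate_conversion_factor(
    ara_mass_rates: Sequence[float] | Iterable[float],
    n2_rates: Sequence[float] | Iterable[float],
    site_season: str = "",
) -> ConversionFactor:
    """Ratio-of-means estimator of the C2H4:N2 conversion factor.

    Parameters
    ----------
    ara_mass_rates : sequence of float
        Acetylene-reduction rates, nmol C2H4 g^-1 DW h^-1.
    n2_rates : sequence of float
        15N2-derived fixation rates, nmol N2 g^-1 DW h^-1.

    Notes
    -----
    The estimate is ``mean(ara) / mean(n2)``, *not* the mean of per-pair
    ratios. The SD is the delta-method propagation of the two sample SDs
    assuming independent means:

    ``Var(R) = s_a^2 / (n_a * m_n^2) + m_a^2 * s_n^2 / (n_n * m_n^4)``.
    """
    ara = np.asarray(list(ara_mass_rates), dtype=float)
    n2 = np.asarray(list(n2_rates), dtype=float)
    if ara.size == 0 or n2.size == 0:
        raise EstimationError("both rate lists must be non-empty")
    mean_a = float(ara.mean())
    mean_n = float(n2.mean())
    if mean_n <= 0:
        raise EstimationError(f"mean N2 rate must be > 0, got {mean_n!r}")
    value = mean_a / mean_n
    sd_a = float(ara.std(ddof=1)) if ara.size > 1 else 0.0
    sd_n = float(n2.std(ddof=1)) if n2.size > 1 else 0.0
    var = sd_a**2 / (ara.size * mean_n**2) + mean_a**2 * sd_n**2 / (n2.size * mean_n**4)
    return ConversionFactor(
        value=value,
        sd=math.sqrt(var),
        basis="experimental",
        site_season=site_season,
        n_pairs=int(min(ara.size, n2.size)),
    )


def ethylene_to_n_mass(
    areal_rate_umol_m2_h: float, factor: ConversionFactor | float
) -> float:
    """Convert an areal ethylene rate to an N-mass fixation rate.

    ``mg N m^-2 h^-1 = rate / factor x 28 / 1000`` — divide the ethylene
    rate (μmol C2H4 m^-2 h^-1) by the mol C2H4 per mol N2 factor, and
    multiply by 28 g N per mol N2 (both N2 atoms are nitrogen). Full
    precision is kept; rounding to one decimal belongs to the report layer.
    """
    if areal_rate_umol_m2_h < 0:
        raise ValueError(f"areal rate must be >= 0, got {areal_rate_umol_m2_h!r}")
    value = factor.value if isinstance(factor, ConversionFactor) else float(factor)
    return areal_rate_umol_m2_h / value * N2_G_N_PER_MOL / 1000.0


def conversion_from_tables(
    plot_rates: pd.DataFrame, fixation: pd.DataFrame
) -> pd.DataFrame:
    """Estimate a per-site experimental factor from paired campaign tables.

    For every site-season that has 15N2 assays, the biocrust plot-level ARA
    mass rates from the *same plots* are paired with the biocrust N2 rates
    and fed to the ratio-of-means estimator.
    """
    rows = []
    if not fixation.empty:
        bio_fix = fixation[fixation["sample_type"] == "biocrust"]
        for (site, season), grp in bio_fix.groupby(["site", "season"], sort=False):
            plots = set(grp["plot"])
            ara = plot_rates[
                (plot_rates["site"] == site)
                & (plot_rates["season"] == season)
                & (plot_rates["sample_type"] == "biocrust")
                & (plot_rates["plot"].isin(plots))
            ]
            if ara.empty:
                continue
            cf = estimate_conversion_factor(
                ara["mass_rate_nmol_g_h"].to_numpy(),
                grp["rate_n2_nmol_g_h"].to_numpy(),
                site_season=f"{site} {season}",
            )
            rows.append(
                {
                    "site": site,
                    "season": season,
                    "basis": cf.basis,
                    "factor_mol_c2h4_per_mol_n2": cf.value,
                    "factor_sd": cf.sd,
                    "n_pairs": cf.n_pairs,
                }
            )
    columns = ["site", "season", "basis", "factor_mol_c2h4_per_mol_n2", "factor_sd", "n_pairs"]
    return pd.DataFrame(rows, columns=columns)


def convert_rates(
    plot_rates: pd.DataFrame,
    factors_by_site: dict[str, ConversionFactor],
    default: ConversionFactor | None = None,
) -> pd.DataFrame:
    """Convert biocrust plot-level ethylene rates to N-mass fixation rates.

    ``factors_by_site`` maps site label to its conversion factor; ``default``
    (e.g. the theoretical factor) is used for sites without one.
    """
    bio = plot_rates[plot_rates["sample_type"] == "biocrust"]
    rows = []
    for rec in bio.itertuples(index=False):
        factor = factors_by_site.get(rec.site, default)
        if factor is None:
            raise EstimationError(f"no conversion factor for site {rec.site!r}")
        rows.append(
            {
                "site": rec.site,
                "season": rec.season,
                "plot": rec.plot,
                "areal_rate_umol_m2_h": rec.areal_rate_umol_m2_h,
                "n_mass_rate_mg_m2_h": ethylene_to_n_mass(rec.areal_rate_umol_m2_h, factor),
                "factor_value": factor.value,
                "factor_basis": factor.basis,
                "below_detection": rec.below_detection,
            }
        )
    columns = [
        "site",
        "season",
        "plot",
        "areal_rate_umol_m2_h",
        "n_mass_rate_mg_m2_h",
        "factor_value",
        "factor_basis",
        "below_detection",
    ]
    return pd.DataFrame(rows, columns=columns)
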