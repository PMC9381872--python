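"""Fumigation-extraction arithmetic, nutrient stoichiometry, and moisture.

Microbial biomass C, N and P are the chloroform-fumigated minus unfumigated
extract flush divided by an extraction-efficiency factor (0.37 for C, 0.54
for N, none for P); unfumigated extracts are the extractable pools (EC, EN,
EP). Concentrations (mg per L of extract) are put on a soil basis (mg per
kg dry soil) through the extractant volume and the extracted soil mass.

Stoichiometric ratios are computed per sample and then summarized — never
as ratios of group means — and a whole ratio family is excluded when its
denominator pool is below the detection limit in more than a configurable
fraction of samples (the microbial-P rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import FUMIGATION_EFFICIENCY
from .errors import CrustfixError

__all__ = [
    "ExtractPair",
    "PoolResult",
    "RatioReport",
    "extract_to_soil_basis",
    "microbial_pool",
    "stoichiometric_ratios",
    "gravimetric_moisture",
    "pool_moisture_for_comparison",
    "pools_from_tables",
    "table1_summary",
]

#: Default extraction ratio: 1 g soil in 25 mL extractant.
DEFAULT_EXTRACT_VOLUME_ML = 25.0
DEFAULT_SOIL_MASS_G = 1.0

#: Default extract-basis detection limits, mg L^-1.
DEFAULT_DETECTION_LIMITS = {"C": 0.1, "N": 0.05, "P": 0.01}

#: Ratio families as (numerator pool, denominator pool) column pairs.
RATIO_FAMILIES = {
    "MBC:MBN": ("mbc", "mbn"),
    "MBC:MBP": ("mbc", "mbp"),
    "MBN:MBP": ("mbn", "mbp"),
    "EC:EN": ("ec", "en"),
    "EC:EP": ("ec", "ep"),
    "EN:EP": ("en", "ep"),
}


def extract_to_soil_basis(conc_mg_l: float, extract_volume_ml: float, soil_dry_mass_g: float) -> float:
    """Convert an extract concentration (mg L^-1) to a soil basis (mg kg^-1).

    mg kg^-1 = conc x (volume in L) / (soil mass in g) x 1000.
    """
    if extract_volume_ml <= 0 or soil_dry_mass_g <= 0:
        raise ValueError("extract volume and soil mass must be > 0")
    if conc_mg_l < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_mg_l!r}")
    return conc_mg_l * (extract_volume_ml / 1000.0) / soil_dry_mass_g * 1000.0


@dataclass(frozen=True)
class ExtractPair:
    """Paired fumigated/unfumigated extract measurements for one analyte."""

    analyte: str  # "C", "N" or "P"
    fumigated_conc_mg_l: float
    unfumigated_conc_mg_l: float
    extract_volume_ml: float = DEFAULT_EXTRACT_VOLUME_ML
    soil_dry_mass_g: float = DEFAULT_SOIL_MASS_G
    detection_limit_mg_l: float | None = None
    fumigated_bdl: bool = False
    unfumigated_bdl: bool = False

    def __post_init__(self) -> None:
        if self.analyte not in FUMIGATION_EFFICIENCY:
            raise CrustfixError(f"unknown analyte {self.analyte!r}; expected C, N or P")

    @property
    def limit(self) -> float:
        if self.detection_limit_mg_l is not None:
            return self.detection_limit_mg_l
        return DEFAULT_DETECTION_LIMITS[self.analyte]


@dataclass(frozen=True)
class PoolResult:
    """Microbial and extractable pool for one analyte on a soil basis."""

    analyte: str
    microbial_pool_mg_kg: float  # NaN when not detected
    extractable_pool_mg_kg: float
    efficiency_used: float
    microbial_not_detected: bool
    extractable_bdl: bool


def microbial_pool(pair: ExtractPair) -> PoolResult:
    """Fumigation-extraction pools for one fumigated/unfumigated pair.

    The microbial pool is the flush divided by the extraction efficiency
    (0.37 C, 0.54 N, 1.0 P). A negative flush, or a flush concentration
    below the analyte's detection limit, is reported as not-detected (NaN),
    never as a negative or sentinel number. The unfumigated member is the
    extractable pool.
    """
    k = FUMIGATION_EFFICIENCY[pair.analyte]
    flush_conc = pair.fumigated_conc_mg_l - pair.unfumigated_conc_mg_l
    not_detected = pair.fumigated_bdl or flush_conc < 0 or abs(flush_conc) < pair.limit
    if flush_conc == 0.0 and not pair.fumigated_bdl:
        # exactly equal pairs are a true zero pool, not a censored one
        not_detected = False
    if not_detected:
        microbial = float("nan")
    else:
        microbial = extract_to_soil_basis(flush_conc, pair.extract_volume_ml, pair.soil_dry_mass_g) / k
    extractable = extract_to_soil_basis(
        pair.unfumigated_conc_mg_l, pair.extract_volume_ml, pair.soil_dry_mass_g
    )
    return PoolResult(
        analyte=pair.analyte,
        microbial_pool_mg_kg=microbial,
        extractable_pool_mg_kg=extractable,
        efficiency_used=k,
        microbial_not_detected=not_detected,
        extractable_bdl=pair.unfumigated_bdl,
    )


@dataclass
class RatioReport:
    """Per-sample ratios, group summaries, and excluded ratio families."""

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    excluded_ratio_families: list[dict] = field(default_factory=list)


def stoichiometric_ratios(
    pools: pd.DataFrame,
    bdl_threshold: float = 0.30,
    group_cols: tuple[str, ...] = ("site", "season", "sample_type"),
) -> RatioReport:
    """Mass-based stoichiometric ratios with the detection-limit rule.

    Ratios are formed per sample and then summarized as mean ± sd per group.
    A sample whose denominator is below detection is omitted from that ratio;
    a whole family is excluded (with its reason recorded) when the fraction
    of below-detection denominators across the table strictly exceeds
    ``bdl_threshold``.

    ``pools`` needs columns mbc/mbn/mbp/ec/en/ep plus ``<pool>_bdl`` flags.
    """
    excluded: list[dict] = []
    per_sample = pools.loc[:, [c for c in pools.columns if c in group_cols or c == "sample_id"]].copy()
    kept_families = []
    n = len(pools)
    for family, (num, den) in RATIO_FAMILIES.items():
        bdl_col = f"{den}_bdl"
        bdl_frac = float(pools[bdl_col].mean()) if n else 0.0
        if bdl_frac > bdl_threshold:
            excluded.append(
                {
                    "family": family,
                    "reason": (
                        f"denominator {den.upper()} below detection in "
                        f"{bdl_frac:.0%} of samples (> {bdl_threshold:.0%} threshold)"
                    ),
                }
            )
            continue
        kept_families.append(family)
        num_vals = pools[num].to_numpy(dtype=float)
        den_vals = pools[den].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                pools[bdl_col].to_numpy() | (den_vals <= 0), np.nan, num_vals / den_vals
            )
        per_sample[family] = ratio
    if n and kept_families:
        summary = (
            per_sample.groupby(list(group_cols), sort=False)[kept_families]
            .agg(["mean", "std"])
            .reset_index()
        )
        summary.columns = [
            "_".join(c).strip("_") if isinstance(c, tuple) else c for c in summary.columns
        ]
    else:
        summary = pd.DataFrame(columns=list(group_cols))
    return RatioReport(per_sample=per_sample, summary=summary, excluded_ratio_families=excluded)


def gravimetric_moisture(wet_mass_g: float, dry_mass_g: float, basis: str = "dry") -> float:
    """Gravimetric soil moisture in percent.

    Default basis is per dry mass, ``(wet - dry) / dry x 100``; pass
    ``basis="wet"`` for a per-wet-mass percentage.
    """
    if dry_mass_g <= 0:
        raise ValueError(f"dry mass must be > 0, got {dry_mass_g!r}")
    if wet_mass_g < dry_mass_g:
        raise ValueError(f"wet mass ({wet_mass_g}) below dry mass ({dry_mass_g})")
    water = wet_mass_g - dry_mass_g
    if basis == "dry":
        return water / dry_mass_g * 100.0
    if basis == "wet":
        return water / wet_mass_g * 100.0
    raise ValueError(f"basis must be 'dry' or 'wet', got {basis!r}")


def pool_moisture_for_comparison(
    biocrust_values, bare_values, mode: str = "seasonal"
) -> np.ndarray:
    """Pool moisture series for between-season comparison or ordination.

    ``mode="seasonal"`` pools biocrust and adjacent bare-soil plot values
    into one series (n = biocrust + bare, e.g. 6 + 6 = 12 per site-season);
    ``mode="multivariate"`` returns the biocrust-only series used for
    ordination. Unequal lengths indicate unpaired plots: a warning is issued
    and all available values are pooled.
    """
    bio = np.asarray(list(biocrust_values), dtype=float)
    bare = np.asarray(list(bare_values), dtype=float)
    if mode == "multivariate":
        return bio
    if mode != "seasonal":
        raise ValueError(f"mode must be 'seasonal' or 'multivariate', got {mode!r}")
    if bio.size != bare.size:
        warnings.warn(
            f"unpaired plots ({bio.size} biocrust vs {bare.size} bare); "
            "pooling all available values",
            stacklevel=2,
        )
    return np.concatenate([bio, bare])


def pools_from_tables(
    extracts: pd.DataFrame,
    samples: pd.DataFrame,
    detection_limits: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Fumigation-extraction pools for every sample in extracts.csv.

    Returns one row per sample with mbc/mbn/mbp and ec/en/ep on a soil
    basis plus ``<pool>_bdl`` not-detected flags.
    """
    limits = dict(DEFAULT_DETECTION_LIMITS)
    if detection_limits:
        limits.update(detection_limits)
    meta = samples.set_index("sample_id")
    records: dict[str, dict] = {}
    for rec in extracts.itertuples(index=False):
        pair = ExtractPair(
            analyte=rec.analyte,
            fumigated_conc_mg_l=rec.fumigated_mg_per_l,
            unfumigated_conc_mg_l=rec.unfumigated_mg_per_l,
            extract_volume_ml=rec.extract_volume_ml,
            soil_dry_mass_g=rec.soil_dry_mass_g,
            detection_limit_mg_l=limits[rec.analyte],
            fumigated_bdl=bool(rec.fumigated_bdl),
            unfumigated_bdl=bool(rec.unfumigated_bdl),
        )
        result = microbial_pool(pair)
        row = records.setdefault(rec.sample_id, {"sample_id": rec.sample_id})
        key = rec.analyte.lower()
        row[f"mb{key}"] = result.microbial_pool_mg_kg
        row[f"mb{key}_bdl"] = result.microbial_not_detected
        row[f"e{key}"] = result.extractable_pool_mg_kg
        row[f"e{key}_bdl"] = result.extractable_bdl
    columns = [
        "sample_id",
        "mbc", "mbn", "mbp", "ec", "en", "ep",
        "mbc_bdl", "mbn_bdl", "mbp_bdl", "ec_bdl", "en_bdl", "ep_bdl",
    ]
    pools = pd.DataFrame(list(records.values()), columns=columns)
    keep = ["site", "season", "plot", "sample_type"]
    pools = pools.merge(meta[keep], left_on="sample_id", right_index=True, how="left")
    return pools[["sample_id", *keep, *columns[1:]]]


def table1_summary(pools: pd.DataFrame, bdl_threshold: float = 0.30) -> pd.DataFrame:
    """Site-by-season biocrust nutrient summary (mean and sd per cell).

    Pools are summarized directly; ratio columns are computed per sample and
    summarized, with ratio families excluded by the detection-limit rule.
    Means and sds are rounded to 2 decimals, mirroring conventional
    reporting of fumigation-extraction tables.
    """
    bio = pools[pools["sample_type"] == "biocrust"]
    report = stoichiometric_ratios(bio, bdl_threshold=bdl_threshold, group_cols=("site", "season"))
    kept = [f for f in RATIO_FAMILIES if f not in {e["family"] for e in report.excluded_ratio_families}]
    rows = []
    for (site, season), grp in bio.groupby(["site", "season"], sort=False):
        row = {"site": site, "season": season}
        for pool in ("mbc", "mbn", "ec", "en", "ep"):
            row[f"{pool}_mean"] = round(float(grp[pool].mean()), 2)
            row[f"{pool}_sd"] = round(float(grp[pool].std(ddof=1)), 2) if len(grp) > 1 else 0.0
        sub = report.per_sample[
            (report.per_sample["site"] == site) & (report.per_sample["season"] == season)
        ]
        for family in kept:
            key = family.replace(":", "_").lower()
            vals = sub[family].dropna()
            row[f"{key}_mean"] = round(float(vals.mean()), 2) if len(vals) else float("nan")
            row[f"{key}_sd"] = round(float(vals.std(ddof=1)), 2) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
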