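"""Acetylene-reduction assay (ARA) gas-chromatography reductions.

Ethylene produced during a closed-jar acetylene-reduction incubation is
quantified from flame-ionization GC peak responses against a single-point
ethylene standard, converted to a molar amount with the ideal-gas molar
volume at the analysis temperature, blank-corrected, and expressed as a
rate both per unit soil-core surface area (μmol C2H4 m^-2 h^-1) and per
unit dry mass (nmol C2H4 g^-1 DW h^-1).

The intact cores sit on the jar lid, so the nominal jar volume is used as
the headspace volume; an optional correction term is exposed for users who
measure displaced volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .constants import CELSIUS_TO_KELVIN, R_L_ATM_PER_MOL_K
from .errors import CalibrationError

__all__ = [
    "GcCalibration",
    "JarGeometry",
    "EthyleneRate",
    "calibrate_gc",
    "molar_volume_l_per_mol",
    "headspace_ethylene_nmol",
    "ppm_from_headspace_nmol",
    "ethylene_rate",
    "areal_from_mass_rate",
    "mass_from_areal_rate",
    "rates_from_tables",
]

#: Net ethylene (nmol per jar) below which a rate is recorded as zero and
#: flagged below detection.
DEFAULT_DETECTION_FLOOR_NMOL = 1.0


@dataclass(frozen=True)
class GcCalibration:
    """Single-point GC calibration through the origin.

    Attributes
    ----------
    standard_concentration : float
        Concentration of the ethylene standard, ppm v/v.
    standard_peak_response : float
        Integrated detector response of the standard, arbitrary units.
    response_factor : float
        ppm per detector unit, ``standard_concentration / standard_peak_response``.
    """

    standard_concentration: float
    standard_peak_response: float
    response_factor: float


def calibrate_gc(standard_peak: float, standard_conc: float = 100.0) -> GcCalibration:
    """Build a single-point, through-origin calibration from one standard run.

    Parameters
    ----------
    standard_peak : float
        Detector response of the standard injection; must be > 0.
    standard_conc : float
        Standard concentration in ppm v/v (a 100 ppm ethylene standard by default).

    Raises
    ------
    CalibrationError
        If the standard peak is not strictly positive.
    """
    if standard_peak <= 0:
        raise CalibrationError(f"standard peak response must be > 0, got {standard_peak!r}")
    if standard_conc <= 0:
        raise CalibrationError(f"standard concentration must be > 0, got {standard_conc!r}")
    return GcCalibration(
        standard_concentration=float(standard_conc),
        standard_peak_response=float(standard_peak),
        response_factor=float(standard_conc) / float(standard_peak),
    )


@dataclass(frozen=True)
class JarGeometry:
    """Closed-jar incubation geometry and gas-quantification conditions."""

    headspace_volume_ml: float = 138.0
    incubation_duration_h: float = 2.0
    core_diameter_cm: float = 3.0
    cores_per_jar: int = 1
    analysis_temperature_c: float = 25.0
    pressure_atm: float = 1.0
    #: Volume displaced by the sample, subtracted from the nominal jar volume.
    headspace_correction_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.headspace_volume_ml <= 0:
            raise ValueError("headspace_volume_ml must be > 0")
        if self.incubation_duration_h <= 0:
            raise ValueError("incubation_duration_h must be > 0")
        if self.core_diameter_cm <= 0:
            raise ValueError("core_diameter_cm must be > 0")
        if self.cores_per_jar < 1:
            raise ValueError("cores_per_jar must be >= 1")

    @property
    def soil_core_area_m2(self) -> float:
        """Total soil surface area in the jar: cores_per_jar x pi r^2, m^2."""
        radius_m = self.core_diameter_cm / 2.0 / 100.0
        return self.cores_per_jar * math.pi * radius_m**2

    @property
    def effective_headspace_l(self) -> float:
        return (self.headspace_volume_ml - self.headspace_correction_ml) / 1000.0


def molar_volume_l_per_mol(temperature_c: float, pressure_atm: float = 1.0) -> float:
    """Ideal-gas molar volume, L mol^-1, at the given temperature and pressure."""
    return R_L_ATM_PER_MOL_K * (temperature_c + CELSIUS_TO_KELVIN) / pressure_atm


def headspace_ethylene_nmol(peak: float, cal: GcCalibration, geom: JarGeometry) -> float:
    """Ethylene amount (nmol) in the jar headspace from a GC peak response.

    ``ppm = peak x response_factor``; the molar amount follows from the
    mixing ratio, the headspace volume and the ideal-gas molar volume at the
    analysis temperature.
    """
    if peak < 0:
        raise ValueError(f"peak response must be >= 0, got {peak!r}")
    ppm = peak * cal.response_factor
    vm = molar_volume_l_per_mol(geom.analysis_temperature_c, geom.pressure_atm)
    mol = ppm * 1e-6 * geom.effective_headspace_l / vm
    return mol * 1e9


def ppm_from_headspace_nmol(nmol: float, geom: JarGeometry) -> float:
    """Exact inverse of :func:`headspace_ethylene_nmol` (used to synthesize peaks)."""
    vm = molar_volume_l_per_mol(geom.analysis_temperature_c, geom.pressure_atm)
    return nmol * 1e-9 * vm / (geom.effective_headspace_l * 1e-6)


@dataclass(frozen=True)
class EthyleneRate:
    """Blank-corrected ethylene production rate of one jar."""

    areal_rate_umol_m2_h: float
    mass_rate_nmol_g_h: float
    net_nmol: float = 0.0
    blank_corrected: bool = True
    below_detection: bool = False


def ethylene_rate(
    sample_nmol: float,
    blank_nmol: float,
    geom: JarGeometry,
    dry_mass_g: float,
    detection_floor_nmol: float = DEFAULT_DETECTION_FLOOR_NMOL,
) -> EthyleneRate:
    """Blank-correct a jar's headspace ethylene and express it as a rate.

    The non-acetylated blank incubated alongside the sample is subtracted;
    a negative difference is floored at zero. Net amounts below the GC
    detection floor are recorded as zero-rate and flagged below detection.

    Parameters
    ----------
    sample_nmol, blank_nmol : float
        Headspace ethylene of the acetylated sample jar and its blank, nmol.
    geom : JarGeometry
        Incubation geometry (duration and soil surface area).
    dry_mass_g : float
        Oven-dry mass of the incubated core(s), g; must be > 0.
    detection_floor_nmol : float
        Net-ethylene quantification floor per jar.
    """
    if dry_mass_g <= 0:
        raise ValueError(f"dry_mass_g must be > 0, got {dry_mass_g!r}")
    net = max(sample_nmol - blank_nmol, 0.0)
    below = net < detection_floor_nmol
    if below:
        net = 0.0
    # nmol -> umol for the areal basis; nmol stays nmol for the mass basis.
    areal = net * 1e-3 / (geom.incubation_duration_h * geom.soil_core_area_m2)
    mass = net / (geom.incubation_duration_h * dry_mass_g)
    return EthyleneRate(
        areal_rate_umol_m2_h=areal,
        mass_rate_nmol_g_h=mass,
        net_nmol=net,
        blank_corrected=True,
        below_detection=below,
    )


def areal_from_mass_rate(mass_rate_nmol_g_h: float, dry_mass_g: float, core_area_m2: float) -> float:
    """Convert a per-dry-mass rate (nmol g^-1 h^-1) to per-area (μmol m^-2 h^-1)."""
    return mass_rate_nmol_g_h * dry_mass_g / core_area_m2 / 1000.0


def mass_from_areal_rate(areal_rate_umol_m2_h: float, dry_mass_g: float, core_area_m2: float) -> float:
    """Exact inverse of :func:`areal_from_mass_rate`."""
    return areal_rate_umol_m2_h * core_area_m2 * 1000.0 / dry_mass_g


def rates_from_tables(
    gc: pd.DataFrame,
    jars: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    analysis_temperature_c: float = 25.0,
    pressure_atm: float = 1.0,
    detection_floor_nmol: float = DEFAULT_DETECTION_FLOOR_NMOL,
) -> pd.DataFrame:
    """Compute per-jar ethylene rates from the campaign gc/jars/samples tables.

    Returns one row per acetylated jar with sample metadata, the areal and
    per-mass rates, the net headspace ethylene, and a below-detection flag.
    """
    sample_meta = samples[["sample_id", "site", "season", "plot", "sample_type", "dry_mass_g"]]
    merged = gc.merge(jars, on="jar_id", how="inner").merge(
        sample_meta, on="sample_id", how="inner"
    )
    rows = []
    for rec in merged.itertuples(index=False):
        cal = calibrate_gc(rec.standard_peak, rec.standard_conc_ppm)
        geom = JarGeometry(
            headspace_volume_ml=rec.headspace_volume_ml,
            incubation_duration_h=rec.duration_h,
            core_diameter_cm=rec.core_diameter_cm,
            cores_per_jar=int(rec.cores_per_jar),
            analysis_temperature_c=analysis_temperature_c,
            pressure_atm=pressure_atm,
        )
        sample_nmol = headspace_ethylene_nmol(rec.sample_peak, cal, geom)
        blank_nmol = headspace_ethylene_nmol(rec.blank_peak, cal, geom)
        rate = ethylene_rate(
            sample_nmol, blank_nmol, geom, rec.dry_mass_g, detection_floor_nmol
        )
        rows.append(
            {
                "jar_id": rec.jar_id,
                "sample_id": rec.sample_id,
                "site": rec.site,
                "season": rec.season,
                "plot": rec.plot,
                "sample_type": rec.sample_type,
                "dry_mass_g": rec.dry_mass_g,
                "net_nmol": rate.net_nmol,
                "areal_rate_umol_m2_h": rate.areal_rate_umol_m2_h,
                "mass_rate_nmol_g_h": rate.mass_rate_nmol_g_h,
                "below_detection": rate.below_detection,
            }
        )
    columns = [
        "jar_id",
        "sample_id",
        "site",
        "season",
        "plot",
        "sample_type",
        "dry_mass_g",
        "net_nmol",
        "areal_rate_umol_m2_h",
        "mass_rate_nmol_g_h",
        "below_detection",
    ]
    return pd.DataFrame(rows, columns=columns)


def aggregate_plot_rates(rates: pd.DataFrame) -> pd.DataFrame:
    """Average subreplicate jar rates to one record per site/season/plot/type.

    A plot is flagged below detection only when every subreplicate is.
    """
    if rates.empty:
        return pd.DataFrame(
            columns=[
                "site",
                "season",
                "plot",
                "sample_type",
                "areal_rate_umol_m2_h",
                "mass_rate_nmol_g_h",
                "below_detection",
                "n_jars",
            ]
        )
    grouped = (
        rates.groupby(["site", "season", "plot", "sample_type"], sort=False)
        .agg(
            areal_rate_umol_m2_h=("areal_rate_umol_m2_h", "mean"),
            mass_rate_nmol_g_h=("mass_rate_nmol_g_h", "mean"),
            below_detection=("below_detection", "all"),
            n_jars=("jar_id", "count"),
        )
        .reset_index()
    )
    return grouped
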