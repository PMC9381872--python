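"""15N2 incubation mass balance.

A jar spiked with 98% 15N2 raises the headspace atom% 15N far above the
natural 0.3663 atom%. Biomass that fixes N2 during the incubation inherits
the label in proportion to the fraction of its N derived from fixation:

    fraction = (atom%_biomass,enriched - atom%_biomass,unenriched)
               / (atom%_headspace - atom%_biomass,unenriched)

Multiplying by the sample's total N and dividing by the atomic mass of N
and the incubation time gives the absolute fixation rate in nmol N g^-1 DW
h^-1; half of that, in nmol N2 g^-1 DW h^-1, is the molar-N2 basis used for
the C2H4:N2 conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import AIR_ATOM_PCT_15N, ATOMIC_MASS_N
from .errors import InvalidAssayError

__all__ = [
    "HeadspaceAtomPct",
    "IsotopeAssay",
    "FixationResult",
    "headspace_atom_pct",
    "fraction_n_fixed",
    "n2_fixation_rate",
    "fixation_from_tables",
]


@dataclass(frozen=True)
class HeadspaceAtomPct:
    """Measured headspace atom% 15N with its excess over air."""

    atom_pct: float
    excess: float
    usable: bool


def headspace_atom_pct(
    gas_blank_atom_pct: float, air_atom_pct: float = AIR_ATOM_PCT_15N
) -> HeadspaceAtomPct:
    """Headspace atom% 15N from a gas-blank jar, with air-excess retained.

    The gas blanks are empty jars spiked with the same 15N2 volume, so their
    measured atom% is the headspace atom%; subtracting the atom% of air gives
    the enrichment excess. A blank at exactly natural abundance flags the
    assay unusable; a blank *below* air is physically impossible and raises.
    """
    if gas_blank_atom_pct < air_atom_pct:
        raise InvalidAssayError(
            f"gas blank atom% ({gas_blank_atom_pct}) below air atom% ({air_atom_pct})"
        )
    excess = gas_blank_atom_pct - air_atom_pct
    return HeadspaceAtomPct(atom_pct=gas_blank_atom_pct, excess=excess, usable=excess > 0)


@dataclass(frozen=True)
class IsotopeAssay:
    """One 15N2 enrichment assay on a pooled biocrust or bare-soil sample.

    atom% values are percentages in [0, 100]; ``total_n`` is g N per g dry
    mass in (0, 1); ``duration_h`` is the incubation length in hours.
    """

    atom_pct_biomass_enriched: float
    atom_pct_biomass_unenriched: float
    atom_pct_headspace: float
    total_n: float
    duration_h: float
    atom_pct_air: float = AIR_ATOM_PCT_15N
    dry_mass_g: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "atom_pct_biomass_enriched",
            "atom_pct_biomass_unenriched",
            "atom_pct_headspace",
            "atom_pct_air",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise InvalidAssayError(f"{name} must be in [0, 100], got {value!r}")
        if not 0.0 < self.total_n < 1.0:
            raise InvalidAssayError(f"total_n must be in (0, 1) g/g, got {self.total_n!r}")
        if self.duration_h <= 0:
            raise InvalidAssayError(f"duration_h must be > 0, got {self.duration_h!r}")


@dataclass(frozen=True)
class FixationResult:
    """Fraction of biomass N fixed and the absolute fixation rate."""

    fraction_fixed: float
    rate_n_atoms_nmol_g_h: float
    rate_n2_nmol_g_h: float
    negative_excess_floored: bool = False


def fraction_n_fixed(assay: IsotopeAssay) -> tuple[float, bool]:
    """Fraction of biomass N derived from fixation, with a floor-warning flag.

    Returns ``(fraction, floored)``; ``floored`` is True when the enriched
    biomass measured *below* the unenriched control (IRMS noise) and the
    negative excess was floored to zero rather than treated as an error.

    Raises
    ------
    InvalidAssayError
        If the headspace is not enriched above the unenriched biomass
        (zero or negative denominator).
    """
    denom = assay.atom_pct_headspace - assay.atom_pct_biomass_unenriched
    if denom <= 0:
        raise InvalidAssayError(
            "headspace atom% must exceed unenriched biomass atom% "
            f"({assay.atom_pct_headspace} vs {assay.atom_pct_biomass_unenriched})"
        )
    numer = assay.atom_pct_biomass_enriched - assay.atom_pct_biomass_unenriched
    if numer < 0:
        return 0.0, True
    return numer / denom, False


def n2_fixation_rate(assay: IsotopeAssay) -> FixationResult:
    """Absolute N2-fixation rate of an assay.

    ``rate_n_atoms = fraction x total_n / 14 / duration`` expressed in nmol N
    g^-1 DW h^-1; the molar-N2 rate is exactly half of it.
    """
    fraction, floored = fraction_n_fixed(assay)
    rate_mol = fraction * assay.total_n / ATOMIC_MASS_N / assay.duration_h
    rate_n_atoms = rate_mol * 1e9
    return FixationResult(
        fraction_fixed=fraction,
        rate_n_atoms_nmol_g_h=rate_n_atoms,
        rate_n2_nmol_g_h=rate_n_atoms / 2.0,
        negative_excess_floored=floored,
    )


def fixation_from_tables(isotope: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Compute fixation fractions and rates for every row of isotope.csv."""
    merged = isotope.merge(
        samples[["sample_id", "site", "season", "plot", "sample_type", "dry_mass_g"]],
        on="sample_id",
        how="inner",
    )
    rows = []
    for rec in merged.itertuples(index=False):
        head = headspace_atom_pct(rec.atom_pct_gas_blank, rec.atom_pct_air)
        assay = IsotopeAssay(
            atom_pct_biomass_enriched=rec.atom_pct_biomass_enriched,
            atom_pct_biomass_unenriched=rec.atom_pct_biomass_unenriched,
            atom_pct_headspace=head.atom_pct,
            total_n=rec.total_n_g_per_g,
            duration_h=rec.duration_h,
            atom_pct_air=rec.atom_pct_air,
            dry_mass_g=rec.dry_mass_g,
        )
        result = n2_fixation_rate(assay)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "site": rec.site,
                "season": rec.season,
                "plot": rec.plot,
                "sample_type": rec.sample_type,
                "headspace_excess_atom_pct": head.excess,
                "fraction_fixed": result.fraction_fixed,
                "rate_n_atoms_nmol_g_h": result.rate_n_atoms_nmol_g_h,
                "rate_n2_nmol_g_h": result.rate_n2_nmol_g_h,
                "negative_excess_floored": result.negative_excess_floored,
            }
        )
    columns = [
        "sample_id",
        "site",
        "season",
        "plot",
        "sample_type",
        "headspace_excess_atom_pct",
        "fraction_fixed",
        "rate_n_atoms_nmol_g_h",
        "rate_n2_nmol_g_h",
        "negative_excess_floored",
    ]
    return pd.DataFrame(rows, columns=columns)
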