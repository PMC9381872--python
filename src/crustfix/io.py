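"""Campaign table schemas, CSV I/O with unit metadata, and validation.

Every table is a UTF-8 CSV with a leading ``# units:`` comment recording
the unit of each column ("-" for dimensionless or labels). Missing values
are empty fields; below-detection is encoded as paired boolean columns,
never as sentinel numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import CampaignValidationError, Violation

__all__ = [
    "SCHEMA_VERSION",
    "CAMPAIGN_SCHEMAS",
    "CampaignTables",
    "read_table",
    "write_table",
    "write_campaign",
    "validate_campaign",
]

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class TableSchema:
    name: str
    units: dict[str, str]  # column -> unit, in column order
    primary_key: tuple[str, ...]
    foreign_keys: tuple[tuple[str, str, str], ...] = ()  # (column, table, column)

    @property
    def columns(self) -> list[str]:
        return list(self.units)


CAMPAIGN_SCHEMAS: dict[str, TableSchema] = {
    "samples": TableSchema(
        "samples",
        {
            "sample_id": "-", "site": "-", "season": "-", "plot": "-",
            "subreplicate": "-", "sample_type": "-", "role": "-",
            "dry_mass_g": "g", "wet_mass_g": "g",
            "core_diameter_cm": "cm", "core_depth_cm": "cm",
        },
        ("sample_id",),
    ),
    "jars": TableSchema(
        "jars",
        {
            "jar_id": "-", "sample_id": "-", "headspace_volume_ml": "mL",
            "duration_h": "h", "acetylated": "bool", "cores_per_jar": "-",
            "core_diameter_cm": "cm", "incubation_temp_c": "degC",
        },
        ("jar_id",),
        (("sample_id", "samples", "sample_id"),),
    ),
    "gc": TableSchema(
        "gc",
        {
            "jar_id": "-", "sample_peak": "detector units",
            "blank_peak": "detector units", "standard_peak": "detector units",
            "standard_conc_ppm": "ppm v/v",
        },
        ("jar_id",),
        (("jar_id", "jars", "jar_id"),),
    ),
    "isotope": TableSchema(
        "isotope",
        {
            "sample_id": "-", "atom_pct_biomass_enriched": "atom% 15N",
            "atom_pct_biomass_unenriched": "atom% 15N",
            "atom_pct_gas_blank": "atom% 15N", "atom_pct_air": "atom% 15N",
            "total_n_g_per_g": "g N / g DW", "duration_h": "h",
        },
        ("sample_id",),
        (("sample_id", "samples", "sample_id"),),
    ),
    "extracts": TableSchema(
        "extracts",
        {
            "sample_id": "-", "analyte": "-", "fumigated_mg_per_l": "mg/L",
            "unfumigated_mg_per_l": "mg/L", "extract_volume_ml": "mL",
            "soil_dry_mass_g": "g", "fumigated_bdl": "bool", "unfumigated_bdl": "bool",
        },
        ("sample_id", "analyte"),
        (("sample_id", "samples", "sample_id"),),
    ),
    "environment": TableSchema(
        "environment",
        {
            "site": "-", "season": "-", "plot": "-", "soil_temp_c": "degC",
            "light_umol_m2_s": "umol m-2 s-1", "rainfall_24h_mm": "mm",
        },
        ("site", "season", "plot"),
    ),
}


def write_table(df: pd.DataFrame, path: str | Path, units: dict[str, str] | None = None) -> Path:
    """Write a CSV with a ``# units:`` metadata header line."""
    path = Path(path)
    units = units or {c: "-" for c in df.columns}
    header = "# units: " + "; ".join(f"{c}={units.get(c, '-')}" for c in df.columns)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header + "\n")
        # %.17g guarantees bit-exact float64 round trips through text
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a CSV written by :func:`write_table`; returns (frame, units)."""
    path = Path(path)
    units: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# units:"):
        for part in first[len("# units:"):].strip().split(";"):
            if "=" in part:
                col, unit = part.split("=", 1)
                units[col.strip()] = unit.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return df, units


@dataclass
class CampaignTables:
    """Parsed and validated campaign tables."""

    path: Path
    tables: dict[str, pd.DataFrame]
    schema_version: str = SCHEMA_VERSION
    config: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def write_campaign(campaign, path: str | Path) -> Path:
    """Write a RawCampaign to a directory of CSVs plus campaign.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in CAMPAIGN_SCHEMAS:
        df = getattr(campaign, name)
        write_table(df, path / f"{name}.csv", CAMPAIGN_SCHEMAS[name].units)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "seed": campaign.config.seed,
        "config": campaign.config.model_dump(mode="json"),
    }
    with open(path / "campaign.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return path


def _check_domains(name: str, df: pd.DataFrame, violations: list[Violation]) -> None:
    """Numeric-domain checks that do not depend on other tables."""
    def bad_rows(mask, column, message):
        for idx in df.index[mask]:
            violations.append(Violation(f"{name}.csv", int(idx), column, message))

    if name == "gc":
        for col in ("sample_peak", "blank_peak", "standard_peak"):
            bad_rows(df[col] < 0, col, "GC peak response must be >= 0")
        bad_rows(df["standard_peak"] <= 0, "standard_peak", "standard peak must be > 0")
    elif name == "isotope":
        for col in (
            "atom_pct_biomass_enriched", "atom_pct_biomass_unenriched",
            "atom_pct_gas_blank", "atom_pct_air",
        ):
            bad_rows(~df[col].between(0, 100), col, "atom% must be in [0, 100]")
    elif name == "samples":
        bad_rows(df["dry_mass_g"] <= 0, "dry_mass_g", "dry mass must be > 0")
        bad_rows(df["wet_mass_g"] < df["dry_mass_g"], "wet_mass_g", "wet mass below dry mass")
    elif name == "jars":
        bad_rows(df["headspace_volume_ml"] <= 0, "headspace_volume_ml", "volume must be > 0")
        bad_rows(df["duration_h"] <= 0, "duration_h", "duration must be > 0")


def validate_campaign(directory: str | Path, raise_on_error: bool = True) -> CampaignTables:
    """Validate a campaign directory against the schema registry.

    Checks table presence, column sets, primary-key uniqueness, referential
    integrity and numeric domains. Nothing is coerced; on failure all
    violations are reported together in a :class:`CampaignValidationError`
    (or returned on the object when ``raise_on_error`` is False).
    """
    directory = Path(directory)
    violations: list[Violation] = []
    tables: dict[str, pd.DataFrame] = {}

    if not directory.is_dir():
        raise FileNotFoundError(f"campaign directory {directory} does not exist")

    for name, schema in CAMPAIGN_SCHEMAS.items():
        fpath = directory / f"{name}.csv"
        if not fpath.exists():
            violations.append(Violation(f"{name}.csv", None, "-", "missing table"))
            continue
        df, _units = read_table(fpath)
        missing_cols = [c for c in schema.columns if c not in df.columns]
        for col in missing_cols:
            violations.append(Violation(f"{name}.csv", None, col, "missing column"))
        if missing_cols:
            continue
        tables[name] = df
        dup = df.duplicated(subset=list(schema.primary_key))
        for idx in df.index[dup]:
            violations.append(
                Violation(f"{name}.csv", int(idx), ",".join(schema.primary_key), "duplicate primary key")
            )
        if len(df):
            _check_domains(name, df, violations)

    for name, schema in CAMPAIGN_SCHEMAS.items():
        if name not in tables:
            continue
        for column, ref_table, ref_column in schema.foreign_keys:
            if ref_table not in tables:
                continue
            known = set(tables[ref_table][ref_column])
            missing_ref = ~tables[name][column].isin(known)
            for idx in tables[name].index[missing_ref]:
                violations.append(
                    Violation(
                        f"{name}.csv", int(idx), column,
                        f"references unknown {ref_table}.{ref_column} "
                        f"{tables[name].loc[idx, column]!r}",
                    )
                )

    config: dict = {}
    sidecar = directory / "campaign.yaml"
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}

    if violations and raise_on_error:
        raise CampaignValidationError(violations)
    result = CampaignTables(path=directory, tables=tables, config=config)
    if violations:
        result.violations = violations  # type: ignore[attr-defined]
    return result
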