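"""Typed records and file formats for hydrothermal-liquefaction (HTL) experiments.

An HTL run converts wet biomass into a liquid *biocrude* in hot compressed
water (optionally with an alcohol co-solvent and/or an alkali catalyst).  A
bench run produces a product slate — biocrude (two solvent-separated
fractions, B1 + B2), solid char, gases and a non-volatile residue (NVR) — plus
an aqueous co-phase product (ACP) carrying dissolved N, P and organic carbon.

This module defines the validated record types every downstream computation
consumes, and a CSV reader/writer for experiment tables.  The file schema
stores raw masses in grams together with the dry feed mass; percentages are
always recomputed downstream, never stored, so closure checks cannot silently
disagree with stored yields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "SchemaError",
    "FeedstockComposition",
    "HTLCondition",
    "ProductSlate",
    "FractionProperties",
    "ACPProfile",
    "GasProfile",
    "ExperimentRecord",
    "read_experiment_table",
    "write_experiment_table",
    "read_feedstock_config",
    "EXPERIMENT_COLUMNS",
]


class ValidationError(ValueError):
    """A record violates a physical or bookkeeping invariant."""


class SchemaError(ValueError):
    """An experiment table is missing mandatory columns or cannot be parsed."""


def _check_pct(name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        raise ValidationError(f"{name} = {value} outside [0, 100] %")


@dataclass
class FeedstockComposition:
    """Ultimate/proximate/biochemical composition and HHV of dry biomass.

    All compositional fields are mass % on an as-received basis; ``hhv_mj_per_kg``
    is the higher heating value in MJ kg^-1.  ``fatty_acid_profile`` maps a
    chain label (e.g. ``"C18"``) to its fraction of total fatty acids.

    The proximate closure (moisture + volatiles + fixed carbon + ash ~ 100 ± 2)
    is checked softly: a violation is recorded in ``notes`` rather than raised,
    because published proximate rows routinely fail closure at face value and
    the discrepancy should be surfaced, not hidden or "fixed".
    """

    carbon_pct: float
    hydrogen_pct: float
    nitrogen_pct: float
    oxygen_pct: float
    moisture_pct: float
    volatiles_pct: float
    fixed_carbon_pct: float
    ash_pct: float
    lipid_pct: float
    protein_pct: float
    carbohydrate_pct: float
    hhv_mj_per_kg: float
    fatty_acid_profile: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        for name in (
            "carbon_pct", "hydrogen_pct", "nitrogen_pct", "oxygen_pct",
            "moisture_pct", "volatiles_pct", "fixed_carbon_pct", "ash_pct",
            "lipid_pct", "protein_pct", "carbohydrate_pct",
        ):
            _check_pct(name, getattr(self, name))
        if self.hhv_mj_per_kg < 0:
            raise ValidationError("hhv_mj_per_kg must be >= 0")
        prox = (self.moisture_pct + self.volatiles_pct
                + self.fixed_carbon_pct + self.ash_pct)
        if not (98.0 <= prox <= 102.0):
            self.notes.append(
                f"proximate analysis sums to {prox:.2f} %, outside 100 +/- 2"
            )
        if self.fatty_acid_profile:
            total = sum(self.fatty_acid_profile.values())
            if abs(total - 1.0) > 0.02:
                raise ValidationError(
                    f"fatty_acid_profile sums to {total:.4f}, not 1 +/- 0.02"
                )


@dataclass
class HTLCondition:
    """Operating condition of one HTL treatment."""

    temperature_c: float
    residence_min: float
    reactor_label: str
    catalyst_loading_frac: float = 0.0
    cosolvent_name: Optional[str] = None
    cosolvent_water_mass_ratio: float = 0.0
    biomass_to_solvent_ratio: float = 0.1
    pressure_mpa: Optional[float] = None  # informational only

    def __post_init__(self) -> None:
        if not (100.0 <= self.temperature_c <= 374.0):
            raise ValidationError(
                f"temperature_c = {self.temperature_c} outside subcritical "
                "HTL window [100, 374] degC"
            )
        if not (0.0 <= self.catalyst_loading_frac <= 0.2):
            raise ValidationError("catalyst_loading_frac outside [0, 0.2]")
        if self.biomass_to_solvent_ratio <= 0:
            raise ValidationError("biomass_to_solvent_ratio must be positive")
        if self.cosolvent_water_mass_ratio < 0:
            raise ValidationError("cosolvent_water_mass_ratio must be >= 0")


@dataclass
class ProductSlate:
    """Raw product masses (g) from one run, relative to the dry feed charged.

    Gas mass is optional: vented-gas reactors cannot quantify it.  The slate
    tolerates a total slightly above the feed (<= 1.05x) because co-solvent
    carbon can be incorporated into products as esters.
    """

    feed_dry_mass_g: float
    biocrude1_mass_g: float
    biocrude2_mass_g: float
    solids_mass_g: float
    nvr_mass_g: float
    gas_mass_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.feed_dry_mass_g <= 0:
            raise ValidationError("feed_dry_mass_g must be > 0")
        for name in ("biocrude1_mass_g", "biocrude2_mass_g", "solids_mass_g",
                     "nvr_mass_g"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.gas_mass_g is not None and self.gas_mass_g < 0:
            raise ValidationError("gas_mass_g must be >= 0")
        total = (self.biocrude1_mass_g + self.biocrude2_mass_g
                 + self.solids_mass_g + (self.gas_mass_g or 0.0)
                 + self.nvr_mass_g)
        if total > self.feed_dry_mass_g * 1.05:
            raise ValidationError(
                f"product masses ({total:.3f} g) exceed 1.05 x feed "
                f"({self.feed_dry_mass_g:.3f} g)"
            )

    @property
    def biocrude_mass_g(self) -> float:
        """Total biocrude, B1 (DCM-soluble) + B2 (acetone-soluble)."""
        return self.biocrude1_mass_g + self.biocrude2_mass_g


@dataclass
class FractionProperties:
    """Elemental composition (mass %) and HHV of a product fraction."""

    carbon_pct: float
    hydrogen_pct: float
    nitrogen_pct: float
    oxygen_pct: float
    hhv_mj_per_kg: float
    ash_pct: float = 0.0
    oxygen_is_by_difference: bool = False

    def __post_init__(self) -> None:
        for name in ("carbon_pct", "hydrogen_pct", "nitrogen_pct", "ash_pct"):
            _check_pct(name, getattr(self, name))
        if self.hhv_mj_per_kg < 0:
            raise ValidationError("hhv_mj_per_kg must be >= 0")
        if self.oxygen_is_by_difference:
            # avoid a module cycle: the difference convention is one line
            expected = max(0.0, 100.0 - self.carbon_pct - self.hydrogen_pct
                           - self.nitrogen_pct - self.ash_pct)
            if abs(self.oxygen_pct - expected) > 1e-9:
                raise ValidationError(
                    f"oxygen_pct = {self.oxygen_pct} but by-difference value "
                    f"is {expected:.6f}"
                )


@dataclass
class ACPProfile:
    """Aqueous co-phase product analyses (concentrations in mg L^-1)."""

    no3_no2_mg_l: float
    nh3_n_mg_l: float
    kjeldahl_n_mg_l: float
    total_p_mg_l: float
    toc_mg_l: float
    ph: float
    nvr_pct: float

    def __post_init__(self) -> None:
        for name in ("no3_no2_mg_l", "nh3_n_mg_l", "kjeldahl_n_mg_l",
                     "total_p_mg_l", "toc_mg_l", "nvr_pct"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.ph <= 14.0):
            raise ValidationError(f"ph = {self.ph} outside [0, 14]")


@dataclass
class GasProfile:
    """Gas composition as mole fractions per species label (CO2, CO, CH4, ...)."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for label, x in self.fractions.items():
            if x < 0:
                raise ValidationError(f"gas fraction {label} = {x} negative")

    def total(self) -> float:
        return sum(self.fractions.values())


@dataclass
class ExperimentRecord:
    """One HTL run: condition, product slate, biocrude properties, co-products."""

    condition_id: str
    condition: HTLCondition
    slate: ProductSlate
    crude: FractionProperties
    acp: Optional[ACPProfile] = None
    gas: Optional[GasProfile] = None


EXPERIMENT_COLUMNS = [
    "condition_id", "temperature_c", "residence_min", "reactor",
    "catalyst_frac", "cosolvent", "cosolvent_ratio", "biomass_solvent_ratio",
    "feed_dry_mass_g", "b1_g", "b2_g", "solids_g", "gas_g", "nvr_g",
    "crude_c_pct", "crude_h_pct", "crude_n_pct", "crude_ash_pct", "crude_hhv",
    "acp_nh3", "acp_kn", "acp_no3no2", "acp_tp", "acp_toc", "acp_ph",
    "acp_nvr_pct", "gas_co2", "gas_co", "gas_ch4", "gas_c2h6",
]

# biocrude oxygen is derived downstream (oxygen_by_difference), never stored
_ACP_COLS = ["acp_nh3", "acp_kn", "acp_no3no2", "acp_tp", "acp_toc", "acp_ph",
             "acp_nvr_pct"]
_GAS_COLS = ["gas_co2", "gas_co", "gas_ch4", "gas_c2h6"]
_GAS_SPECIES = {"gas_co2": "CO2", "gas_co": "CO", "gas_ch4": "CH4",
                "gas_c2h6": "C2H6"}


def _is_blank(value: object) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def _crude_oxygen(c: float, h: float, n: float, ash: float) -> float:
    return max(0.0, 100.0 - c - h - n - ash)


def read_experiment_table(path: str | Path) -> list[ExperimentRecord]:
    """Read an experiment CSV (schema in :data:`EXPERIMENT_COLUMNS`).

    Returns one validated :class:`ExperimentRecord` per row.  The optional ACP
    and gas blocks are ``None`` when all of their cells are empty.  Any schema,
    parse or invariant violation is reported with the offending row/column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"condition_id": str})
    except Exception as exc:  # pragma: no cover - pandas messages vary
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in EXPERIMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    numeric_cols = [c for c in EXPERIMENT_COLUMNS
                    if c not in ("condition_id", "reactor", "cosolvent")]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric value in column '{col}' at row {bad[0]}: "
                f"{df.loc[bad[0], col]!r}"
            )
        df[col] = coerced

    records: list[ExperimentRecord] = []
    for idx, row in df.iterrows():
        try:
            cosolvent = row["cosolvent"]
            if _is_blank(cosolvent) or str(cosolvent).lower() in ("", "none"):
                cosolvent = None
            condition = HTLCondition(
                temperature_c=row["temperature_c"],
                residence_min=row["residence_min"],
                reactor_label=str(row["reactor"]),
                catalyst_loading_frac=row["catalyst_frac"],
                cosolvent_name=cosolvent,
                cosolvent_water_mass_ratio=row["cosolvent_ratio"],
                biomass_to_solvent_ratio=row["biomass_solvent_ratio"],
            )
            slate = ProductSlate(
                feed_dry_mass_g=row["feed_dry_mass_g"],
                biocrude1_mass_g=row["b1_g"],
                biocrude2_mass_g=row["b2_g"],
                solids_mass_g=row["solids_g"],
                nvr_mass_g=row["nvr_g"],
                gas_mass_g=None if _is_blank(row["gas_g"]) else row["gas_g"],
            )
            crude = FractionProperties(
                carbon_pct=row["crude_c_pct"],
                hydrogen_pct=row["crude_h_pct"],
                nitrogen_pct=row["crude_n_pct"],
                ash_pct=row["crude_ash_pct"],
                oxygen_pct=_crude_oxygen(row["crude_c_pct"], row["crude_h_pct"],
                                         row["crude_n_pct"],
                                         row["crude_ash_pct"]),
                hhv_mj_per_kg=row["crude_hhv"],
                oxygen_is_by_difference=True,
            )
            acp = None
            if not all(_is_blank(row[c]) for c in _ACP_COLS):
                acp = ACPProfile(
                    no3_no2_mg_l=row["acp_no3no2"], nh3_n_mg_l=row["acp_nh3"],
                    kjeldahl_n_mg_l=row["acp_kn"], total_p_mg_l=row["acp_tp"],
                    toc_mg_l=row["acp_toc"], ph=row["acp_ph"],
                    nvr_pct=row["acp_nvr_pct"],
                )
            gas = None
            if not all(_is_blank(row[c]) for c in _GAS_COLS):
                gas = GasProfile({
                    _GAS_SPECIES[c]: (0.0 if _is_blank(row[c]) else row[c])
                    for c in _GAS_COLS
                })
            records.append(ExperimentRecord(
                condition_id=str(row["condition_id"]), condition=condition,
                slate=slate, crude=crude, acp=acp, gas=gas,
            ))
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
    return records


def write_experiment_table(records: list[ExperimentRecord],
                           path: str | Path) -> Path:
    """Write records to the experiment CSV schema; inverse of the reader.

    Optional-absent blocks become empty cells.  Numeric values are written at
    full ``repr`` precision so read(write(x)) round-trips to < 1e-9.
    """
    path = Path(path)
    rows = []
    for rec in records:
        c, s = rec.condition, rec.slate
        row: dict[str, object] = {
            "condition_id": rec.condition_id,
            "temperature_c": c.temperature_c,
            "residence_min": c.residence_min,
            "reactor": c.reactor_label,
            "catalyst_frac": c.catalyst_loading_frac,
            "cosolvent": c.cosolvent_name if c.cosolvent_name else "none",
            "cosolvent_ratio": c.cosolvent_water_mass_ratio,
            "biomass_solvent_ratio": c.biomass_to_solvent_ratio,
            "feed_dry_mass_g": s.feed_dry_mass_g,
            "b1_g": s.biocrude1_mass_g,
            "b2_g": s.biocrude2_mass_g,
            "solids_g": s.solids_mass_g,
            "gas_g": s.gas_mass_g,
            "nvr_g": s.nvr_mass_g,
            "crude_c_pct": rec.crude.carbon_pct,
            "crude_h_pct": rec.crude.hydrogen_pct,
            "crude_n_pct": rec.crude.nitrogen_pct,
            "crude_ash_pct": rec.crude.ash_pct,
            "crude_hhv": rec.crude.hhv_mj_per_kg,
        }
        if rec.acp is not None:
            row.update({
                "acp_nh3": rec.acp.nh3_n_mg_l, "acp_kn": rec.acp.kjeldahl_n_mg_l,
                "acp_no3no2": rec.acp.no3_no2_mg_l, "acp_tp": rec.acp.total_p_mg_l,
                "acp_toc": rec.acp.toc_mg_l, "acp_ph": rec.acp.ph,
                "acp_nvr_pct": rec.acp.nvr_pct,
            })
        if rec.gas is not None:
            for col, species in _GAS_SPECIES.items():
                row[col] = rec.gas.fractions.get(species, 0.0)
        rows.append(row)
    df = pd.DataFrame(rows, columns=EXPERIMENT_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_feedstock_config(path: str | Path) -> FeedstockComposition:
    """Load a :class:`FeedstockComposition` from a JSON or YAML file whose keys
    mirror the dataclass field names."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping of feedstock fields")
    return FeedstockComposition(**data)
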