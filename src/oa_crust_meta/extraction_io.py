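"""Reading, validating and harmonizing study-extraction tables.

Each row of an extraction table is one ambient-vs-acidified comparison for a
single species x anatomical structure x measured parameter, carrying the raw
group means, a variance statistic in whatever form the source article
reported it (SD, SE, 95% CI, or IQR), sample sizes, measurement units,
treatment carbonate chemistry, and the biological moderators used for
subgroup analyses (taxonomic order, biogeographic zone, life-history stage,
anatomical region).

This module owns the harmonization steps that happen before any effect size
is computed: converting every variance statistic to a standard deviation,
rescaling ion-content measurements to a common unit where the source unit
permits it, and assigning the latitude-based biogeographic zone.
"""

from __future__ import annotations

import csv
import logging
import math
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "CarbonateInputs",
    "StudyRecord",
    "ExtractionError",
    "DEFAULT_CONVERSION_LEDGER",
    "DEFAULT_UNIT_LEDGER",
    "ATOMIC_MASS_G_PER_MOL",
    "read_extraction_table",
    "write_extraction_table",
    "convert_variance_to_sd",
    "standardize_units",
    "assign_biogeo_zone",
]

Order = Literal["Decapoda", "Sessilia"]
LifeStage = Literal["larvae", "juvenile", "adult"]
BiogeoZone = Literal["tropical", "temperate", "polar"]
Anatomy = Literal["carapace", "chelae", "base_plate", "parietal_plate", "other"]
Parameter = Literal["calcium", "magnesium", "hardness", "thickness"]
VarType = Literal["SD", "SE", "CI95", "IQR"]

#: Atomic masses (g/mol) used for mass-fraction <-> molar unit conversion.
ATOMIC_MASS_G_PER_MOL = {"calcium": 40.078, "magnesium": 24.305}

#: Machine-readable ledger of variance-statistic -> SD conversion constants.
#: Swappable so alternative conventions can be configured without code edits.
DEFAULT_CONVERSION_LEDGER = {
    "ci95_z": 1.96,       # normal two-sided 95% quantile
    "iqr_to_sd": 1.349,   # IQR of a normal = 1.349 * SD
}

#: Unit ledger: unit string -> (family, factor to the family's canonical unit).
#: Families: "fraction" (canonical: percent of tissue dry mass) and
#: "molar" (canonical: umol per mg dry mass). Units absent from the ledger
#: are treated as specialized/native and pass through unconverted.
DEFAULT_UNIT_LEDGER = {
    "percent_dry_mass": ("fraction", 1.0),
    "percent": ("fraction", 1.0),
    "mg_per_100mg": ("fraction", 1.0),
    "mg_per_g": ("fraction", 0.1),
    "ug_per_mg": ("fraction", 0.1),
    "g_per_kg": ("fraction", 0.1),
    "umol_per_mg": ("molar", 1.0),
    "mmol_per_g": ("molar", 1.0),
    "umol_per_g": ("molar", 1e-3),
    "mol_per_kg": ("molar", 1.0),
}


class ExtractionError(ValueError):
    """Raised for schema or row-validation failures in extraction tables."""


class CarbonateInputs(BaseModel):
    """Reported seawater chemistry from which treatment pCO2 can be solved.

    pH is on the total scale; TA and DIC in umol/kg-SW; temperature in
    degrees C; salinity in practical salinity units. At least one of TA or
    DIC must accompany pH for the carbonate system to be determined.
    """

    model_config = ConfigDict(frozen=True)

    pH_total: float = Field(gt=4.0, lt=10.0)
    TA: Optional[float] = Field(default=None, gt=0)
    DIC: Optional[float] = Field(default=None, gt=0)
    temperature: float = Field(ge=-2.0, le=40.0)
    salinity: float = Field(ge=5.0, le=45.0)

    @model_validator(mode="after")
    def _needs_ta_or_dic(self) -> "CarbonateInputs":
        if self.TA is None and self.DIC is None:
            raise ValueError("chemistry requires TA or DIC alongside pH")
        return self


class StudyRecord(BaseModel):
    """One extracted ambient-vs-acidified comparison.

    ``mean_control``/``mean_treatment`` are the ambient and acidified group
    means (strictly positive: the log response ratio requires it);
    ``var_stat_*`` holds the variance statistic as reported, with its form in
    ``var_type`` (for CI95 the statistic is the half-width of the interval).
    Exactly one route to the treatment pCO2 must exist: either
    ``pco2_treatment_uatm`` directly, or ``chemistry`` sufficient to solve it.
    """

    model_config = ConfigDict(validate_assignment=True)

    record_id: str
    article_id: str
    species: str
    order: Order
    life_stage: LifeStage
    latitude_deg: Optional[float] = None
    biogeo_zone: Optional[BiogeoZone] = None
    anatomy: Anatomy
    parameter: Parameter
    unit: str
    mean_control: float = Field(gt=0)
    mean_treatment: float = Field(gt=0)
    var_stat_control: float = Field(ge=0)
    var_stat_treatment: float = Field(ge=0)
    var_type: VarType
    n_control: int = Field(ge=1)
    n_treatment: int = Field(ge=1)
    pco2_treatment_uatm: Optional[float] = Field(default=None, gt=0)
    chemistry: Optional[CarbonateInputs] = None
    final_timepoint: bool = True

    @model_validator(mode="after")
    def _check_chemistry_route(self) -> "StudyRecord":
        if self.pco2_treatment_uatm is None and self.chemistry is None:
            raise ValueError(
                f"record {self.record_id!r}: needs pco2_treatment_uatm or "
                "chemistry (pH with TA or DIC)"
            )
        if self.latitude_deg is None and self.biogeo_zone is None:
            raise ValueError(
                f"record {self.record_id!r}: needs latitude_deg or biogeo_zone"
            )
        if self.latitude_deg is not None and abs(self.latitude_deg) > 90:
            raise ValueError(
                f"record {self.record_id!r}: |latitude| > 90"
            )
        if self.biogeo_zone is None:
            # assignment triggers validate_assignment; bypass via __dict__
            self.__dict__["biogeo_zone"] = assign_biogeo_zone(self.latitude_deg)
        return self

    def sd_control(self, ledger: dict | None = None) -> float:
        return convert_variance_to_sd(
            self.var_stat_control, self.var_type, self.n_control, ledger=ledger
        )

    def sd_treatment(self, ledger: dict | None = None) -> float:
        return convert_variance_to_sd(
            self.var_stat_treatment, self.var_type, self.n_treatment, ledger=ledger
        )


def convert_variance_to_sd(
    value: float,
    var_type: str,
    n: Optional[int] = None,
    ci_low: Optional[float] = None,
    ci_high: Optional[float] = None,
    ledger: dict | None = None,
) -> float:
    """Convert a reported variance statistic to a standard deviation.

    Conversions (constants from ``ledger``, default
    :data:`DEFAULT_CONVERSION_LEDGER`):

    * ``SD``   -> identity
    * ``SE``   -> ``SE * sqrt(n)`` (requires n >= 2)
    * ``CI95`` -> ``(ci_high - ci_low) * sqrt(n) / (2 * z)``; if only a
      single value is given it is taken to be the half-width, so
      ``value * sqrt(n) / z``
    * ``IQR``  -> ``IQR / 1.349`` (normal-distribution identity)
    """
    ledger = {**DEFAULT_CONVERSION_LEDGER, **(ledger or {})}
    if value is not None and value < 0:
        raise ValueError("variance statistic must be nonnegative")
    if var_type == "SD":
        return float(value)
    if var_type == "SE":
        if n is None or n < 2:
            raise ValueError("SE -> SD conversion requires n >= 2")
        return float(value) * math.sqrt(n)
    if var_type == "CI95":
        z = ledger["ci95_z"]
        if ci_low is not None and ci_high is not None:
            if ci_high < ci_low:
                raise ValueError("ci_high must be >= ci_low")
            half = (ci_high - ci_low) / 2.0
        else:
            half = float(value)
        if n is None or n < 1:
            raise ValueError("CI95 -> SD conversion requires n")
        return half * math.sqrt(n) / z
    if var_type == "IQR":
        return float(value) / ledger["iqr_to_sd"]
    raise ValueError(f"unknown variance statistic type {var_type!r}")


def assign_biogeo_zone(latitude_deg: float) -> str:
    """Assign the latitude-based biogeographic zone.

    Tropical: |lat| in [0, 35); temperate: [35, 50); polar: [50, 90].
    Symmetric across hemispheres.
    """
    a = abs(latitude_deg)
    if a > 90:
        raise ValueError(f"|latitude| must be <= 90, got {latitude_deg}")
    if a < 35:
        return "tropical"
    if a < 50:
        return "temperate"
    return "polar"


def _unit_to_canonical(unit: str, ledger: dict) -> tuple[str, float] | None:
    return ledger.get(unit)


def standardize_units(
    record: StudyRecord,
    target: Literal["percent_dry_mass", "umol_per_mg", "native"] = "percent_dry_mass",
    unit_ledger: dict | None = None,
) -> StudyRecord:
    """Rescale an ion-content record to a common measurement unit.

    Mean and variance statistic are multiplied by the same factor, so the
    downstream log response ratio and its variance are unchanged (both are
    invariant to common rescaling of the two groups). Mass-fraction units
    convert to molar units (and back) through the element's atomic mass.
    Units absent from the ledger are specialized (e.g. instrument counts) and
    pass through flagged as native.
    """
    if target == "native":
        return record
    if record.parameter not in ATOMIC_MASS_G_PER_MOL:
        raise ValueError("unit standardization applies to calcium/magnesium only")
    ledger = unit_ledger or DEFAULT_UNIT_LEDGER
    entry = _unit_to_canonical(record.unit, ledger)
    if entry is None:
        if record.unit in ("native", "percent_dry_mass", "umol_per_mg"):
            return record
        logger.info(
            "record %s: unit %r not in ledger; kept native", record.record_id, record.unit
        )
        return record
    family, factor = entry
    mass = ATOMIC_MASS_G_PER_MOL[record.parameter]
    # canonical fraction unit: percent dry mass; canonical molar: umol/mg.
    # X percent dry mass = 10*X ug/mg; ug/mg / (g/mol) = umol/mg.
    if target == "percent_dry_mass":
        scale = factor if family == "fraction" else factor * mass / 10.0
        new_unit = "percent_dry_mass"
    elif target == "umol_per_mg":
        scale = factor if family == "molar" else factor * 10.0 / mass
        new_unit = "umol_per_mg"
    else:
        raise ValueError(f"unknown target unit {target!r}")
    return record.model_copy(
        update={
            "mean_control": record.mean_control * scale,
            "mean_treatment": record.mean_treatment * scale,
            "var_stat_control": record.var_stat_control * scale,
            "var_stat_treatment": record.var_stat_treatment * scale,
            "unit": new_unit,
        }
    )


# Columns of the canonical extraction CSV, in file order.
CSV_COLUMNS = [
    "record_id", "article_id", "species", "order", "life_stage",
    "latitude_deg", "biogeo_zone", "anatomy", "parameter", "unit",
    "mean_control", "mean_treatment", "var_stat_control", "var_stat_treatment",
    "var_type", "n_control", "n_treatment", "pco2_treatment_uatm",
    "pH_total", "TA", "DIC", "temperature", "salinity", "final_timepoint",
]

_CHEM_FIELDS = ["pH_total", "TA", "DIC", "temperature", "salinity"]


def _parse_row(row: dict, column_map: dict[str, str]) -> StudyRecord:
    get = lambda field: row.get(column_map.get(field, field)) or None
    chem_vals = {f: get(f) for f in _CHEM_FIELDS}
    chemistry = None
    if chem_vals["pH_total"] not in (None, ""):
        chemistry = CarbonateInputs(
            pH_total=float(chem_vals["pH_total"]),
            TA=float(chem_vals["TA"]) if chem_vals["TA"] else None,
            DIC=float(chem_vals["DIC"]) if chem_vals["DIC"] else None,
            temperature=float(chem_vals["temperature"]),
            salinity=float(chem_vals["salinity"]),
        )
    ft = get("final_timepoint")
    return StudyRecord(
        record_id=get("record_id"),
        article_id=get("article_id"),
        species=get("species"),
        order=get("order"),
        life_stage=get("life_stage"),
        latitude_deg=float(get("latitude_deg")) if get("latitude_deg") else None,
        biogeo_zone=get("biogeo_zone"),
        anatomy=get("anatomy"),
        parameter=get("parameter"),
        unit=get("unit"),
        mean_control=float(get("mean_control")),
        mean_treatment=float(get("mean_treatment")),
        var_stat_control=float(get("var_stat_control")),
        var_stat_treatment=float(get("var_stat_treatment")),
        var_type=get("var_type"),
        n_control=int(float(get("n_control"))),
        n_treatment=int(float(get("n_treatment"))),
        pco2_treatment_uatm=(
            float(get("pco2_treatment_uatm")) if get("pco2_treatment_uatm") else None
        ),
        chemistry=chemistry,
        final_timepoint=(str(ft).strip().lower() not in ("false", "0", "no"))
        if ft is not None
        else True,
    )


def read_extraction_table(
    path,
    column_map: dict[str, str] | None = None,
    strict: bool = True,
    keep_final_timepoint_only: bool = True,
    delimiter: str = ",",
):
    """Read an extraction CSV into validated :class:`StudyRecord` objects.

    Rows that fail validation raise :class:`ExtractionError` naming the row
    index and record id when ``strict``; otherwise they are logged and
    skipped. When the table carries a timepoint flag, only rows from the
    final measurement timepoint are kept (repeated-measure studies
    contribute their last timepoint only).

    Returns the records in file order.
    """
    column_map = column_map or {}
    records: list[StudyRecord] = []
    rejects: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ExtractionError(f"{path}: empty file, no header row")
        mapped = {column_map.get(c, c) for c in ("record_id", "mean_control", "mean_treatment")}
        missing = mapped - set(reader.fieldnames)
        if missing:
            raise ExtractionError(f"{path}: missing mandatory column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                rec = _parse_row(row, column_map)
            except (ValueError, TypeError) as exc:
                msg = f"row {i} (record_id={row.get('record_id')!r}): {exc}"
                if strict:
                    raise ExtractionError(msg) from exc
                logger.warning("rejected %s", msg)
                rejects.append((i, str(exc)))
                continue
            if keep_final_timepoint_only and not rec.final_timepoint:
                continue
            records.append(rec)
    return records


def write_extraction_table(records: Sequence[StudyRecord], path, delimiter: str = ",") -> None:
    """Write records back to the canonical extraction CSV layout."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS, delimiter=delimiter)
        writer.writeheader()
        for rec in records:
            row = {c: "" for c in CSV_COLUMNS}
            d = rec.model_dump()
            chem = d.pop("chemistry", None)
            for key, val in d.items():
                if key in row and val is not None:
                    row[key] = val
            if chem:
                for f in _CHEM_FIELDS:
                    if chem.get(f) is not None:
                        row[f] = chem[f]
            row["final_timepoint"] = str(rec.final_timepoint).lower()
            writer.writerow(row)
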