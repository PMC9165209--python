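"""Log response ratios, their sampling variances, and pCO2 binning.

The effect size throughout is the log response ratio

    L = ln(X_E / X_C) = ln X_E - ln X C

with X_E the acidified-treatment mean and X_C the ambient-control mean.
Its within-study sampling variance combines both groups' standard
deviations, sample sizes and means:

    v = S_E^2 / (n_E X_E^2) + S_C^2 / (n_C X_C^2)

Treatment intensity is the acidified seawater pCO2, grouped into the bins
500-999, 1000-1499, 1500-1999 and 2000+ uatm (treated as half-open
intervals on the continuous uatm scale). Treatments below 500 uatm fall
outside all bins and are excluded from binned analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .extraction_io import StudyRecord

__all__ = [
    "EffectSize",
    "PCO2_BINS",
    "OUT_OF_RANGE",
    "log_response_ratio",
    "pooled_variance",
    "assign_pco2_bin",
    "compute_effect_sizes",
    "effects_frame",
]

#: Bin label -> [low, high) interval in uatm. The last bin is unbounded.
PCO2_BINS = {
    "500-999": (500.0, 1000.0),
    "1000-1499": (1000.0, 1500.0),
    "1500-1999": (1500.0, 2000.0),
    "2000+": (2000.0, math.inf),
}

OUT_OF_RANGE = "out_of_range"

#: Floor applied to degenerate zero variances when used as inverse weights.
DEFAULT_VARIANCE_FLOOR = 1e-8


def log_response_ratio(mean_treatment: float, mean_control: float) -> float:
    """L = ln(X_E) - ln(X_C). Both means must be strictly positive."""
    if mean_treatment <= 0 or mean_control <= 0:
        raise ValueError("log response ratio requires strictly positive means")
    return math.log(mean_treatment) - math.log(mean_control)


def pooled_variance(
    sd_treatment: float,
    n_treatment: int,
    mean_treatment: float,
    sd_control: float,
    n_control: int,
    mean_control: float,
) -> float:
    """Within-study sampling variance of the log response ratio.

    v = S_E^2/(n_E X_E^2) + S_C^2/(n_C X_C^2). Returns 0 (with a warning)
    when both SDs are exactly zero — a reporting artifact, not real
    precision.
    """
    if mean_treatment <= 0 or mean_control <= 0:
        raise ValueError("pooled variance requires strictly positive means")
    if sd_treatment < 0 or sd_control < 0:
        raise ValueError("standard deviations must be nonnegative")
    if n_treatment < 1 or n_control < 1:
        raise ValueError("sample sizes must be >= 1")
    if sd_treatment == 0 and sd_control == 0:
        warnings.warn(
            "both group SDs are zero: degenerate zero variance", stacklevel=2
        )
        return 0.0
    return sd_treatment**2 / (n_treatment * mean_treatment**2) + sd_control**2 / (
        n_control * mean_control**2
    )


def assign_pco2_bin(pco2_treatment_uatm: float) -> str:
    """Map a treatment pCO2 (uatm) to its bin label.

    Values below 500 uatm return :data:`OUT_OF_RANGE` (a marker, not an
    error); every value >= 500 maps to exactly one bin.
    """
    if pco2_treatment_uatm <= 0:
        raise ValueError("pCO2 must be positive")
    for label, (lo, hi) in PCO2_BINS.items():
        if lo <= pco2_treatment_uatm < hi:
            return label
    return OUT_OF_RANGE


@dataclass(frozen=True)
class EffectSize:
    """One log response ratio with its variance, bin, and moderators."""

    record_id: str
    article_id: str
    species: str
    parameter: str
    L: float
    v: float
    pco2_bin: str
    order: str
    biogeo_zone: str
    life_stage: str
    anatomy: str
    pco2_treatment_uatm: Optional[float] = None
    flags: tuple = field(default_factory=tuple)


def compute_effect_sizes(
    records: Sequence[StudyRecord],
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    conversion_ledger: dict | None = None,
) -> list[EffectSize]:
    """Compute one :class:`EffectSize` per study record.

    Variance statistics are first harmonized to SDs via the conversion
    ledger. Degenerate zero variances are floored at ``variance_floor`` so
    no record receives infinite inverse-variance weight. Records must
    already carry ``pco2_treatment_uatm`` (run the carbonate solver first
    for records that report chemistry instead).
    """
    out: list[EffectSize] = []
    for rec in records:
        if rec.pco2_treatment_uatm is None:
            raise ValueError(
                f"record {rec.record_id!r} has no treatment pCO2; "
                "derive it from chemistry first"
            )
        L = log_response_ratio(rec.mean_treatment, rec.mean_control)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = pooled_variance(
                rec.sd_treatment(conversion_ledger),
                rec.n_treatment,
                rec.mean_treatment,
                rec.sd_control(conversion_ledger),
                rec.n_control,
                rec.mean_control,
            )
        flags = ()
        if v <= 0:
            v = variance_floor
            flags = ("degenerate_variance_floored",)
        out.append(
            EffectSize(
                record_id=rec.record_id,
                article_id=rec.article_id,
                species=rec.species,
                parameter=rec.parameter,
                L=L,
                v=v,
                pco2_bin=assign_pco2_bin(rec.pco2_treatment_uatm),
                order=rec.order,
                biogeo_zone=rec.biogeo_zone,
                life_stage=rec.life_stage,
                anatomy=rec.anatomy,
                pco2_treatment_uatm=rec.pco2_treatment_uatm,
                flags=flags,
            )
        )
    return out


def effects_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Tabular view of effect sizes for export and joins."""
    return pd.DataFrame(
        [
            {
                "record_id": e.record_id,
                "article_id": e.article_id,
                "species": e.species,
                "parameter": e.parameter,
                "L": e.L,
                "v": e.v,
                "pco2_bin": e.pco2_bin,
                "order": e.order,
                "biogeo_zone": e.biogeo_zone,
                "life_stage": e.life_stage,
                "anatomy": e.anatomy,
                "pco2_treatment_uatm": e.pco2_treatment_uatm,
            }
            for e in effects
        ]
    )
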