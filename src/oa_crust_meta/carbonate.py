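"""Seawater carbonate-system solver: treatment pCO2 from pH plus TA or DIC.

Source articles that manipulate seawater CO2 do not always report the
partial pressure of CO2 directly; many report pH together with total
alkalinity (TA) or dissolved inorganic carbon (DIC). Given two carbonate
parameters plus temperature and salinity the full system is determined, and
pCO2 follows from the dissolved CO2 concentration and Henry's-law
solubility.

Constant set (total pH scale, surface pressure, zero nutrients):

* K1, K2 — Lueker, Dickson & Keeling (2000), carbonic acid dissociation
* K0 — Weiss (1974), CO2 solubility in seawater
* KB — Dickson (1990), boric acid
* KW — Millero (1995), water self-ionization
* B_T — Uppström (1974), total borate from salinity

pCO2 is reported (not fugacity); the fugacity correction is under 1% at
surface conditions and is omitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

__all__ = [
    "CarbonateState",
    "InfeasibleChemistryError",
    "k0_weiss",
    "k1_lueker",
    "k2_lueker",
    "kb_dickson",
    "kw_millero",
    "total_borate",
    "solve_pco2_from_pH_TA",
    "solve_pco2_from_pH_DIC",
    "solve_dic_from_pH_TA",
    "solve_pH_from_TA_DIC",
    "solve_pH_from_TA_pCO2",
    "solve_record_pco2",
]

CONSTANTS_SET = "Lueker00-K1K2/Dickson90-KB/Millero95-KW/Weiss74-K0/Uppstrom74-BT"

T_RANGE = (-2.0, 40.0)
S_RANGE = (5.0, 45.0)


class InfeasibleChemistryError(ValueError):
    """Raised when the stated pH/TA combination admits no positive carbonate
    alkalinity (the borate and water corrections exceed TA)."""


def _kelvin(t_c: float) -> float:
    return t_c + 273.15


def _check_ranges(t_c: float, s: float) -> None:
    if not (T_RANGE[0] <= t_c <= T_RANGE[1]):
        raise ValueError(f"temperature {t_c} degC outside {T_RANGE}")
    if not (S_RANGE[0] <= s <= S_RANGE[1]):
        raise ValueError(f"salinity {s} outside {S_RANGE}")


def k0_weiss(t_c: float, s: float) -> float:
    """CO2 solubility K0 (mol kg-1 atm-1), Weiss (1974)."""
    T = _kelvin(t_c)
    ln_k0 = (
        -60.2409
        + 93.4517 * (100.0 / T)
        + 23.3585 * math.log(T / 100.0)
        + s * (0.023517 - 0.023656 * (T / 100.0) + 0.0047036 * (T / 100.0) ** 2)
    )
    return math.exp(ln_k0)


def k1_lueker(t_c: float, s: float) -> float:
    """First carbonic acid dissociation constant, total scale (mol/kg-SW)."""
    T = _kelvin(t_c)
    pk1 = 3633.86 / T - 61.2172 + 9.6777 * math.log(T) - 0.011555 * s + 0.0001152 * s**2
    return 10.0 ** (-pk1)


def k2_lueker(t_c: float, s: float) -> float:
    """Second carbonic acid dissociation constant, total scale (mol/kg-SW)."""
    T = _kelvin(t_c)
    pk2 = 471.78 / T + 25.929 - 3.16967 * math.log(T) - 0.01781 * s + 0.0001122 * s**2
    return 10.0 ** (-pk2)


def kb_dickson(t_c: float, s: float) -> float:
    """Boric acid dissociation constant, total scale (mol/kg-SW)."""
    T = _kelvin(t_c)
    ln_kb = (
        (-8966.90 - 2890.53 * s**0.5 - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s**2) / T
        + 148.0248
        + 137.1942 * s**0.5
        + 1.62142 * s
        + (-24.4344 - 25.085 * s**0.5 - 0.2474 * s) * math.log(T)
        + 0.053105 * s**0.5 * T
    )
    return math.exp(ln_kb)


def kw_millero(t_c: float, s: float) -> float:
    """Water self-ionization constant (mol/kg-SW)^2."""
    T = _kelvin(t_c)
    ln_kw = (
        148.9802
        - 13847.26 / T
        - 23.6521 * math.log(T)
        + (118.67 / T - 5.977 + 1.0495 * math.log(T)) * s**0.5
        - 0.01615 * s
    )
    return math.exp(ln_kw)


def total_borate(s: float) -> float:
    """Total borate B_T (mol/kg-SW) from salinity, Uppström (1974)."""
    return 0.0004157 * s / 35.0


@dataclass(frozen=True)
class CarbonateState:
    """A solved seawater carbonate system.

    TA and DIC in umol/kg-SW, pCO2 in uatm, temperature degC, salinity PSU.
    """

    pH_total: float
    TA: Optional[float]
    DIC: float
    temperature: float
    salinity: float
    pCO2: float
    constants_set: str = CONSTANTS_SET


def _carbonate_alkalinity(h: float, ta_mol: float, t_c: float, s: float) -> float:
    """TA minus borate and water contributions: HCO3 + 2*CO3 (mol/kg)."""
    kb = kb_dickson(t_c, s)
    kw = kw_millero(t_c, s)
    bt = total_borate(s)
    ca = ta_mol - bt * kb / (kb + h) - kw / h + h
    if ca <= 0:
        raise InfeasibleChemistryError(
            "carbonate alkalinity non-positive after borate/water correction"
        )
    return ca


def solve_pco2_from_pH_TA(
    pH_total: float, TA: float, temperature: float, salinity: float
) -> float:
    """pCO2 (uatm) from total-scale pH and total alkalinity (umol/kg-SW)."""
    _check_ranges(temperature, salinity)
    h = 10.0 ** (-pH_total)
    ta_mol = TA * 1e-6
    ca = _carbonate_alkalinity(h, ta_mol, temperature, salinity)
    k1 = k1_lueker(temperature, salinity)
    k2 = k2_lueker(temperature, salinity)
    # CA = [HCO3](1 + 2 K2/[H])  =>  speciation at fixed H
    hco3 = ca / (1.0 + 2.0 * k2 / h)
    co2_star = h * hco3 / k1
    return co2_star / k0_weiss(temperature, salinity) * 1e6


def solve_pco2_from_pH_DIC(
    pH_total: float, DIC: float, temperature: float, salinity: float
) -> float:
    """pCO2 (uatm) from total-scale pH and DIC (umol/kg-SW)."""
    _check_ranges(temperature, salinity)
    h = 10.0 ** (-pH_total)
    k1 = k1_lueker(temperature, salinity)
    k2 = k2_lueker(temperature, salinity)
    denom = 1.0 + k1 / h + k1 * k2 / h**2
    co2_star = DIC * 1e-6 / denom
    return co2_star / k0_weiss(temperature, salinity) * 1e6


def solve_dic_from_pH_TA(
    pH_total: float, TA: float, temperature: float, salinity: float
) -> float:
    """DIC (umol/kg-SW) consistent with the given pH and TA."""
    _check_ranges(temperature, salinity)
    h = 10.0 ** (-pH_total)
    ca = _carbonate_alkalinity(h, TA * 1e-6, temperature, salinity)
    k1 = k1_lueker(temperature, salinity)
    k2 = k2_lueker(temperature, salinity)
    hco3 = ca / (1.0 + 2.0 * k2 / h)
    co3 = hco3 * k2 / h
    co2_star = h * hco3 / k1
    return (co2_star + hco3 + co3) * 1e6


def _ta_residual(ph: float, ta_umol: float, dic_umol: float, t_c: float, s: float) -> float:
    h = 10.0 ** (-ph)
    k1 = k1_lueker(t_c, s)
    k2 = k2_lueker(t_c, s)
    kb = kb_dickson(t_c, s)
    kw = kw_millero(t_c, s)
    bt = total_borate(s)
    dic = dic_umol * 1e-6
    denom = 1.0 + k1 / h + k1 * k2 / h**2
    co2 = dic / denom
    hco3 = co2 * k1 / h
    co3 = hco3 * k2 / h
    ta = hco3 + 2 * co3 + bt * kb / (kb + h) + kw / h - h
    return ta - ta_umol * 1e-6


def solve_pH_from_TA_DIC(
    TA: float, DIC: float, temperature: float, salinity: float
) -> float:
    """Total-scale pH consistent with the given TA and DIC (umol/kg-SW)."""
    _check_ranges(temperature, salinity)
    return brentq(_ta_residual, 4.0, 10.0, args=(TA, DIC, temperature, salinity), xtol=1e-10)


def solve_pH_from_TA_pCO2(
    TA: float, pCO2: float, temperature: float, salinity: float
) -> float:
    """Total-scale pH consistent with the given TA (umol/kg-SW) and pCO2 (uatm)."""
    _check_ranges(temperature, salinity)

    def resid(ph: float) -> float:
        return solve_pco2_from_pH_TA(ph, TA, temperature, salinity) - pCO2

    return brentq(resid, 5.5, 9.5, xtol=1e-10)


def solve_record_pco2(chemistry) -> CarbonateState:
    """Solve a record's :class:`~oa_crust_meta.extraction_io.CarbonateInputs`.

    Prefers the pH+TA route when TA is present, otherwise pH+DIC.
    """
    if chemistry.TA is not None:
        pco2 = solve_pco2_from_pH_TA(
            chemistry.pH_total, chemistry.TA, chemistry.temperature, chemistry.salinity
        )
        dic = solve_dic_from_pH_TA(
            chemistry.pH_total, chemistry.TA, chemistry.temperature, chemistry.salinity
        )
    else:
        pco2 = solve_pco2_from_pH_DIC(
            chemistry.pH_total, chemistry.DIC, chemistry.temperature, chemistry.salinity
        )
        dic = chemistry.DIC
    return CarbonateState(
        pH_total=chemistry.pH_total,
        TA=chemistry.TA,
        DIC=dic,
        temperature=chemistry.temperature,
        salinity=chemistry.salinity,
        pCO2=pco2,
    )
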