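"""Synthetic extraction-table generator with known latent parameters.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised and parameter recovery scored without
any external download:

* per-bin true effects: a study in bin b draws its true log response ratio
  theta_i ~ Normal(mu_b, tau2);
* paired Ca-Mg structure: the magnesium effect of a paired experiment is
  theta_Mg = mu_Mg,b + beta_b * (theta_Ca - mu_Ca,b) + Normal(0, tau2_resid),
  so the within-bin regression of Mg on Ca effects has true slope beta_b;
* within-study sampling noise: group means are reported as sample means of
  n draws from a positive-truncated normal (so small-n log-ratio bias is
  present, as in real extractions), with group SD = CV * true mean;
* reporting heterogeneity: each record's variance statistic is re-encoded
  as SD, SE, 95% CI half-width, or IQR per a configurable mixture, exactly
  invertible by the conversion ledger;
* chemistry-only records: a configurable fraction reports pH + TA instead
  of pCO2, exercising the carbonate solver path (the latent pCO2 is stored
  in the truth sidecar).

Default study counts per bin and parameter mirror a realistic synthesis of
the ocean-acidification crustacean literature (51 Ca, 45 Mg, 19 hardness,
18 thickness effects), and default true effects follow its qualitative
sign pattern across bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import carbonate
from .extraction_io import ATOMIC_MASS_G_PER_MOL, CarbonateInputs, StudyRecord

__all__ = [
    "SyntheticConfig",
    "generate_dataset",
    "generate_with_truth",
    "encode_variance_reports",
    "simulate_effects",
]

BINS = ("500-999", "1000-1499", "1500-1999", "2000+")
_BIN_RANGES = {
    "500-999": (500.0, 1000.0),
    "1000-1499": (1000.0, 1500.0),
    "1500-1999": (1500.0, 2000.0),
    "2000+": (2000.0, 3000.0),
}


def _default_mu():
    # sign pattern across bins: Ca (+,+,-,-), Mg (-,+,-,+),
    # biomechanics (-,ND,-,=), thickness (-,-,-,=)
    return {
        "calcium": {"500-999": 0.0065, "1000-1499": 0.0193, "1500-1999": -0.0796, "2000+": -0.017},
        "magnesium": {"500-999": -0.0196, "1000-1499": 0.0152, "1500-1999": -0.0799, "2000+": 0.0483},
        "hardness": {"500-999": -0.10, "1000-1499": 0.0, "1500-1999": -0.12, "2000+": 0.0},
        "thickness": {"500-999": -0.05, "1000-1499": -0.05, "1500-1999": -0.05, "2000+": 0.0},
    }


def _default_k():
    return {
        "calcium": {"500-999": 16, "1000-1499": 12, "1500-1999": 15, "2000+": 8},
        "magnesium": {"500-999": 14, "1000-1499": 9, "1500-1999": 14, "2000+": 8},
        "hardness": {"500-999": 8, "1000-1499": 0, "1500-1999": 10, "2000+": 1},
        "thickness": {"500-999": 8, "1000-1499": 1, "1500-1999": 8, "2000+": 1},
    }


def _default_beta():
    return {"500-999": -0.55, "1000-1499": 0.26, "1500-1999": 0.05, "2000+": 0.0}


@dataclass
class SyntheticConfig:
    """Tunable parameters of the generator; defaults define the reference
    study conditions used throughout the test suite."""

    mu: dict = field(default_factory=_default_mu)
    k_bin: dict = field(default_factory=_default_k)
    tau2: float = 0.01
    beta: dict = field(default_factory=_default_beta)
    tau2_mg_resid: float = 0.005
    cv_range: tuple = (0.05, 0.30)
    n_range: tuple = (3, 10)
    order_probs: dict = field(
        default_factory=lambda: {"Decapoda": 0.75, "Sessilia": 0.25}
    )
    zone_probs: dict = field(
        default_factory=lambda: {"polar": 0.45, "temperate": 0.40, "tropical": 0.15}
    )
    stage_probs: dict = field(
        default_factory=lambda: {"larvae": 0.10, "juvenile": 0.35, "adult": 0.55}
    )
    # ion units mirror the reporting mix of real extractions:
    # about half percent-dry-mass, an eighth umol/mg, the rest specialized
    unit_probs: dict = field(
        default_factory=lambda: {
            "percent_dry_mass": 0.49,
            "umol_per_mg": 0.12,
            "native_specialized": 0.39,
        }
    )
    var_mixture: dict = field(
        default_factory=lambda: {"SD": 0.40, "SE": 0.40, "CI95": 0.10, "IQR": 0.10}
    )
    chemistry_fraction: float = 0.10
    rng_seed: int = 0

    def validate(self) -> None:
        if self.tau2 < 0 or self.tau2_mg_resid < 0:
            raise ValueError("tau2 values must be >= 0")
        if not (0 < self.cv_range[0] <= self.cv_range[1] < 1):
            raise ValueError("cv_range must be within (0, 1)")
        if self.n_range[0] < 1 or self.n_range[1] < self.n_range[0]:
            raise ValueError("invalid sample-size range")
        if not (0 <= self.chemistry_fraction <= 1):
            raise ValueError("chemistry_fraction must be in [0, 1]")
        for name, probs in (
            ("order_probs", self.order_probs),
            ("zone_probs", self.zone_probs),
            ("stage_probs", self.stage_probs),
            ("unit_probs", self.unit_probs),
            ("var_mixture", self.var_mixture),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for param, per_bin in self.k_bin.items():
            if any(k < 0 for k in per_bin.values()):
                raise ValueError(f"negative study count for {param}")


# Log-scale location/scale of control means per parameter and unit family.
_MEAN_DISTS = {
    ("calcium", "percent_dry_mass"): (math.log(20.0), 0.30),
    ("magnesium", "percent_dry_mass"): (math.log(2.0), 0.30),
    ("calcium", "umol_per_mg"): (math.log(20.0 * 10 / ATOMIC_MASS_G_PER_MOL["calcium"]), 0.30),
    ("magnesium", "umol_per_mg"): (math.log(2.0 * 10 / ATOMIC_MASS_G_PER_MOL["magnesium"]), 0.30),
    ("calcium", "native_specialized"): (math.log(100.0), 0.8),
    ("magnesium", "native_specialized"): (math.log(100.0), 0.8),
    ("hardness", "vickers"): (math.log(200.0), 0.40),
    ("thickness", "um"): (math.log(100.0), 0.40),
}

_ZONE_LAT = {"tropical": (0.0, 35.0), "temperate": (35.0, 50.0), "polar": (50.0, 75.0)}
_ZONE_TEMP = {"tropical": 26.0, "temperate": 14.0, "polar": 4.0}

_SPECIES = {
    "Decapoda": [
        "Carcinus maenas", "Chionoecetes bairdi", "Paralithodes camtschaticus",
        "Homarus americanus", "Callinectes sapidus", "Necora puber",
    ],
    "Sessilia": ["Amphibalanus amphitrite", "Amphibalanus improvisus", "Semibalanus balanoides"],
}


def _choice(rng: np.random.Generator, probs: dict) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]


def _truncnorm_mean(rng, mean, sd, n) -> float:
    """Sample mean of n positive-truncated Normal(mean, sd) draws."""
    draws = rng.normal(mean, sd, size=n)
    # resample negatives (truncation at zero keeps means positive)
    bad = draws <= 0
    while bad.any():
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = draws <= 0
    return float(draws.mean())


def encode_variance_reports(
    sd: float, var_type: str, n: int
) -> float:
    """Re-express a true SD in the assigned reporting format.

    The encoding is the exact inverse of the SD-harmonization ledger:
    SE = SD/sqrt(n); the 95% CI half-width = 1.96*SD/sqrt(n);
    IQR = 1.349*SD.
    """
    if var_type == "SD":
        return sd
    if var_type == "SE":
        return sd / math.sqrt(n)
    if var_type == "CI95":
        return 1.96 * sd / math.sqrt(n)
    if var_type == "IQR":
        return 1.349 * sd
    raise ValueError(f"unknown var_type {var_type!r}")


def _make_record(
    rng, config, rid, aid, species, order, stage, zone, lat, anatomy,
    parameter, unit, theta, pco2, use_chemistry,
) -> StudyRecord:
    loc, scale = _MEAN_DISTS[(parameter, unit)]
    x_c_true = float(np.exp(rng.normal(loc, scale)))
    x_e_true = x_c_true * math.exp(theta)
    cv = float(rng.uniform(*config.cv_range))
    n_c = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
    n_e = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
    sd_c, sd_e = cv * x_c_true, cv * x_e_true
    mean_c = _truncnorm_mean(rng, x_c_true, sd_c, n_c)
    mean_e = _truncnorm_mean(rng, x_e_true, sd_e, n_e)
    var_type = _choice(rng, config.var_mixture)
    chem = None
    pco2_field: Optional[float] = pco2
    if use_chemistry:
        temp = _ZONE_TEMP[zone]
        ph = carbonate.solve_pH_from_TA_pCO2(2300.0, pco2, temp, 35.0)
        chem = CarbonateInputs(
            pH_total=round(ph, 4), TA=2300.0, DIC=None, temperature=temp, salinity=35.0
        )
        pco2_field = None
    return StudyRecord(
        record_id=rid,
        article_id=aid,
        species=species,
        order=order,
        life_stage=stage,
        latitude_deg=lat,
        biogeo_zone=zone,
        anatomy=anatomy,
        parameter=parameter,
        unit=unit if unit != "native_specialized" else "instrument_counts",
        mean_control=mean_c,
        mean_treatment=mean_e,
        var_stat_control=encode_variance_reports(sd_c, var_type, n_c),
        var_stat_treatment=encode_variance_reports(sd_e, var_type, n_e),
        var_type=var_type,
        n_control=n_c,
        n_treatment=n_e,
        pco2_treatment_uatm=pco2_field,
        chemistry=chem,
    )


def generate_with_truth(config: SyntheticConfig):
    """Generate records plus a sidecar of every latent parameter drawn."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    records: list[StudyRecord] = []
    truth: dict = {
        "mu": config.mu,
        "tau2": config.tau2,
        "beta": config.beta,
        "tau2_mg_resid": config.tau2_mg_resid,
        "rng_seed": config.rng_seed,
        "records": {},
    }
    counter = 0

    def next_id(prefix):
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:04d}"

    # --- paired ion experiments -------------------------------------------
    for b in BINS:
        k_ca = config.k_bin.get("calcium", {}).get(b, 0)
        k_mg = config.k_bin.get("magnesium", {}).get(b, 0)
        k_pair = min(k_ca, k_mg)
        for j in range(max(k_ca, k_mg)):
            order = _choice(rng, config.order_probs)
            zone = _choice(rng, config.zone_probs)
            lat = float(rng.uniform(*_ZONE_LAT[zone])) * (1 if rng.random() < 0.5 else -1)
            stage = _choice(rng, config.stage_probs)
            anatomy = (
                _choice(rng, {"carapace": 0.6, "chelae": 0.3, "other": 0.1})
                if order == "Decapoda"
                else _choice(rng, {"base_plate": 0.5, "parietal_plate": 0.4, "other": 0.1})
            )
            species = _SPECIES[order][int(rng.integers(len(_SPECIES[order])))]
            aid = f"art_{b}_{j:03d}"
            pco2 = float(rng.uniform(*_BIN_RANGES[b]))
            use_chem = bool(rng.random() < config.chemistry_fraction)
            unit = _choice(rng, config.unit_probs)
            theta_ca = float(rng.normal(config.mu["calcium"][b], math.sqrt(config.tau2)))
            theta_mg = float(
                config.mu["magnesium"][b]
                + config.beta[b] * (theta_ca - config.mu["calcium"][b])
                + rng.normal(0.0, math.sqrt(config.tau2_mg_resid))
            )
            paired = j < k_pair
            for param, theta, wanted in (
                ("calcium", theta_ca, j < k_ca),
                ("magnesium", theta_mg, j < k_mg),
            ):
                if not wanted:
                    continue
                rid = next_id("syn")
                rec = _make_record(
                    rng, config, rid, aid, species, order, stage, zone, lat,
                    anatomy, param, unit, theta, pco2, use_chem,
                )
                records.append(rec)
                truth["records"][rid] = {
                    "theta": theta, "pco2": pco2, "bin": b, "parameter": param,
                    "paired": paired,
                }

    # --- biomechanics and thickness ---------------------------------------
    for param, unit in (("hardness", "vickers"), ("thickness", "um")):
        for b in BINS:
            for j in range(config.k_bin.get(param, {}).get(b, 0)):
                order = _choice(rng, config.order_probs)
                zone = _choice(rng, config.zone_probs)
                lat = float(rng.uniform(*_ZONE_LAT[zone])) * (1 if rng.random() < 0.5 else -1)
                stage = _choice(rng, config.stage_probs)
                anatomy = "carapace" if order == "Decapoda" else "parietal_plate"
                species = _SPECIES[order][int(rng.integers(len(_SPECIES[order])))]
                pco2 = float(rng.uniform(*_BIN_RANGES[b]))
                theta = float(rng.normal(config.mu[param][b], math.sqrt(config.tau2)))
                rid = next_id("syn")
                rec = _make_record(
                    rng, config, rid, f"art_{param}_{b}_{j:03d}", species, order,
                    stage, zone, lat, anatomy, param, unit, theta, pco2, False,
                )
                records.append(rec)
                truth["records"][rid] = {
                    "theta": theta, "pco2": pco2, "bin": b, "parameter": param,
                    "paired": False,
                }
    return records, truth


def generate_dataset(config: SyntheticConfig) -> list[StudyRecord]:
    """Generate a synthetic extraction dataset (records only)."""
    return generate_with_truth(config)[0]


def simulate_effects(
    mu: float,
    tau2: float,
    k: int,
    v_range: tuple = (0.002, 0.02),
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Draw (L_i, v_i) pairs directly from the random-effects model.

    A light-weight simulator for estimator calibration (coverage, recovery)
    that skips the extraction layer: v_i ~ Uniform(v_range),
    L_i ~ Normal(Normal(mu, tau2), v_i).
    """
    rng = rng or np.random.default_rng()
    v = rng.uniform(v_range[0], v_range[1], size=k)
    theta = rng.normal(mu, math.sqrt(tau2), size=k)
    L = rng.normal(theta, np.sqrt(v))
    return list(zip(L.tolist(), v.tolist()))
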