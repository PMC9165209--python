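"""End-to-end orchestration: extraction table -> report bundle.

Stages, in order: read and validate the extraction table; solve treatment
pCO2 from carbonate chemistry where it was not reported directly;
standardize ion units; compute log response ratios and their variances;
random-effects syntheses per pCO2 bin (combined ions, Ca-only, Mg-only,
biomechanics, thickness); subgroup grids by taxonomy, biogeography,
life stage and anatomy; leave-out sensitivity re-fits; and the per-bin
weighted Mg-on-Ca regressions. Outputs are plot-ready CSV tables plus a
machine-readable JSON manifest (input hash, configuration, package
version) from which every number is reproducible by calling the module
operations directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .carbonate import solve_record_pco2
from .effect_sizes import (
    EffectSize, OUT_OF_RANGE, PCO2_BINS, compute_effect_sizes, effects_frame,
)
from .extraction_io import StudyRecord, read_extraction_table, standardize_units
from .meta_model import (
    MODERATOR_FIELDS, MetaResult, leave_out_sensitivity, subgroup_analysis,
    summarize_effects,
)
from .ca_mg_regression import pair_effects, subset_regression, weighted_regression

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "derive_missing_pco2",
           "load_run_config", "bin_summary_table", "subgroup_grid",
           "regression_table"]

BIN_ORDER = list(PCO2_BINS)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str
    output_dir: str
    unit_target: str = "percent_dry_mass"
    weight_scheme: str = "mg_variance_plus_tau2"
    variance_floor: float = 1e-8
    alpha: float = 0.05
    exclude_articles_sensitivity: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def load_run_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file.

    Keys mirror the dataclass fields; unknown keys are rejected so typos
    fail loudly.
    """
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "exclude_articles_sensitivity" in raw:
        raw["exclude_articles_sensitivity"] = tuple(raw["exclude_articles_sensitivity"])
    return RunConfig(**raw)


def derive_missing_pco2(records: Sequence[StudyRecord]) -> tuple[list[StudyRecord], pd.DataFrame]:
    """Fill pco2_treatment_uatm from chemistry where missing.

    Returns updated records and a provenance table (given vs derived).
    """
    out, prov = [], []
    for rec in records:
        if rec.pco2_treatment_uatm is not None:
            out.append(rec)
            prov.append({"record_id": rec.record_id, "pco2_uatm": rec.pco2_treatment_uatm,
                         "provenance": "given"})
        else:
            state = solve_record_pco2(rec.chemistry)
            out.append(rec.model_copy(update={"pco2_treatment_uatm": state.pCO2}))
            prov.append({"record_id": rec.record_id, "pco2_uatm": state.pCO2,
                         "provenance": "derived"})
    return out, pd.DataFrame(prov)


def _result_row(r: MetaResult) -> dict:
    return {
        "label": r.label, "k": r.k, "mu_hat": r.mu_hat, "se": r.se_mu,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "z": r.z, "p": r.p,
        "tau2": r.tau2, "Q": r.Q, "q_df": r.q_df, "q_p": r.q_p,
        "significant": r.significant, "flags": ";".join(r.flags),
    }


def bin_summary_table(effects: Sequence[EffectSize], parameters: Sequence[str],
                      label: str) -> pd.DataFrame:
    """One random-effects summary per pCO2 bin for the given parameters."""
    rows = []
    for b in BIN_ORDER:
        sub = [e for e in effects if e.pco2_bin == b and e.parameter in parameters]
        if not sub:
            rows.append({"label": f"{label}|{b}", "k": 0, "mu_hat": float("nan"),
                         "significant": False, "flags": "no_data"})
            continue
        rows.append(_result_row(summarize_effects(sub, label=f"{label}|{b}")))
    df = pd.DataFrame(rows)
    df.insert(0, "pco2_bin", BIN_ORDER)
    return df


def subgroup_grid(effects: Sequence[EffectSize], parameter: str) -> pd.DataFrame:
    """Moderator-level x pCO2-bin grid of summary effects for one element.

    Mirrors the layout of a subgroup table: rows are moderator levels
    (grouped by moderator), columns are bins, cells hold mu_hat, k, and a
    significance star; empty cells are ND.
    """
    pool = [e for e in effects if e.parameter == parameter]
    rows = []
    overall = {"moderator": "overall", "level": "overall"}
    for b in BIN_ORDER:
        sub = [e for e in pool if e.pco2_bin == b]
        overall[b] = _cell(summarize_effects(sub, label=b)) if sub else "ND"
    rows.append(overall)
    for moderator, attr in MODERATOR_FIELDS.items():
        levels = sorted({getattr(e, attr) for e in pool})
        for lv in levels:
            row = {"moderator": moderator, "level": lv}
            for b in BIN_ORDER:
                sub = [e for e in pool if e.pco2_bin == b and getattr(e, attr) == lv]
                row[b] = _cell(summarize_effects(sub)) if sub else "ND"
            rows.append(row)
    return pd.DataFrame(rows)


def _cell(r: MetaResult) -> str:
    star = "*" if r.significant else ""
    return f"{r.mu_hat:.4f}{star} (n={r.k})"


def regression_table(effects: Sequence[EffectSize], weight_scheme: str) -> pd.DataFrame:
    """Per-bin weighted Mg-on-Ca regression results."""
    pairs = pair_effects([e for e in effects if e.pco2_bin != OUT_OF_RANGE])
    rows = []
    for b in BIN_ORDER:
        n_in_bin = sum(p.pco2_bin == b for p in pairs)
        if n_in_bin < 3:
            rows.append({"pco2_bin": b, "n": n_in_bin, "slope": float("nan"),
                         "note": "fewer than 3 pairs"})
            continue
        r = weighted_regression(pairs, bin_label=b, weight_scheme=weight_scheme)
        rows.append({
            "pco2_bin": b, "n": r.n, "slope": r.slope, "intercept": r.intercept,
            "se_slope": r.se_slope, "t": r.t, "p_slope": r.p_slope,
            "adj_R2": r.adj_R2, "weight_scheme": r.weight_scheme, "note": "",
        })
    return pd.DataFrame(rows)


def forest_data(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Per-effect points with normal-approximation CIs for forest plots."""
    df = effects_frame(effects)
    half = 1.959963984540054 * df["v"].pow(0.5)
    df["ci_low"] = df["L"] - half
    df["ci_high"] = df["L"] + half
    return df


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_analysis(config: RunConfig, records: Optional[Sequence[StudyRecord]] = None) -> dict:
    """Run every stage and write the report bundle.

    Returns a dict of output names to file paths. ``records`` may be passed
    directly (e.g. fresh from the generator) to skip the read stage; the
    manifest then hashes the in-memory table instead of a file.

    Any stage failure removes partial outputs before re-raising, so a
    bundle directory is either complete or absent.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        written[name] = path

    try:
        if records is None:
            records = read_extraction_table(config.input_path)
        records, provenance = derive_missing_pco2(records)
        records = [
            standardize_units(r, config.unit_target)
            if r.parameter in ("calcium", "magnesium") else r
            for r in records
        ]
        effects = compute_effect_sizes(records, variance_floor=config.variance_floor)
        binned = [e for e in effects if e.pco2_bin != OUT_OF_RANGE]

        emit("pco2_provenance", provenance)
        emit("effect_sizes", effects_frame(effects))
        emit("forest_data", forest_data(binned))
        emit("bins_ions_combined", bin_summary_table(binned, ("calcium", "magnesium"), "ions"))
        emit("bins_calcium", bin_summary_table(binned, ("calcium",), "calcium"))
        emit("bins_magnesium", bin_summary_table(binned, ("magnesium",), "magnesium"))
        emit("bins_biomechanics", bin_summary_table(binned, ("hardness",), "hardness"))
        emit("bins_thickness", bin_summary_table(binned, ("thickness",), "thickness"))
        emit("subgroups_calcium", subgroup_grid(binned, "calcium"))
        emit("subgroups_magnesium", subgroup_grid(binned, "magnesium"))
        emit("regression_ca_mg", regression_table(binned, config.weight_scheme))

        # leave-out sensitivity per element, within each bin that has data
        sens_rows = []
        if config.exclude_articles_sensitivity:
            for param in ("calcium", "magnesium"):
                for b in BIN_ORDER:
                    sub = [e for e in binned if e.parameter == param and e.pco2_bin == b]
                    kept = [e for e in sub
                            if e.article_id not in config.exclude_articles_sensitivity]
                    if not kept or len(kept) == len(sub):
                        continue
                    r = leave_out_sensitivity(
                        sub, exclude_articles=config.exclude_articles_sensitivity,
                        label=f"{param}|{b}|excl",
                    )
                    sens_rows.append({"parameter": param, "pco2_bin": b, **_result_row(r)})
        emit("sensitivity", pd.DataFrame(sens_rows))

        if isinstance(config.input_path, (str, Path)) and Path(config.input_path).exists():
            input_hash = _sha256(config.input_path)
        else:
            blob = "\n".join(r.model_dump_json() for r in records).encode()
            input_hash = hashlib.sha256(blob).hexdigest()
        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "input_sha256": input_hash,
            "n_records": len(records),
            "n_effects": len(effects),
            "outputs": sorted(written),
        }
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = mpath
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    return {k: str(v) for k, v in written.items()}
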