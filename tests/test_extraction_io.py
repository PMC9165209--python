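"""Extraction-table reading, variance harmonization, units and zones."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oa_crust_meta import (
    StudyRecord,
    assign_biogeo_zone,
    convert_variance_to_sd,
    read_extraction_table,
    standardize_units,
    write_extraction_table,
)
from oa_crust_meta.effect_sizes import log_response_ratio, pooled_variance
from oa_crust_meta.extraction_io import ExtractionError

CSV_HEADER = (
    "record_id,article_id,species,order,life_stage,latitude_deg,biogeo_zone,"
    "anatomy,parameter,unit,mean_control,mean_treatment,var_stat_control,"
    "var_stat_treatment,var_type,n_control,n_treatment,pco2_treatment_uatm,"
    "pH_total,TA,DIC,temperature,salinity,final_timepoint"
)


def _row(rid, mean_control="20.0"):
    return (
        f"{rid},a1,Carcinus maenas,Decapoda,adult,54.0,,carapace,calcium,"
        f"percent_dry_mass,{mean_control},18.0,2.0,2.2,SD,6,6,1600,,,,,,true"
    )


def test_well_formed_file_round_trips_in_order(tmp_path):
    path = tmp_path / "fixture.csv"
    path.write_text("\n".join([CSV_HEADER, _row("r1"), _row("r2"), _row("r3")]) + "\n")
    records = read_extraction_table(path)
    assert [r.record_id for r in records] == ["r1", "r2", "r3"]
    out = tmp_path / "rt.csv"
    write_extraction_table(records, out)
    assert read_extraction_table(out) == records


def test_zero_mean_row_rejected_with_row_diagnostic(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("\n".join([CSV_HEADER, _row("r1"), _row("r2", "0.0")]) + "\n")
    with pytest.raises(ExtractionError, match="row 3.*r2"):
        read_extraction_table(path)
    kept = read_extraction_table(path, strict=False)
    assert [r.record_id for r in kept] == ["r1"]


def test_missing_mandatory_column_is_schema_error(tmp_path):
    path = tmp_path / "noschema.csv"
    path.write_text("record_id,article_id\nr1,a1\n")
    with pytest.raises(ExtractionError, match="mean_control"):
        read_extraction_table(path)


def test_non_final_timepoint_rows_are_dropped(tmp_path):
    path = tmp_path / "tp.csv"
    early = _row("r1").replace(",true", ",false")
    path.write_text("\n".join([CSV_HEADER, early, _row("r2")]) + "\n")
    assert [r.record_id for r in read_extraction_table(path)] == ["r2"]


def test_record_requires_a_pco2_route(record_kwargs):
    record_kwargs.pop("pco2_treatment_uatm")
    with pytest.raises(ValueError, match="pco2"):
        StudyRecord(**record_kwargs)


@pytest.mark.parametrize(
    "value,var_type,n,expected",
    [
        (2.0, "SD", 5, 2.0),
        (2.0, "SD", 2, 2.0),
        (1.5, "SE", 9, 4.5),
        (2.698, "IQR", 5, 2.0),  # normal IQR / 1.349
        (1.96, "CI95", 4, 2.0),  # half-width * sqrt(n) / 1.96
    ],
)
def test_variance_statistic_to_sd(value, var_type, n, expected):
    assert convert_variance_to_sd(value, var_type, n) == pytest.approx(expected, rel=1e-3)


def test_ci95_from_bounds_matches_half_width():
    sd = convert_variance_to_sd(None, "CI95", 4, ci_low=-1.96, ci_high=1.96)
    assert sd == pytest.approx(2.0)
    with pytest.raises(ValueError):
        convert_variance_to_sd(None, "CI95", 4, ci_low=1.0, ci_high=0.0)


def test_se_conversion_needs_n_of_two():
    with pytest.raises(ValueError):
        convert_variance_to_sd(1.0, "SE", 1)
    with pytest.raises(ValueError):
        convert_variance_to_sd(-1.0, "SD")


def test_iqr_factor_matches_normal_distribution():
    """IQR/1.349 recovers the SD of a normal sample (simulation oracle)."""
    rng = np.random.default_rng(42)
    draws = rng.normal(10.0, 2.0, size=1_000_000)
    q75, q25 = np.percentile(draws, [75, 25])
    assert convert_variance_to_sd(q75 - q25, "IQR") == pytest.approx(2.0, rel=0.01)


@given(
    value=st.floats(0.01, 1e3),
    c=st.floats(0.01, 1e3),
    var_type=st.sampled_from(["SD", "SE", "CI95", "IQR"]),
)
@settings(max_examples=100, deadline=None)
def test_conversion_homogeneous_of_degree_one(value, c, var_type):
    a = convert_variance_to_sd(value, var_type, 9)
    b = convert_variance_to_sd(c * value, var_type, 9)
    assert b == pytest.approx(c * a, rel=1e-9)


@pytest.mark.parametrize(
    "lat,zone",
    [(-10, "tropical"), (0, "tropical"), (34.999, "tropical"),
     (35, "temperate"), (42, "temperate"), (-42, "temperate"),
     (50, "polar"), (90, "polar")],
)
def test_biogeographic_zone_bins(lat, zone):
    assert assign_biogeo_zone(lat) == zone


def test_zone_rejects_impossible_latitude():
    with pytest.raises(ValueError):
        assign_biogeo_zone(91.0)


@given(lat=st.floats(-90, 90))
@settings(max_examples=200, deadline=None)
def test_zone_symmetric_across_hemispheres(lat):
    assert assign_biogeo_zone(lat) == assign_biogeo_zone(-lat)


def test_mass_fraction_unit_standardization(record_kwargs):
    rec = StudyRecord(**{**record_kwargs, "unit": "mg_per_100mg", "mean_control": 20.0})
    out = standardize_units(rec, "percent_dry_mass")
    assert out.unit == "percent_dry_mass"
    assert out.mean_control == pytest.approx(20.0)


def test_mass_to_molar_uses_atomic_mass(record_kwargs):
    rec = StudyRecord(
        **{**record_kwargs, "unit": "ug_per_mg",
           "mean_control": 40.078, "mean_treatment": 40.078}
    )
    out = standardize_units(rec, "umol_per_mg")
    assert out.unit == "umol_per_mg"
    assert out.mean_control == pytest.approx(1.0, rel=1e-12)


def test_specialized_units_pass_through(record_kwargs):
    rec = StudyRecord(**{**record_kwargs, "unit": "instrument_counts"})
    assert standardize_units(rec, "percent_dry_mass") == rec


@given(
    scale_choice=st.sampled_from(["mg_per_g", "ug_per_mg", "umol_per_g", "percent"]),
    target=st.sampled_from(["percent_dry_mass", "umol_per_mg"]),
    xc=st.floats(1.0, 50.0),
    xe=st.floats(1.0, 50.0),
    sd=st.floats(0.01, 5.0),
)
@settings(max_examples=100, deadline=None)
def test_unit_conversion_leaves_lnrr_and_variance_invariant(
    scale_choice, target, xc, xe, sd
):
    rec = StudyRecord(
        record_id="r1", article_id="a1", species="Carcinus maenas",
        order="Decapoda", life_stage="adult", latitude_deg=54.0,
        anatomy="carapace", parameter="calcium", unit=scale_choice,
        mean_control=xc, mean_treatment=xe, var_stat_control=sd,
        var_stat_treatment=sd, var_type="SD", n_control=6, n_treatment=6,
        pco2_treatment_uatm=1600.0,
    )
    out = standardize_units(rec, target)
    before = log_response_ratio(rec.mean_treatment, rec.mean_control)
    after = log_response_ratio(out.mean_treatment, out.mean_control)
    assert after == pytest.approx(before, abs=1e-12)
    v_before = pooled_variance(rec.sd_treatment(), rec.n_treatment, rec.mean_treatment,
                               rec.sd_control(), rec.n_control, rec.mean_control)
    v_after = pooled_variance(out.sd_treatment(), out.n_treatment, out.mean_treatment,
                              out.sd_control(), out.n_control, out.mean_control)
    assert v_after == pytest.approx(v_before, rel=1e-9)


def test_zone_derived_from_latitude_when_absent(record_kwargs):
    rec = StudyRecord(**record_kwargs)  # latitude 54
    assert rec.biogeo_zone == "polar"
    assert math.isclose(rec.latitude_deg, 54.0)
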