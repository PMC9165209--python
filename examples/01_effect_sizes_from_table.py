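"""Compute log response ratios from a tiny hand-written extraction table.

Three ambient-vs-acidified comparisons of exoskeletal calcium content,
with the variance statistic reported in three different formats (SD, SE,
95% CI half-width) to show the harmonization step.
"""

from oa_crust_meta import StudyRecord, compute_effect_sizes

records = [
    StudyRecord(
        record_id=f"r{i}", article_id=a, species=sp, order="Decapoda",
        life_stage="adult", latitude_deg=lat, anatomy="carapace",
        parameter="calcium", unit="percent_dry_mass",
        mean_control=xc, mean_treatment=xe,
        var_stat_control=vc, var_stat_treatment=vt, var_type=vtype,
        n_control=n, n_treatment=n, pco2_treatment_uatm=pco2,
    )
    for i, (a, sp, lat, xc, xe, vc, vt, vtype, n, pco2) in enumerate([
        ("art1", "Carcinus maenas", 54.0, 22.0, 19.5, 2.1, 2.4, "SD", 6, 1650.0),
        ("art2", "Chionoecetes bairdi", 57.8, 24.5, 24.1, 0.9, 1.1, "SE", 8, 780.0),
        ("art3", "Callinectes sapidus", 38.9, 20.3, 21.0, 1.8, 1.7, "CI95", 5, 1120.0),
    ])
]

for rec, eff in zip(records, compute_effect_sizes(records)):
    print(f"{rec.species:24s} L = {eff.L:+.4f}  v = {eff.v:.5f}  bin = {eff.pco2_bin}")

# L < 0 means less calcium under acidification than ambient (e.g. L = -0.12
# is a ~11% reduction); v is the within-study sampling variance of L, the
# inverse-weight basis for the meta-analysis. Each record lands in the pCO2
# bin of its acidified treatment.
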