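# oa-crust-meta

A meta-analysis pipeline for the effects of ocean acidification on
crustacean exoskeletons. It synthesizes ambient-vs-acidified comparisons
of exoskeletal **ion content** (calcium, magnesium), **biomechanical
resistance** (microhardness, shell strength) and **cuticle thickness**
extracted from published experiments on decapods and sessile barnacles,
and asks whether high seawater pCO2 changes these properties in a
predictable way.

## The model

Each extracted comparison contributes a log response ratio

```
L = ln(X_E / X_C)
```

with acidified-treatment mean `X_E` and ambient-control mean `X_C`, and
within-study sampling variance

```
v = S_E² / (n_E X_E²) + S_C² / (n_C X_C²)
```

Effects are grouped by the acidified treatment's pCO2 (bins 500–999,
1000–1499, 1500–1999, 2000+ µatm; studies reporting pH + TA/DIC instead
of pCO2 go through a seawater carbonate-system solver first). Each bin is
summarized by a DerSimonian–Laird random-effects model: between-study
variance `τ²` from the moment estimator, summary effect
`μ̂ = Σ w*ᵢ Lᵢ / Σ w*ᵢ` with `w*ᵢ = 1/(vᵢ + τ²)`, Wald 95% CI, and the
Cochran `Q` heterogeneity statistic. Subgroup re-fits split each bin by
taxonomic order, biogeographic zone, life stage, or anatomical region;
leave-out sensitivity re-fits drop named articles. Finally, Ca and Mg
effects from the same experiment are paired and `L_Mg` is regressed on
`L_Ca` per bin by weighted least squares, probing whether the two ions of
Mg-calcite co-vary or trade off under acidification.

A synthetic study generator emulates the whole extraction schema —
configurable true effects per bin, `τ²`, paired Ca–Mg structure with a
known slope, mixed variance-reporting formats (SD/SE/CI/IQR), mixed
units, and chemistry-only records — so every stage is testable and
parameter recovery can be scored without downloading anything.

## Worked example

```python
from oa_crust_meta import (SyntheticConfig, generate_dataset,
                           compute_effect_sizes, summarize_effects)
from oa_crust_meta.pipeline import derive_missing_pco2

records, _ = derive_missing_pco2(generate_dataset(SyntheticConfig(rng_seed=1)))
effects = compute_effect_sizes(records)
ca = [e for e in effects if e.parameter == "calcium" and e.pco2_bin == "1500-1999"]
print(summarize_effects(ca, label="Ca|1500-1999"))
```

prints (abridged)

```
mu_hat=-0.1003  ci=(-0.1684, -0.0322)  k=15  tau2=0.0098  Q=40.02
```

i.e. across the 15 simulated studies in the 1500–1999 µatm bin, calcium
content is about 10% lower under acidification (the CI excludes zero, so
the effect is significant at α = .05), with substantial between-study
heterogeneity — matching the generator's true effect of −0.08 for that
bin up to sampling error. The scripts in `examples/` walk through each
capability (effect sizes, the carbonate solver, bin/subgroup/sensitivity
meta-analysis, the Ca–Mg regression, the full report bundle), and the
`oa-crust-meta` command exposes the same stages from a shell
(`simulate`, `derive-pco2`, `effect-sizes`, `meta`, `camg-regression`,
`run`).

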