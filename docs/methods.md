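# Methods

## Statistical model

The unit of analysis is one ambient-vs-acidified comparison of a single
quantity (Ca content, Mg content, hardness, or cuticle thickness) in one
species and anatomical structure. Its effect size is the log response
ratio `L = ln(X_E/X_C)`, which is unitless and invariant to any common
rescaling of the two group means — the property that makes comparisons
across studies with heterogeneous measurement units meaningful. The
delta-method sampling variance `v = S_E²/(n_E X_E²) + S_C²/(n_C X_C²)`
treats the group means as approximately normal; it degrades for very
small n or CV approaching 1, which is part of what the random-effects
layer absorbs.

The synthesis model is two-level: `L_i ~ Normal(θ_i, v_i)`,
`θ_i ~ Normal(μ, τ²)`, with `v_i` treated as known. `τ²` uses the
DerSimonian–Laird moment estimator (truncated at zero), matching the
standard `metafor` DL fit; the unit test suite pins exact agreement with
metafor 4.8-0 output. Inference on `μ̂` uses Wald z intervals, not
Knapp–Hartung t intervals, because that is the DL default of the
reference implementation the printed results come from; the known
consequence — mild CI undercoverage at moderate k — is quantified by the
calibration test (coverage bounded in [90%, 97%] at k = 20 rather than a
nominal 95%). Significance is declared exactly when the 95% CI excludes
zero (α = .05), which for Wald intervals coincides with p < .05.
Heterogeneity is reported as the fixed-effect-weighted Q with k−1 df;
for an intercept-only model this is the residual heterogeneity statistic.
Single-effect groups are reported with their own sampling variance,
flagged, and never marked significant.

## Harmonization ledgers

Variance statistics are converted to SDs via a machine-readable ledger:
SE·√n, CI95 half-width·√n/1.96, IQR/1.349 (the normal-distribution
identity 2·Φ⁻¹(0.75) ≈ 1.349), identity for SD. The constants sit in
`DEFAULT_CONVERSION_LEDGER` so alternative conventions can be swapped in
configuration rather than code.

Ion-content units convert through a second ledger between the
mass-fraction family (canonical: percent of tissue dry mass) and the
molar family (canonical: µmol/mg), linked by atomic masses (Ca 40.078,
Mg 24.305 g/mol). Units outside both families (instrument-specific
scales) pass through unchanged and are flagged native — legitimate
because the log response ratio cancels any within-study scale. A
property test asserts lnRR and v are invariant to unit conversion at
1e-12/1e-9.

Biogeographic zones are assigned from collection latitude with half-open
intervals |lat| ∈ [0,35) tropical, [35,50) temperate, [50,90] polar,
symmetric across hemispheres. The pCO2 bins are likewise half-open
([500,1000), [1000,1500), [1500,2000), [2000,∞) µatm): the printed
integer labels are shorthand for a continuous variable, and half-open
edges make the assignment deterministic. Treatments under 500 µatm are
marked out-of-range and excluded from binned analyses.

## Carbonate-system solver

For studies reporting pH with TA or DIC instead of pCO2, the solver uses
the common oceanographic surface-water default constant set: K1/K2 from
Lueker et al. (2000) on the total pH scale, K0 from Weiss (1974), K_B
from Dickson (1990), K_W from Millero (1995), total borate from Uppström
(1974); zero nutrient alkalinity, surface pressure, pCO2 rather than
fugacity (the correction is <1% at surface conditions). Each
parameterization is pinned to its published 4-significant-figure check
value at 25 °C, S = 35, and the closed-form speciation path is
cross-checked against an independently coded root-finding solve of the
full alkalinity balance at 10 reference points (agreement ~1e-9
relative, asserted at the 1% level). Reported pH is taken as total-scale;
NBS-scale values without conversion data would be treated as total and
flagged, since no conversion information exists in that situation.
Infeasible inputs (borate + water alkalinity exceeding TA) raise rather
than returning a negative carbonate alkalinity.

## Ca–Mg regression weighting

"Weighted by both the sampling variance and τ²" admits several
constructions. The default is response-variance weighting,
`w_i = 1/(v_Mg,i + τ̂²_Mg)` with `τ̂²_Mg` re-estimated per bin by DL on
the magnesium effects in that bin — the standard WLS reading in which
the regression's error variance is the Mg effect's marginal variance.
Two alternatives are exposed (`both_variances_plus_tau2`, which adds the
Ca sampling variance, and `unweighted`) so results can be bracketed
across readings. Adjusted R² follows the weighted least-squares summary
convention (weighted residual and total sums of squares about the
weighted mean), which with unit weights reduces exactly to ordinary
least squares. Pairing is exact on (article, species, anatomy,
treatment pCO2); measurement error in the Ca predictor is ignored (no
errors-in-variables fit), a known limitation shared with plain `lm`.

## Synthetic data generator

The generator draws, per study in bin b: a true effect
`θ ~ Normal(μ_b, τ²)`; a control mean from a log-normal whose location
matches realistic tissue values (Ca ≈ 20% dry mass, Mg ≈ 2%, hardness
≈ 200 on a microindentation scale, thickness ≈ 100 µm); a coefficient of
variation uniform in (0.05, 0.30) and group sizes uniform in 3–10,
typical of the underlying literature. Reported group means are sample
means of n positive-truncated normal draws — not set exactly — so the
small-sample bias of the log ratio is present, as in real extractions.
Paired experiments generate the Mg effect as
`θ_Mg = μ_Mg,b + β_b(θ_Ca − μ_Ca,b) + Normal(0, τ²_resid)`, giving the
within-bin Mg-on-Ca regression a known true slope. Variance statistics
are re-encoded per a mixture of SD/SE/CI95/IQR with the exact inverse of
the conversion ledger; a configurable fraction of records reports
pH + TA chemistry (pH rounded to 4 decimals, as articles print it)
instead of pCO2, exercising the solver path. Default study counts per
bin and parameter (51 Ca, 45 Mg, 19 hardness, 18 thickness) and the
qualitative sign pattern of the default true effects mirror the
synthesis conditions the pipeline targets; τ² defaults to 0.01, a
moderate heterogeneity for ecological response ratios.

What the generator does *not* emulate: non-normal within-group
distributions, correlated effects from multiple structures of the same
animals, selective reporting or publication bias, digitization error
from figure extraction, and pH-scale ambiguity. Passing recovery and
coverage tests therefore shows the estimators are correct under the
model's own assumptions, not that real extractions satisfy them.

## Numerical choices

Degenerate zero variances (both group SDs reported as 0) are floored at
ε = 1e-8 before inverse-variance weighting, so reporting artifacts
cannot acquire infinite weight. τ² truncates at 0. Root-finding
(pH from TA+DIC, pH from TA+pCO2) uses Brent's method on [4, 10] pH with
xtol 1e-10. Report bundles are written with a fixed float format and no
timestamps, so a rerun with the same configuration and seed is
bit-identical; a failed stage removes partial outputs. All randomness
flows from a single integer seed through `numpy.random.default_rng`.

Problem sizes used by the calibration checks: parameter recovery at
k = 200 studies through the full generator-to-estimate path (absolute
error bound 0.02 ≈ 2 standard errors of μ̂ at that size); CI coverage
over 1000 direct-simulation meta-analyses at k = 20; carbonate oracle
agreement at 10 reference points; 200-replicate slope recovery for the
weighted regression.

## Known limitations

- DL is the only τ² estimator (no REML/Paule–Mandel), and no
  publication-bias diagnostics are included — both deliberate scope
  choices to mirror the target analysis.
- The Ca–Mg regression treats `L_Ca` as error-free.
- Effects from the same article share no explicit correlation structure;
  articles contributing many comparisons are handled only through
  leave-out sensitivity, not a multilevel model.
- The carbonate solver's constant choices may differ in the last digits
  from any particular `seacarb` configuration; derived pCO2 is accurate
  to well under the width of a 500-µatm bin.
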