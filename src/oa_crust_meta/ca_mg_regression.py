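"""Weighted regression of magnesium on calcium effect sizes.

Crustacean cuticle carbonate is magnesium-substituted calcite, so calcium
and magnesium responses to acidification within the same experiment are
expected to co-vary. This module pairs Ca and Mg log response ratios that
come from the same experiment — same article, species, anatomical
structure, and treatment pCO2 — and fits, per pCO2 bin, a weighted linear
model

    L_Mg,i = a + b * L_Ca,i + e_i,    weight w_i

The default weight scheme is inverse response variance including the
between-study component, w_i = 1/(v_Mg,i + tau2_Mg), with tau2_Mg
re-estimated per bin by DerSimonian-Laird on the magnesium effects.
Because "weighted by both the sampling variance and tau^2" admits more
than one construction, alternatives (adding the Ca sampling variance, or
no weights at all) are exposed behind ``weight_scheme``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .effect_sizes import EffectSize
from .meta_model import dl_tau2

logger = logging.getLogger(__name__)

__all__ = [
    "PairedEffect",
    "RegressionResult",
    "WEIGHT_SCHEMES",
    "pair_effects",
    "weighted_regression",
    "subset_regression",
]

WEIGHT_SCHEMES = ("mg_variance_plus_tau2", "both_variances_plus_tau2", "unweighted")


@dataclass(frozen=True)
class PairedEffect:
    """Ca and Mg effect sizes from one experiment."""

    experiment_id: str
    article_id: str
    L_Ca: float
    v_Ca: float
    L_Mg: float
    v_Mg: float
    pco2_bin: str


@dataclass(frozen=True)
class RegressionResult:
    """Weighted least-squares fit of L_Mg on L_Ca."""

    label: str
    slope: float
    intercept: float
    se_slope: float
    t: float
    p_slope: float
    adj_R2: float
    n: int
    weight_scheme: str


def _pair_key(e: EffectSize) -> tuple:
    return (e.article_id, e.species, e.anatomy, e.pco2_treatment_uatm)


def pair_effects(effects: Sequence[EffectSize]) -> list[PairedEffect]:
    """Match calcium and magnesium effects from the same experiment.

    The pairing key is (article, species, anatomy, treatment pCO2). Effects
    of one element lacking a partner are logged and dropped; two effects of
    the same element under one key is an ambiguity error.
    """
    by_element: dict[str, dict[tuple, EffectSize]] = {"calcium": {}, "magnesium": {}}
    for e in effects:
        if e.parameter not in by_element:
            continue
        key = _pair_key(e)
        bucket = by_element[e.parameter]
        if key in bucket:
            raise ValueError(
                f"duplicate {e.parameter} effect for experiment key {key}: "
                f"{bucket[key].record_id} vs {e.record_id}"
            )
        bucket[key] = e
    pairs: list[PairedEffect] = []
    for key, ca in by_element["calcium"].items():
        mg = by_element["magnesium"].get(key)
        if mg is None:
            logger.info("calcium effect %s unpaired; dropped", ca.record_id)
            continue
        pairs.append(
            PairedEffect(
                experiment_id="|".join(str(p) for p in key),
                article_id=ca.article_id,
                L_Ca=ca.L,
                v_Ca=ca.v,
                L_Mg=mg.L,
                v_Mg=mg.v,
                pco2_bin=ca.pco2_bin,
            )
        )
    for key, mg in by_element["magnesium"].items():
        if key not in by_element["calcium"]:
            logger.info("magnesium effect %s unpaired; dropped", mg.record_id)
    return pairs


def _weights(pairs: list[PairedEffect], scheme: str) -> np.ndarray:
    if scheme == "unweighted":
        return np.ones(len(pairs))
    v_mg = np.array([p.v_Mg for p in pairs])
    if len(pairs) >= 2:
        tau2 = dl_tau2([(p.L_Mg, p.v_Mg) for p in pairs])
    else:
        tau2 = 0.0
    if scheme == "mg_variance_plus_tau2":
        return 1.0 / (v_mg + tau2)
    if scheme == "both_variances_plus_tau2":
        v_ca = np.array([p.v_Ca for p in pairs])
        return 1.0 / (v_ca + v_mg + tau2)
    raise ValueError(f"unknown weight scheme {scheme!r}; choose from {WEIGHT_SCHEMES}")


def weighted_regression(
    pairs: Sequence[PairedEffect],
    bin_label: Optional[str] = None,
    weight_scheme: str = "mg_variance_plus_tau2",
    label: str = "",
) -> RegressionResult:
    """Weighted least squares of L_Mg on L_Ca within one pCO2 bin.

    Adjusted R^2 follows the standard weighted least-squares summary
    convention (weighted sums of squares about the weighted mean). With
    unit weights this is exactly ordinary least squares.
    """
    sel = [p for p in pairs if bin_label is None or p.pco2_bin == bin_label]
    if len(sel) < 3:
        raise ValueError(
            f"need >= 3 pairs for regression, have {len(sel)}"
            + (f" in bin {bin_label}" if bin_label else "")
        )
    x = np.array([p.L_Ca for p in sel])
    y = np.array([p.L_Mg for p in sel])
    if np.allclose(x, x[0]):
        raise ValueError("all L_Ca identical: singular design")
    w = _weights(sel, weight_scheme)
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return RegressionResult(
        label=label or (bin_label or "all"),
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        se_slope=float(model.bse[1]),
        t=float(model.tvalues[1]),
        p_slope=float(model.pvalues[1]),
        adj_R2=float(model.rsquared_adj),
        n=len(sel),
        weight_scheme=weight_scheme,
    )


def subset_regression(
    pairs: Sequence[PairedEffect],
    bin_label: Optional[str] = None,
    include_articles: Optional[Iterable[str]] = None,
    exclude_articles: Iterable[str] = (),
    weight_scheme: str = "mg_variance_plus_tau2",
    label: str = "",
) -> RegressionResult:
    """Regression on an article-filtered subset of pairs."""
    inc = set(include_articles) if include_articles is not None else None
    exc = set(exclude_articles)
    kept = [
        p for p in pairs
        if (inc is None or p.article_id in inc) and p.article_id not in exc
    ]
    return weighted_regression(
        kept, bin_label=bin_label, weight_scheme=weight_scheme,
        label=label or f"subset({bin_label or 'all'})",
    )
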