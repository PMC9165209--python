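"""Random-effects synthesis by the DerSimonian-Laird method.

The model: each study's log response ratio L_i estimates a study-specific
true effect theta_i ~ Normal(mu, tau^2), observed with known sampling
variance v_i. tau^2 (between-study variance) is estimated by the
DerSimonian-Laird moment estimator from the fixed-effect Q statistic:

    w_i = 1/v_i,  ybar = sum(w_i L_i)/sum(w_i)
    Q = sum(w_i (L_i - ybar)^2)
    C = sum(w_i) - sum(w_i^2)/sum(w_i)
    tau^2 = max(0, (Q - (k-1)) / C)

The summary effect then uses random-effects weights w_i* = 1/(v_i + tau^2),
with a Wald z interval mu_hat +/- 1.96 SE. An effect is significant at
alpha = .05 exactly when its 95% CI excludes zero. Residual heterogeneity
is reported as Q (chi-square with k-1 df under homogeneity).

Subgroup analyses simply re-fit the model on each moderator level;
leave-out sensitivity analyses re-fit after excluding named articles or
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .effect_sizes import EffectSize

__all__ = [
    "MetaResult",
    "dl_tau2",
    "random_effects_summary",
    "summarize_effects",
    "subgroup_analysis",
    "leave_out_sensitivity",
    "MODERATOR_FIELDS",
]

ALPHA = 0.05
Z_CRIT = float(stats.norm.ppf(1 - ALPHA / 2))  # 1.959964...

#: Moderator name -> EffectSize attribute holding its level.
MODERATOR_FIELDS = {
    "taxonomy": "order",
    "biogeography": "biogeo_zone",
    "life_stage": "life_stage",
    "anatomy": "anatomy",
}


@dataclass(frozen=True)
class MetaResult:
    """Summary of one random-effects fit."""

    label: str
    k: int
    mu_hat: float
    se_mu: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    Q: float
    q_df: int
    q_p: float
    flags: tuple = field(default_factory=tuple)

    @property
    def significant(self) -> bool:
        """CI-excludes-zero rule at alpha = .05 (coincides with p < .05
        for Wald z intervals); single-study results are never flagged."""
        if "single_study" in self.flags:
            return False
        return self.ci_low > 0 or self.ci_high < 0


def _as_arrays(effects) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(effects, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("effects must be a sequence of (L_i, v_i) pairs")
    return arr[:, 0], arr[:, 1]


def dl_tau2(effects: Sequence[tuple[float, float]]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance."""
    L, v = _as_arrays(effects)
    k = len(L)
    if k < 2:
        raise ValueError("DL tau^2 requires at least 2 effect sizes")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    w = 1.0 / v
    sw = w.sum()
    ybar = (w * L).sum() / sw
    Q = (w * (L - ybar) ** 2).sum()
    C = sw - (w**2).sum() / sw
    return float(max(0.0, (Q - (k - 1)) / C))


def random_effects_summary(
    effects: Sequence[tuple[float, float]], label: str = ""
) -> MetaResult:
    """DerSimonian-Laird random-effects summary of (L_i, v_i) pairs.

    A single effect is returned as-is with its own variance, flagged
    ``single_study`` (tau^2 and Q are undefined at k = 1 and reported 0).
    """
    L, v = _as_arrays(effects)
    k = len(L)
    if k == 0:
        raise ValueError("no effect sizes supplied")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    if k == 1:
        mu, se = float(L[0]), float(np.sqrt(v[0]))
        z = mu / se
        p = 2 * stats.norm.sf(abs(z))
        return MetaResult(
            label=label, k=1, mu_hat=mu, se_mu=se,
            ci_low=mu - Z_CRIT * se, ci_high=mu + Z_CRIT * se,
            z=float(z), p=float(p), tau2=0.0, Q=0.0, q_df=0, q_p=float("nan"),
            flags=("single_study",),
        )
    # fixed-effect stage: Q with inverse-variance weights
    w = 1.0 / v
    sw = w.sum()
    ybar = (w * L).sum() / sw
    Q = float((w * (L - ybar) ** 2).sum())
    C = sw - (w**2).sum() / sw
    tau2 = float(max(0.0, (Q - (k - 1)) / C))
    # random-effects stage
    wstar = 1.0 / (v + tau2)
    mu = float((wstar * L).sum() / wstar.sum())
    se = float(wstar.sum() ** -0.5)
    z = mu / se
    p = float(2 * stats.norm.sf(abs(z)))
    q_df = k - 1
    q_p = float(stats.chi2.sf(Q, q_df))
    return MetaResult(
        label=label, k=k, mu_hat=mu, se_mu=se,
        ci_low=mu - Z_CRIT * se, ci_high=mu + Z_CRIT * se,
        z=float(z), p=p, tau2=tau2, Q=Q, q_df=q_df, q_p=q_p,
    )


def summarize_effects(effects: Iterable[EffectSize], label: str = "") -> MetaResult:
    """Random-effects summary of :class:`EffectSize` objects."""
    pairs = [(e.L, e.v) for e in effects]
    return random_effects_summary(pairs, label=label)


def subgroup_analysis(
    effects: Sequence[EffectSize],
    moderator: str,
    bin_label: Optional[str] = None,
) -> list[MetaResult]:
    """Re-fit the random-effects model per level of one moderator.

    ``moderator`` is one of taxonomy, biogeography, life_stage, anatomy.
    ``bin_label`` optionally restricts to one pCO2 bin first (pass
    pre-filtered effects and ``None`` to skip). Levels appear in order of
    first occurrence; levels with no data are simply absent.
    """
    if moderator not in MODERATOR_FIELDS:
        raise ValueError(
            f"moderator must be one of {sorted(MODERATOR_FIELDS)}, got {moderator!r}"
        )
    attr = MODERATOR_FIELDS[moderator]
    pool = [e for e in effects if bin_label is None or e.pco2_bin == bin_label]
    levels: list[str] = []
    for e in pool:
        lv = getattr(e, attr)
        if lv not in levels:
            levels.append(lv)
    results = []
    for lv in levels:
        sub = [e for e in pool if getattr(e, attr) == lv]
        label = f"{moderator}={lv}" + (f"|{bin_label}" if bin_label else "")
        results.append(summarize_effects(sub, label=label))
    return results


def leave_out_sensitivity(
    effects: Sequence[EffectSize],
    exclude_articles: Iterable[str] = (),
    exclude_records: Iterable[str] = (),
    label: str = "",
) -> MetaResult:
    """Re-fit after removing named articles and/or records.

    The exclusion is recorded in the result label. Emptying the set is an
    error.
    """
    ex_a, ex_r = set(exclude_articles), set(exclude_records)
    kept = [
        e for e in effects
        if e.article_id not in ex_a and e.record_id not in ex_r
    ]
    if not kept:
        raise ValueError("exclusion removed every effect size")
    tag = ",".join(sorted(ex_a | ex_r)) or "none"
    return summarize_effects(kept, label=label or f"excluding[{tag}]")
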