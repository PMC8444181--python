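"""The replicate-level statistical scheme for MI/CC comparisons.

Workflow, applied to replicate-wise MI or capacity values:

1. `center_scale` — each group is mean-centred and scaled to unit sd, then
   groups are pooled, removing trend variation so normality can be assessed
   on the whole collection at once.
2. `ks_normality` — one-sample Kolmogorov–Smirnov test of the pooled
   standardised values against the standard normal, gating parametric tests.
3. `anova_nway` — fixed-effects main-effects ANOVA for the global factors
   (genotype × dose for MI, genotype × time for capacity).
4. `anova_1way` + `cohens_d_unbiased` — the post-hoc scheme: direct
   two-group F tests and the unbiased standardised mean difference

       d_unb = (m_A − m_B) / s_AB,   s_AB = sqrt((SS_A + SS_B)/(df_A + df_B))

5. `significance_decision` — a comparison is starred only when p ≤ 0.05
   *and* |d_unb| > 0.2; the effect is graded small/medium/large at
   0.2/0.5/0.8.

`pearson_correlation` and `compare_replicate_correlations` implement the
replicate-level comparison of expression–phosphorylation correlations
(two-sample t-test between per-replicate Pearson coefficients; the reported
β is the difference of group means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .exceptions import DegenerateDataError

EFFECT_THRESHOLDS = {"small": 0.2, "medium": 0.5, "large": 0.8}


def _as_array(values, name="values") -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.isfinite(a).all():
        raise ValueError(f"{name} contains non-finite entries")
    return a


def center_scale(values, labels, ddof: int = 1) -> np.ndarray:
    """Standardise within groups (mean 0, sd 1) and return the pooled values.

    Raises on groups with fewer than two values or zero spread, naming the
    group.
    """
    a = _as_array(values)
    labels = np.asarray(labels)
    if len(labels) != len(a):
        raise ValueError("labels must match values in length")
    out = np.empty_like(a)
    for g in pd.unique(labels):
        mask = labels == g
        grp = a[mask]
        if len(grp) < 2:
            raise DegenerateDataError(f"group {g!r} has fewer than 2 values")
        sd = grp.std(ddof=ddof)
        if sd == 0:
            raise DegenerateDataError(f"group {g!r} is constant; cannot scale")
        out[mask] = (grp - grp.mean()) / sd
    return out


def ks_normality(standardized) -> tuple[float, float]:
    """One-sample KS test of pooled standardised values against N(0, 1)."""
    z = _as_array(standardized, "standardized")
    if len(z) < 5:
        raise ValueError("need >= 5 values for the KS test")
    if np.ptp(z) == 0:
        raise DegenerateDataError("degenerate (constant) input")
    stat, p = sps.kstest(z, "norm")
    return float(stat), float(p)


def anova_nway(data: pd.DataFrame, value_col: str, factor_cols: Sequence[str]) -> pd.DataFrame:
    """Fixed-effects main-effects ANOVA; one (F, p) row per factor.

    Interactions are not fitted; with the balanced designs produced by the
    generator the sums-of-squares type is immaterial.
    """
    for f in factor_cols:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    clean = data.rename(columns={value_col: "_y"})
    formula = "_y ~ " + " + ".join(f"C(Q('{f}'))" for f in factor_cols)
    fit = smf.ols(formula, data=clean).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    rows = []
    for f in factor_cols:
        key = f"C(Q('{f}'))"
        rows.append({"factor": f, "F": float(table.loc[key, "F"]),
                     "p": float(table.loc[key, "PR(>F)"])})
    return pd.DataFrame(rows)


def anova_1way(A, B) -> tuple[float, float]:
    """Two-group one-way ANOVA F test; equals the squared pooled t test."""
    a, b = _as_array(A, "A"), _as_array(B, "B")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("both groups are a single constant; F undefined")
    if a.mean() == b.mean() and np.allclose(np.sort(a), np.sort(b)):
        return 0.0, 1.0
    F, p = sps.f_oneway(a, b)
    return float(F), float(p)


@dataclass(frozen=True)
class EffectSize:
    """Unbiased Cohen's d with its building blocks."""

    d_unb: float
    m_A: float
    m_B: float
    SS_A: float
    SS_B: float
    df_A: int
    df_B: int
    s_AB: float
    category: str


def classify_effect(d: float) -> str:
    """Grade |d|: > 0.8 large, > 0.5 medium, > 0.2 small, else negligible."""
    if not np.isfinite(d):
        raise ValueError(f"d must be finite, got {d}")
    mag = abs(d)
    if mag > EFFECT_THRESHOLDS["large"]:
        return "large"
    if mag > EFFECT_THRESHOLDS["medium"]:
        return "medium"
    if mag > EFFECT_THRESHOLDS["small"]:
        return "small"
    return "negligible"


def cohens_d_unbiased(A, B) -> EffectSize:
    """Standardised mean difference with the pooled sum-of-squares scale.

    ``d_unb = (m_A − m_B) / s_AB`` with
    ``s_AB = sqrt((SS_A + SS_B) / (df_A + df_B))`` and ``df = n − 1`` per
    group, accounting for unequal group sizes and variances.
    """
    a, b = _as_array(A, "A"), _as_array(B, "B")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    m_A, m_B = a.mean(), b.mean()
    SS_A = float(((a - m_A) ** 2).sum())
    SS_B = float(((b - m_B) ** 2).sum())
    df_A, df_B = len(a) - 1, len(b) - 1
    s_AB = float(np.sqrt((SS_A + SS_B) / (df_A + df_B)))
    if s_AB == 0:
        raise DegenerateDataError("pooled scale s_AB is zero; d undefined")
    d = float((m_A - m_B) / s_AB)
    return EffectSize(d, float(m_A), float(m_B), SS_A, SS_B, df_A, df_B, s_AB,
                      classify_effect(d))


@dataclass(frozen=True)
class Comparison:
    """One pairwise comparison with its two-stage significance decision."""

    p: float
    effect: EffectSize
    flagged: bool


def significance_decision(p: float, effect: EffectSize) -> Comparison:
    """Star a comparison only when p ≤ 0.05 *and* |d_unb| > 0.2."""
    flagged = (p <= 0.05) and (abs(effect.d_unb) > EFFECT_THRESHOLDS["small"])
    return Comparison(p=float(p), effect=effect, flagged=flagged)


def compare_groups(A, B) -> Comparison:
    """Post-hoc comparison of two groups: 1-way ANOVA + unbiased Cohen's d."""
    _, p = anova_1way(A, B)
    return significance_decision(p, cohens_d_unbiased(A, B))


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    a, b = _as_array(x, "x"), _as_array(y, "y")
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length samples with >= 3 values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("a variable is constant; correlation undefined")
    return float(sps.pearsonr(a, b).statistic)


def compare_replicate_correlations(
    r_A, r_B, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sample t-test between per-replicate correlation coefficients.

    Returns ``(beta, t, p)`` where ``beta = mean(r_A) − mean(r_B)``.  The
    pooled-variance form is the default; Welch via ``equal_var=False``.
    """
    a, b = _as_array(r_A, "r_A"), _as_array(r_B, "r_B")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each replicate list needs >= 2 correlations")
    beta = float(a.mean() - b.mean())
    if np.ptp(np.concatenate([a, b])) == 0:
        # all correlations identical: no difference, no evidence
        return beta, 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return beta, float(t), float(p)
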