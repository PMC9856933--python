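"""Clinical enrichment, expression homogeneity and survival analysis.

Categorical clinical features are tested one-level-versus-rest against the
two subtypes with a two-sided Fisher exact test (hypergeometric
enumeration); continuous features with a two-sided Wilcoxon rank-sum test
(exact for small samples, normal approximation with tie correction
otherwise). Transcriptional homogeneity compares the per-gene within-group
variance vectors by rank test, and survival uses Kaplan-Meier curves with
the two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "fisher_exact_2x2",
    "categorical_enrichment",
    "continuous_enrichment",
    "homogeneity_test",
    "km_logrank",
    "enrichment_table",
]

# Relative tolerance for declaring hypergeometric point probabilities tied
# in the two-sided Fisher sum (the convention of R's fisher.test).
_FISHER_REL_TOL = 1.0 + 1e-7


@dataclass
class EnrichmentRow:
    feature: str
    test: str  # "fisher" | "wilcoxon"
    statistic: float
    p_value: float
    direction: str  # group with the larger reference-level share / values


def fisher_support_pvalues(n: int, r1: int, c1: int, alternative: str = "two-sided"):
    """Fisher exact p for every table sharing the margins (n, r1, c1).

    Returns (support, p) where ``support`` holds the admissible values of
    the top-left cell a and ``p[i]`` is the exact p for a = support[i],
    obtained by hypergeometric enumeration over the support.
    """
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    if alternative == "two-sided":
        p = np.array([pmf[pmf <= pa * _FISHER_REL_TOL].sum() for pa in pmf])
    elif alternative == "greater":
        p = pmf[::-1].cumsum()[::-1]
    elif alternative == "less":
        p = pmf.cumsum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return support, np.minimum(p, 1.0)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher exact p for a 2x2 table by hypergeometric enumeration.

    ``table`` is [[a, b], [c, d]]; rows are the two categories, columns the
    two groups. The two-sided p sums all tables (same margins) whose point
    probability does not exceed the observed one (within a 1e-7 relative
    tolerance, the convention of R's fisher.test).
    ``alternative='greater'`` is the upper tail on ``a``.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in contingency table")
    if n == 0 or r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0  # empty margin: no information
    support, p = fisher_support_pvalues(n, r1, c1, alternative)
    return float(p[a - support[0]])


def categorical_enrichment(
    ann: pd.DataFrame,
    feature: str,
    reference_level: str,
    group_col: str = "group",
) -> EnrichmentRow:
    """Fisher enrichment of one categorical level between the two groups.

    Builds the 2x2 table (reference level vs all other levels) x (group h
    vs group o) and tests it two-sided; the direction is the group with
    the higher reference-level proportion.
    """
    sub = ann[[feature, group_col]].dropna()
    groups = sorted(sub[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups, got {groups}")
    gh, go = groups
    is_ref = sub[feature] == reference_level
    a = int(((sub[group_col] == gh) & is_ref).sum())
    b = int(((sub[group_col] == go) & is_ref).sum())
    c = int(((sub[group_col] == gh) & ~is_ref).sum())
    d = int(((sub[group_col] == go) & ~is_ref).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.warning("empty margin for feature %r; p set to 1", feature)
        p = 1.0
    else:
        p = fisher_exact_2x2([[a, b], [c, d]], alternative="two-sided")
    prop_h = a / (a + c) if a + c else 0.0
    prop_o = b / (b + d) if b + d else 0.0
    odds = (a * d) / (b * c) if b * c else np.inf
    return EnrichmentRow(
        feature=f"{feature}:{reference_level}",
        test="fisher",
        statistic=float(odds),
        p_value=p,
        direction=gh if prop_h >= prop_o else go,
    )


def continuous_enrichment(
    values: pd.Series, groups: pd.Series, feature: str = "", exact_max_n: int = 50
) -> EnrichmentRow:
    """Two-sided Wilcoxon rank-sum comparison of a continuous feature.

    Exact enumeration when both groups hold at most ``exact_max_n``
    observations and the data are tie-free; otherwise the normal
    approximation with tie correction (and continuity correction).
    """
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    levels = sorted(df.g.unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    xh = df.v[df.g == levels[0]].to_numpy(dtype=float)
    xo = df.v[df.g == levels[1]].to_numpy(dtype=float)
    if len(np.unique(df.v)) == 1:
        return EnrichmentRow(feature, "wilcoxon", np.nan, 1.0, levels[0])
    has_ties = len(np.unique(df.v)) < len(df)
    method = (
        "exact"
        if (max(len(xh), len(xo)) <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(xh, xo, alternative="two-sided", method=method)
    direction = levels[0] if np.median(xh) >= np.median(xo) else levels[1]
    return EnrichmentRow(feature, "wilcoxon", float(res.statistic), float(res.pvalue), direction)


def homogeneity_test(m: pd.DataFrame, groups: pd.Series):
    """Compare transcriptional homogeneity between the two subtypes.

    Per-gene sample variances are computed within each group and the two
    variance vectors are compared with a two-sided Wilcoxon rank-sum test.
    Returns (median variance group h, median variance group o, p).
    """
    groups = groups.reindex(m.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    vh = m.loc[:, groups == levels[0]].var(axis=1, ddof=1)
    vo = m.loc[:, groups == levels[1]].var(axis=1, ddof=1)
    if (m.loc[:, groups == levels[0]].shape[1] < 3) or (
        m.loc[:, groups == levels[1]].shape[1] < 3
    ):
        raise ValueError("each group needs at least 3 samples")
    if np.allclose(vh, vo):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(vh, vo, alternative="two-sided").pvalue)
    return float(vh.median()), float(vo.median()), p


def km_logrank(times, events, groups):
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns (curves, p) where ``curves`` maps group label to a DataFrame
    with columns time / at_risk / survival (step function starting at
    S(0)=1) and ``p`` is the 1-df log-rank chi-square p value.
    """
    df = pd.DataFrame({"t": times, "e": events, "g": groups}).dropna()
    if (df.e > 0).sum() < 1:
        raise ValueError("need at least one event")
    levels = sorted(df.g.unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    if (df.g == levels[0]).sum() == 0 or (df.g == levels[1]).sum() == 0:
        raise ValueError("a group has zero subjects")
    curves = {}
    for g in levels:
        sub = df[df.g == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub.t, event_observed=sub.e)
        ev = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=float),
                "survival": kmf.survival_function_["KM_estimate"]
                .reindex(ev.index)
                .to_numpy(dtype=float),
            }
        )
    a, b = (df[df.g == g] for g in levels)
    res = logrank_test(a.t, b.t, event_observed_A=a.e, event_observed_B=b.e)
    return curves, float(res.p_value)


def enrichment_table(
    ann: pd.DataFrame,
    categorical: dict,
    continuous: list,
    group_col: str = "group",
) -> pd.DataFrame:
    """Run the full clinical-enrichment panel and return a tidy table.

    ``categorical`` maps feature name -> reference level; ``continuous``
    lists continuous feature names.
    """
    rows = []
    for feat, ref in categorical.items():
        rows.append(categorical_enrichment(ann, feat, ref, group_col=group_col))
    for feat in continuous:
        rows.append(
            continuous_enrichment(ann[feat], ann[group_col], feature=feat)
        )
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
            }
            for r in rows
        ]
    )
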