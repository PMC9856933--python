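"""miRNA expression filtering, differential expression and mRNA integration.

Mature-miRNA raw counts are filtered for expression, normalized to
counts-per-million with TMM (trimmed mean of M-values) scale factors, and
tested for subtype differential expression on the log2(CPM + 0.5) scale
with Welch's t and Holm correction. Pre-miRNA expression is the mean of the
derived mature forms. The regulatory network keeps database-supported
miRNA-target pairs where both sides are differentially expressed
(|log2FC| > 1, adjusted p < 0.01) and the pair is significantly
anti-correlated across samples (one-sided Pearson, BH-adjusted p < 0.01).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "filter_expressed",
    "tmm_factors",
    "cpm",
    "normalize_and_de",
    "premirna_expression",
    "integrate",
    "logfc_concordance",
]


def filter_expressed(
    c: pd.DataFrame, min_total: int = 10, min_max: int = 5
) -> pd.DataFrame:
    """Keep miRNAs with summed raw count > ``min_total`` and at least
    ``min_max`` reads in one sample. Order-preserving and idempotent."""
    total = c.sum(axis=1)
    peak = c.max(axis=1)
    return c.loc[(total > min_total) & (peak >= min_max)]


def tmm_factors(
    c: pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """TMM (trimmed mean of M-values) normalization factors per sample.

    The reference sample is the library whose 75th count percentile
    (relative to library size) is closest to the mean across libraries.
    For each sample, log-ratios M and average abundances A against the
    reference are computed on features positive in both; the upper/lower
    ``m_trim`` of M and ``a_trim`` of A are discarded and the factor is the
    weighted mean M (inverse asymptotic-variance weights), exponentiated.
    Factors are rescaled to multiply to one.
    """
    x = c.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    uq = np.array([np.quantile(x[:, j][x[:, j] > 0], 0.75) / lib[j] for j in range(x.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    r, nr = x[:, ref_j], lib[ref_j]
    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_j:
            continue
        obs, n = x[:, j], lib[j]
        pos = (obs > 0) & (r > 0)
        if pos.sum() < 2:
            continue
        o, rr = obs[pos], r[pos]
        m = np.log2((o / n) / (rr / nr))
        a = 0.5 * np.log2((o / n) * (rr / nr))
        w = (n - o) / (n * o) + (nr - rr) / (nr * rr)
        if np.allclose(m, m[0]):
            factors[j] = 2 ** m[0]
            continue
        lo_m, hi_m = np.quantile(m, [m_trim, 1 - m_trim])
        lo_a, hi_a = np.quantile(a, [a_trim, 1 - a_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            keep = np.ones_like(m, dtype=bool)
        factors[j] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=c.columns)


def cpm(c: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    lib = c.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    if factors is not None:
        lib = lib * factors.reindex(c.columns)
    return c.div(lib, axis=1) * 1e6


def normalize_and_de(
    c: pd.DataFrame,
    groups: pd.Series,
    lfc_min: float = 1.0,
    p_max: float = 0.01,
    median_cpm_min: float = 1.0,
) -> pd.DataFrame:
    """TMM-CPM normalization and two-group differential expression.

    Welch's t on log2(CPM + 0.5) stands in for a count-model fit; p values
    are Holm-adjusted. The ``significant`` flag applies the three published
    cut-offs: |log2FC| > ``lfc_min``, adjusted p < ``p_max`` and a median
    normalized count above ``median_cpm_min`` in at least one group.
    """
    groups = groups.reindex(c.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    if (groups == levels[0]).sum() < 2 or (groups == levels[1]).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    norm = cpm(c, tmm_factors(c))
    logx = np.log2(norm + 0.5)
    xh = logx.loc[:, groups == levels[0]].to_numpy()
    xo = logx.loc[:, groups == levels[1]].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xh, xo, axis=1, equal_var=False)
    bad = ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    p_holm = multipletests(p, method="holm")[1]
    med_h = norm.loc[:, groups == levels[0]].median(axis=1)
    med_o = norm.loc[:, groups == levels[1]].median(axis=1)
    out = pd.DataFrame(
        {
            "log2fc": xh.mean(axis=1) - xo.mean(axis=1),
            "t_score": t,
            "p_raw": p,
            "p_holm": p_holm,
            "median_norm_h": med_h,
            "median_norm_o": med_o,
        },
        index=c.index,
    )
    out["significant"] = (
        (out.log2fc.abs() > lfc_min)
        & (out.p_holm < p_max)
        & ((out.median_norm_h > median_cpm_min) | (out.median_norm_o > median_cpm_min))
    )
    return out


def premirna_expression(mature: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    """Summarize mature-miRNA signal to precursor level by averaging.

    ``mapping`` maps mature id -> precursor id (each mature form belongs to
    at most one precursor). Unmapped mature ids are excluded with a log
    message. Input is expected on a normalized (CPM or log) scale.
    """
    mapping = mapping.dropna()
    unmapped = [i for i in mature.index if i not in mapping.index]
    if unmapped:
        logger.info("excluding %d mature miRNA(s) without precursor mapping", len(unmapped))
    mapped = mature.loc[[i for i in mature.index if i in mapping.index]]
    pre = mapped.groupby(mapping.reindex(mapped.index)).mean()
    pre.index.name = "pre_mirna_id"
    return pre


def integrate(
    mirna_expr: pd.DataFrame,
    mirna_de: pd.DataFrame,
    gene_expr: pd.DataFrame,
    gene_de: pd.DataFrame,
    db: pd.DataFrame,
    lfc_min: float = 1.0,
    de_p_max: float = 0.01,
    adj_p_max: float = 0.01,
    p_adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Anti-correlation integration of miRNA and mRNA expression.

    For every database pair (columns ``pre_mirna_id``, ``gene_id``,
    ``source``) whose miRNA and gene both pass the differential-expression
    filters (|log2FC| > ``lfc_min`` and adjusted p < ``de_p_max`` in their
    respective DE tables, column ``p_holm``), the Pearson correlation over
    shared samples is tested one-sided for anti-correlation; p values are
    adjusted across all candidate pairs and records with adjusted
    p < ``adj_p_max`` and negative correlation are retained.
    """
    if db.empty:
        return _empty_network()
    shared = [s for s in mirna_expr.columns if s in set(gene_expr.columns)]
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, got {len(shared)}")

    def passes(de: pd.DataFrame, idx) -> bool:
        if idx not in de.index:
            return False
        row = de.loc[idx]
        return abs(row["log2fc"]) > lfc_min and row["p_holm"] < de_p_max

    cand = []
    for rec in db.itertuples(index=False):
        if rec.pre_mirna_id not in mirna_expr.index or rec.gene_id not in gene_expr.index:
            continue
        if passes(mirna_de, rec.pre_mirna_id) and passes(gene_de, rec.gene_id):
            cand.append(rec)
    if not cand:
        return _empty_network()

    rows = []
    for rec in cand:
        x = mirna_expr.loc[rec.pre_mirna_id, shared].to_numpy(dtype=float)
        y = gene_expr.loc[rec.gene_id, shared].to_numpy(dtype=float)
        res = stats.pearsonr(x, y, alternative="less")
        rows.append(
            {
                "pre_mirna_id": rec.pre_mirna_id,
                "gene_id": rec.gene_id,
                "pcc": float(res.statistic),
                "p_neg": float(res.pvalue),
                "mirna_log2fc": float(mirna_de.loc[rec.pre_mirna_id, "log2fc"]),
                "gene_log2fc": float(gene_de.loc[rec.gene_id, "log2fc"]),
                "source": rec.source,
            }
        )
    net = pd.DataFrame(rows)
    net["p_adj"] = multipletests(net.p_neg, method=p_adjust)[1]
    net = net[(net.p_adj < adj_p_max) & (net.pcc < 0)].reset_index(drop=True)
    return net.drop(columns=["p_neg"])


def _empty_network() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "pre_mirna_id",
            "gene_id",
            "pcc",
            "mirna_log2fc",
            "gene_log2fc",
            "source",
            "p_adj",
        ]
    )


def logfc_concordance(lfc_a: pd.Series, lfc_b: pd.Series) -> float:
    """Coefficient of determination between two log-fold-change vectors.

    Ordinary least squares of ``lfc_a`` on ``lfc_b`` over their shared
    index; returns R^2.
    """
    shared = lfc_a.index.intersection(lfc_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared features")
    x = lfc_b.loc[shared].to_numpy(dtype=float)
    y = lfc_a.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance log-fold-change vector")
    return float(stats.linregress(x, y).rvalue ** 2)


def cluster_summary(de: pd.DataFrame, members: list) -> dict:
    """Per-cluster DE summary for a user-supplied miRNA membership list
    (e.g. an imprinted cluster): how many members were tested, how many are
    significantly differential, and their mean log2 fold change."""
    present = [m for m in members if m in de.index]
    sub = de.loc[present]
    return {
        "n_members": len(members),
        "n_tested": len(present),
        "n_significant": int(sub["significant"].sum()) if "significant" in sub else 0,
        "mean_log2fc": float(sub["log2fc"].mean()) if len(present) else float("nan"),
    }
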