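"""Subtype signature derivation and nearest-centroid classification.

Differential expression between the two transcriptional subgroups (h vs o)
uses a per-gene two-tailed Welch t test with Holm family-wise correction;
the signed t scores order the signature. Group centroids are per-gene means
over the training samples, and new samples are assigned by distance
``1 - Spearman rho`` to each centroid, either with a fixed distance cutoff
(default 0.6) or by a 1-D Gaussian-mixture decomposition of the distance
distribution selected by BIC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CentroidModel",
    "Assignment",
    "welch_de",
    "build_centroids",
    "classify_samples",
    "call_high_expression",
]


def welch_de(m: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-group differential expression by Welch's t test.

    Parameters
    ----------
    m : genes x samples log2 expression.
    labels : per-sample group labels with exactly two levels; the first
        level in sorted order is treated as group "h" and t scores are
        oriented h minus o.

    Returns
    -------
    DataFrame indexed by gene with columns ``t_score``, ``p_raw``,
    ``p_holm``, ``log2fc`` (difference of group means). Genes with zero
    variance in both groups get t=0, p=1.
    """
    labels = labels.reindex(m.columns)
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    gh, go = levels
    xh = m.loc[:, labels == gh].to_numpy(dtype=float)
    xo = m.loc[:, labels == go].to_numpy(dtype=float)
    if xh.shape[1] < 2 or xo.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples for Welch's test")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xh, xo, axis=1, equal_var=False)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p_holm = multipletests(p, method="holm")[1]
    return pd.DataFrame(
        {
            "t_score": t,
            "p_raw": p,
            "p_holm": p_holm,
            "log2fc": xh.mean(axis=1) - xo.mean(axis=1),
        },
        index=m.index,
    )


@dataclass
class CentroidModel:
    """Nearest-centroid classifier artifact.

    Distance policy is fixed to ``1 - Spearman correlation``; samples whose
    minimum centroid distance is at or above ``assign_threshold`` remain
    unclassified in threshold mode.
    """

    signature_genes: list
    centroid_h: np.ndarray
    centroid_o: np.ndarray
    assign_threshold: float = 0.6
    gmm_max_components: int = 3
    aggregate: str = "mean"
    distance: str = "1 - spearman"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "signature_genes": list(self.signature_genes),
                    "centroid_h": [float(v) for v in self.centroid_h],
                    "centroid_o": [float(v) for v in self.centroid_o],
                    "assign_threshold": self.assign_threshold,
                    "gmm_max_components": self.gmm_max_components,
                    "aggregate": self.aggregate,
                    "distance": self.distance,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CentroidModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            signature_genes=d["signature_genes"],
            centroid_h=np.asarray(d["centroid_h"], dtype=float),
            centroid_o=np.asarray(d["centroid_o"], dtype=float),
            assign_threshold=d.get("assign_threshold", 0.6),
            gmm_max_components=d.get("gmm_max_components", 3),
            aggregate=d.get("aggregate", "mean"),
            distance=d.get("distance", "1 - spearman"),
        )


@dataclass
class Assignment:
    sample_id: str
    dist_h: float
    dist_o: float
    label: str  # "h", "o" or "unclassified"
    gmm_component: int | None = None


def build_centroids(
    m: pd.DataFrame,
    labels: pd.Series,
    signature: list,
    aggregate: str = "mean",
    assign_threshold: float = 0.6,
) -> CentroidModel:
    """Per-gene group centroids over the signature genes.

    ``aggregate`` is the per-gene summary within each group ("mean",
    or "median" as an option).
    """
    missing = [g for g in signature if g not in m.index]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing[:10]}")
    labels = labels.reindex(m.columns)
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    agg = np.mean if aggregate == "mean" else np.median
    sub = m.loc[list(signature)]
    ch = agg(sub.loc[:, labels == levels[0]].to_numpy(dtype=float), axis=1)
    co = agg(sub.loc[:, labels == levels[1]].to_numpy(dtype=float), axis=1)
    return CentroidModel(
        signature_genes=list(signature),
        centroid_h=ch,
        centroid_o=co,
        aggregate=aggregate,
        assign_threshold=assign_threshold,
    )


def _spearman_distance(profile: np.ndarray, centroid: np.ndarray) -> float:
    rho = stats.spearmanr(profile, centroid).statistic
    return float(1.0 - rho)


def classify_samples(
    m: pd.DataFrame,
    model: CentroidModel,
    mode: str = "threshold",
    seed: int = 0,
) -> pd.DataFrame:
    """Assign samples to h/o by rank-correlation distance to centroids.

    threshold mode: label = nearest group when the minimum distance is
    below ``model.assign_threshold``, else unclassified.

    gmm mode: 1-D Gaussian mixtures with 1..``gmm_max_components``
    components and equal ("tied") or free variances are fit to the dist_h
    distribution; the BIC-best model labels samples in its lowest-mean
    component h, highest-mean component o, any intermediate component
    unclassified. With a single component all samples fall back to the
    threshold rule.

    Missing signature genes are dropped pairwise (an error below 50%
    coverage, a warning above 10% missing).
    """
    sig = [g for g in model.signature_genes if g in m.index]
    frac = len(sig) / len(model.signature_genes)
    if frac < 0.5:
        raise ValueError(
            f"only {frac:.0%} of signature genes present; need at least 50%"
        )
    if frac < 0.9:
        logger.warning("%.0f%% of signature genes missing at prediction", 100 * (1 - frac))
    if len(sig) < 3:
        raise ValueError("fewer than 3 shared signature genes; rank correlation meaningless")
    pos = [model.signature_genes.index(g) for g in sig]
    ch = model.centroid_h[pos]
    co = model.centroid_o[pos]
    sub = m.loc[sig]

    rows = []
    for s in m.columns:
        prof = sub[s].to_numpy(dtype=float)
        dh = _spearman_distance(prof, ch)
        do = _spearman_distance(prof, co)
        rows.append((s, dh, do))
    out = pd.DataFrame(rows, columns=["sample_id", "dist_h", "dist_o"]).set_index(
        "sample_id"
    )

    if mode == "threshold":
        nearest = np.where(out.dist_h <= out.dist_o, "h", "o")
        mind = np.minimum(out.dist_h, out.dist_o)
        out["label"] = np.where(mind < model.assign_threshold, nearest, "unclassified")
        out["gmm_component"] = pd.NA
    elif mode == "gmm":
        comp, labels = _gmm_assign(
            out.dist_h.to_numpy(),
            max_components=model.gmm_max_components,
            seed=seed,
            fallback_threshold=model.assign_threshold,
            dist_o=out.dist_o.to_numpy(),
        )
        out["label"] = labels
        out["gmm_component"] = comp
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def _gmm_assign(dist_h, max_components, seed, fallback_threshold, dist_o):
    """BIC-selected 1-D GMM on the h-centroid distance distribution."""
    x = dist_h.reshape(-1, 1)
    best, best_bic = None, np.inf
    for k in range(1, max_components + 1):
        if k > len(x):
            break
        for cov in ("tied", "full"):
            gm = GaussianMixture(
                n_components=k,
                covariance_type=cov,
                n_init=10,
                random_state=seed,
                reg_covar=1e-6,
            ).fit(x)
            bic = gm.bic(x)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
    comp = best.predict(x)
    means = best.means_.ravel()
    order = np.argsort(means)
    if best.n_components == 1:
        nearest = np.where(dist_h <= dist_o, "h", "o")
        mind = np.minimum(dist_h, dist_o)
        labels = np.where(mind < fallback_threshold, nearest, "unclassified")
    else:
        low, high = order[0], order[-1]
        labels = np.full(len(x), "unclassified", dtype=object)
        labels[comp == low] = "h"
        labels[comp == high] = "o"
    return comp, labels


def call_high_expression(
    m: pd.DataFrame, gene: str, platforms: pd.Series | None = None
) -> pd.Series:
    """Flag samples where ``gene`` exceeds the global third quartile.

    The Q3 reference is the linear-interpolation quantile of the flattened
    full matrix (all genes, all samples); when a per-sample platform tag is
    given, Q3 is computed separately within each platform. Strict
    inequality: a value exactly at Q3 is not called high.
    """
    if gene not in m.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    vals = m.loc[gene]
    if platforms is None:
        q3 = float(np.quantile(m.to_numpy(dtype=float), 0.75))
        return vals > q3
    platforms = platforms.reindex(m.columns)
    out = pd.Series(False, index=m.columns)
    for plat, cols in m.columns.to_series().groupby(platforms):
        q3 = float(np.quantile(m[list(cols)].to_numpy(dtype=float), 0.75))
        out[list(cols)] = vals[list(cols)] > q3
    return out
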