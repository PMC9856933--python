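"""Cross-platform expression harmonization.

Merges two log2-scale expression matrices (genes x samples) measured on
different microarray platforms into a single comparable matrix:

1. keep only genes whose measurements reproduce across platforms
   (per-gene cross-platform Pearson correlation over shared samples),
2. quantile-normalize each experiment, then the merged matrix,
3. per gene, median-center within each experiment and re-add the mean of
   the two experiment medians, so both platforms end up on a common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizationReport",
    "select_reproducible_genes",
    "quantile_normalize",
    "merge_and_harmonize",
]


@dataclass
class HarmonizationReport:
    """Outcome of cross-platform gene selection.

    Attributes
    ----------
    selected_genes : list of str
        Genes judged reproducible between the two platforms.
    per_gene_self_pcc : pandas.Series
        Cross-platform self-correlation for every common, non-degenerate
        gene (indexed by gene id).
    experiment_medians : dict
        Per-platform overall median expression, for reporting.
    dropped_constant : list of str
        Common genes excluded because one platform measured them at
        constant level (undefined correlation).
    """

    selected_genes: list = field(default_factory=list)
    per_gene_self_pcc: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    experiment_medians: dict = field(default_factory=dict)
    dropped_constant: list = field(default_factory=list)


def _cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation between rows of ``a`` and rows of ``b``.

    Rows must already be non-constant. Returns a (len(a), len(b)) matrix.
    """
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return az @ bz.T


def select_reproducible_genes(
    a: pd.DataFrame,
    b: pd.DataFrame,
    shared: list | None = None,
    pcc_min: float = 0.8,
    both_directions: bool = True,
) -> HarmonizationReport:
    """Select genes that reproduce between two platforms.

    A gene is selected when its cross-platform self-correlation over the
    shared samples exceeds ``pcc_min``, or when that self-correlation beats
    its correlation with every *other* gene (the best-reciprocal clause,
    applied in both directions unless ``both_directions`` is False, in which
    case only the a-against-b direction is required).

    Parameters
    ----------
    a, b : pandas.DataFrame
        Genes x samples, log2 scale.
    shared : list of sample ids measured on both platforms. Defaults to the
        intersection of columns.

    Returns
    -------
    HarmonizationReport
    """
    if shared is None:
        shared = [s for s in a.columns if s in set(b.columns)]
    shared = list(shared)
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared samples to correlate, got {len(shared)}"
        )
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no genes in common between the two platforms")

    av = a.loc[common, shared].to_numpy(dtype=float)
    bv = b.loc[common, shared].to_numpy(dtype=float)
    const = (av.std(axis=1) == 0) | (bv.std(axis=1) == 0)
    dropped = list(common[const])
    if dropped:
        logger.warning(
            "excluding %d constant-expression gene(s) with undefined correlation",
            len(dropped),
        )
    genes = common[~const]
    av, bv = av[~const], bv[~const]

    cc = _cross_correlation(av, bv)  # cc[i, j] = PCC(a[gene_i], b[gene_j])
    self_pcc = np.diag(cc)
    n = len(genes)
    if n == 1:
        best_row = best_col = np.ones(1, dtype=bool)
    else:
        off = cc - np.diag(np.full(n, np.inf))  # mask diagonal
        best_row = self_pcc > off.max(axis=1)  # beats PCC(a[g], b[h]) for all h
        best_col = self_pcc > off.max(axis=0)  # beats PCC(b[g], a[h]) for all h
    best = (best_row & best_col) if both_directions else best_row
    keep = (self_pcc > pcc_min) | best

    return HarmonizationReport(
        selected_genes=list(genes[keep]),
        per_gene_self_pcc=pd.Series(self_pcc, index=genes),
        experiment_medians={
            "a": float(np.median(a.to_numpy())),
            "b": float(np.median(b.to_numpy())),
        },
        dropped_constant=dropped,
    )


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to a common reference distribution.

    The reference is the mean across columns of the sorted value vectors;
    tied values within a column receive the average of the reference values
    at their tied ranks. Idempotent; preserves row and column order.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = m.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        vals = ref[ranks]
        # average reference values over ties so equal inputs map to equal outputs
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=vals)
            counts = np.bincount(inv)
            vals = (sums / counts)[inv]
        out[:, j] = vals
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def merge_and_harmonize(
    a: pd.DataFrame,
    b: pd.DataFrame,
    genes: list | None = None,
    suffix_platforms: bool = False,
) -> pd.DataFrame:
    """Merge two platforms into one harmonized matrix.

    Each experiment is quantile-normalized separately, the column-merged
    matrix is quantile-normalized again, and each gene is median-centered
    within each experiment with the mean of the two experiment medians added
    back. By construction the per-gene medians of the two platforms are
    identical afterwards.

    Sample ids must be disjoint between the inputs; with
    ``suffix_platforms=True`` overlapping ids are suffixed ``.A`` / ``.B``.
    """
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both platforms must contain at least one sample")
    if genes is None:
        genes = list(a.index.intersection(b.index))
    missing = [g for g in genes if g not in a.index or g not in b.index]
    if missing:
        raise KeyError(f"genes absent from one platform: {missing[:5]}...")
    overlap = set(a.columns) & set(b.columns)
    if overlap:
        if not suffix_platforms:
            raise ValueError(
                "duplicate sample ids across platforms; pass suffix_platforms=True "
                f"or rename (first: {sorted(overlap)[:3]})"
            )
        a = a.rename(columns={s: f"{s}.A" for s in a.columns})
        b = b.rename(columns={s: f"{s}.B" for s in b.columns})

    a_n = quantile_normalize(a.loc[genes])
    b_n = quantile_normalize(b.loc[genes])
    merged = quantile_normalize(pd.concat([a_n, b_n], axis=1))

    cols_a = list(a_n.columns)
    cols_b = list(b_n.columns)
    med_a = merged[cols_a].median(axis=1)
    med_b = merged[cols_b].median(axis=1)
    target = (med_a + med_b) / 2.0
    merged[cols_a] = merged[cols_a].sub(med_a, axis=0).add(target, axis=0)
    merged[cols_b] = merged[cols_b].sub(med_b, axis=0).add(target, axis=0)
    return merged
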