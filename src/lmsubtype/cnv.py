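"""Copy-number projection onto genes, penetrance and recurrence enrichment.

Per-patient copy-number segments (BED-like, 0-based half-open) are
projected onto gene models: a gene overlapping several segments takes the
lowest copy number, CN=128 artifact segments are discarded, and genes
absent in more than a third of patients are dropped. Integer copy numbers
map to events (homozygous/heterozygous deletion, normal, gain,
amplification); penetrance is the per-group event frequency over
non-missing patients. Group enrichment of merged losses and gains uses a
one-tailed Fisher exact test, and cytoband enrichment a one-tailed Fisher
over significant genes per band with Holm correction across bands.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .clinstats import fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_EVENT_MAP",
    "segments_to_genes",
    "classify_events",
    "penetrance",
    "group_enrichment",
    "cytoband_enrichment",
]

ARTIFACT_CN = 128

# copy-number -> event category boundaries; amplification at CN >= 6 keeps
# the in-situ-hybridization convention consistent with the array calls
DEFAULT_EVENT_MAP = {"homdel_max": 0, "hetdel_max": 1, "normal_max": 2, "gain_max": 5}

EVENTS = ["homdel", "hetdel", "normal", "gain", "amp"]


def segments_to_genes(
    segs: pd.DataFrame,
    genes: pd.DataFrame,
    max_missing_fraction: float = 1 / 3,
) -> pd.DataFrame:
    """Project segments onto genes: gene x patient integer copy number.

    ``segs`` columns: patient_id, chrom, start, end, copy_number (0-based
    half-open). ``genes`` columns: chrom, start, end, gene_id. Rules:
    CN=128 segments are artifacts and dropped; a gene overlapping several
    segments takes the minimum CN; no overlap means missing (NaN); genes
    missing in more than ``max_missing_fraction`` of patients are dropped.
    """
    _check_intervals(segs, "segments")
    _check_intervals(genes, "genes")
    patients = sorted(segs.patient_id.unique())
    segs = segs[segs.copy_number != ARTIFACT_CN]
    gene_ids = list(genes.gene_id)
    out = pd.DataFrame(np.nan, index=gene_ids, columns=patients)
    gene_arr = {
        chrom: sub[["start", "end", "gene_id"]]
        for chrom, sub in genes.groupby("chrom")
    }
    for (patient, chrom), sub in segs.groupby(["patient_id", "chrom"]):
        if chrom not in gene_arr:
            continue
        g = gene_arr[chrom]
        gs = g.start.to_numpy()
        ge = g.end.to_numpy()
        for seg in sub.itertuples(index=False):
            hit = (gs < seg.end) & (ge > seg.start)  # half-open overlap
            if not hit.any():
                continue
            ids = g.gene_id.to_numpy()[hit]
            cur = out.loc[ids, patient]
            out.loc[ids, patient] = np.fmin(cur.to_numpy(dtype=float), seg.copy_number)
    missing_frac = out.isna().mean(axis=1)
    dropped = missing_frac > max_missing_fraction
    if dropped.any():
        logger.info("dropping %d gene(s) missing in > 1/3 of patients", int(dropped.sum()))
    return out.loc[~dropped]


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    bad = df.index[(df.start >= df.end) | (df.start < 0)]
    if len(bad):
        raise ValueError(f"malformed interval in {what} at row(s) {list(bad[:5])}")


def classify_events(t: pd.DataFrame, event_map: dict | None = None) -> pd.DataFrame:
    """Map integer copy numbers to event categories.

    Default: 0 homdel, 1 hetdel, 2 normal, 3-5 gain, >= 6 amp; missing
    copy numbers stay 'missing'. Boundaries configurable via ``event_map``.
    """
    em = dict(DEFAULT_EVENT_MAP, **(event_map or {}))
    cn = t.to_numpy(dtype=float)
    ev = np.full(cn.shape, "missing", dtype=object)
    with np.errstate(invalid="ignore"):
        ev[cn <= em["homdel_max"]] = "homdel"
        ev[(cn > em["homdel_max"]) & (cn <= em["hetdel_max"])] = "hetdel"
        ev[(cn > em["hetdel_max"]) & (cn <= em["normal_max"])] = "normal"
        ev[(cn > em["normal_max"]) & (cn <= em["gain_max"])] = "gain"
        ev[cn > em["gain_max"]] = "amp"
    ev[~np.isfinite(cn)] = "missing"
    return pd.DataFrame(ev, index=t.index, columns=t.columns)


def penetrance(events: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene, per-group event frequencies (missing patients discarded).

    Returns a long table with one row per (gene, group, event) including
    the merged categories loss = homdel+hetdel and gain_any = gain+amp.
    """
    groups = groups.reindex(events.columns)
    rows = []
    for g in sorted(groups.dropna().unique()):
        sub = events.loc[:, groups == g]
        arr = sub.to_numpy()
        nonmiss = (arr != "missing").sum(axis=1).astype(float)
        for ev in EVENTS:
            count = (arr == ev).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq = np.where(nonmiss > 0, count / np.where(nonmiss > 0, nonmiss, 1), np.nan)
            rows.append(
                pd.DataFrame(
                    {"gene_id": events.index, "group": g, "event": ev,
                     "count": count, "n": nonmiss, "frequency": freq}
                )
            )
    out = pd.concat(rows, ignore_index=True)
    merged = []
    for (gene, grp), sub in out.groupby(["gene_id", "group"], sort=False):
        by = sub.set_index("event")
        for name, parts in (("loss", ("homdel", "hetdel")), ("gain_any", ("gain", "amp"))):
            cnt = int(by.loc[list(parts), "count"].sum())
            n = float(by["n"].iloc[0])
            merged.append(
                {"gene_id": gene, "group": grp, "event": name, "count": cnt,
                 "n": n, "frequency": cnt / n if n > 0 else np.nan}
            )
    return pd.concat([out, pd.DataFrame(merged)], ignore_index=True)


def group_enrichment(
    events: pd.DataFrame,
    groups: pd.Series,
    enriched_group: str = "h",
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Per-gene one-tailed Fisher test for event enrichment in one group.

    Losses (homdel + hetdel) and gains (gain + amp) are tested separately;
    the alternative is over-representation in ``enriched_group``. Missing
    patients are discarded per gene.
    """
    groups = groups.reindex(events.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    other = [g for g in levels if g != enriched_group][0]
    arr = events.to_numpy()
    in_h = (groups == enriched_group).to_numpy()
    in_o = (groups == other).to_numpy()
    rows = []
    for direction, members in (("loss", ("homdel", "hetdel")), ("gain", ("gain", "amp"))):
        is_ev = np.isin(arr, members)
        nonmiss = arr != "missing"
        for i, gene in enumerate(events.index):
            a = int((is_ev[i] & in_h).sum())
            b = int((is_ev[i] & in_o).sum())
            c = int((~is_ev[i] & nonmiss[i] & in_h).sum())
            d = int((~is_ev[i] & nonmiss[i] & in_o).sum())
            p = fisher_exact_2x2([[a, b], [c, d]], alternative="greater")
            rows.append(
                {"gene_id": gene, "direction": direction, "n_event_h": a,
                 "n_event_o": b, "p_value": p, "significant": p < p_max}
            )
    return pd.DataFrame(rows)


def cytoband_enrichment(
    sig_genes: dict,
    all_genes: pd.DataFrame,
    bands: pd.DataFrame,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Cytoband enrichment of significantly altered genes, per event type.

    ``sig_genes`` maps event type (e.g. "loss", "gain") to the set of
    significantly altered genes; ``all_genes`` is the gene model
    (chrom/start/end/gene_id) forming the universe; ``bands`` the cytoband
    BED (chrom/start/end/band_id). Genes are assigned to the band
    containing their start position. Per event type, each band gets a
    one-tailed Fisher test (significant vs not x in band vs not) with Holm
    correction across bands; per band only the most significant surviving
    event is reported.
    """
    from statsmodels.stats.multitest import multipletests

    band_of = _assign_bands(all_genes, bands)
    universe = band_of.index
    results = []
    for event, genes in sig_genes.items():
        genes = set(genes) & set(universe)
        if not genes:
            continue
        recs = []
        for band in bands.band_id:
            members = set(universe[band_of == band])
            a = len(genes & members)
            b = len(genes - members)
            c = len(members - genes)
            d = len(universe) - a - b - c
            p = fisher_exact_2x2([[a, b], [c, d]], alternative="greater")
            recs.append({"band_id": band, "event": event, "n_sig_in_band": a, "p_value": p})
        sub = pd.DataFrame(recs)
        sub["p_holm"] = multipletests(sub.p_value, method="holm")[1]
        results.append(sub)
    if not results:
        return pd.DataFrame(columns=["band_id", "event", "n_sig_in_band", "p_value", "p_holm"])
    res = pd.concat(results, ignore_index=True)
    res = res[res.p_holm < p_max]
    # most significant event per band
    res = (
        res.sort_values(["band_id", "p_holm", "p_value", "event"])
        .groupby("band_id", as_index=False)
        .first()
    )
    return res.reset_index(drop=True)


def _assign_bands(genes: pd.DataFrame, bands: pd.DataFrame) -> pd.Series:
    """Band id per gene, by gene start position; genes outside all bands
    are excluded with a warning."""
    out = {}
    outside = []
    for rec in genes.itertuples(index=False):
        sub = bands[(bands.chrom == rec.chrom) & (bands.start <= rec.start) & (rec.start < bands.end)]
        if len(sub) == 0:
            outside.append(rec.gene_id)
            continue
        out[rec.gene_id] = sub.band_id.iloc[0]
    if outside:
        logger.warning("%d gene(s) outside all cytobands excluded", len(outside))
    return pd.Series(out, dtype=object)
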