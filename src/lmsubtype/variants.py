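"""Somatic variant filtering, alteration summaries and mutational signatures.

Somatic SNVs are retained under depth/allele-fraction/population-frequency
rules (tumor depth >= 14, normal depth >= 8, tumor AF >= 0.3, normal AF = 0,
population AF < 0.1%, coding, non-synonymous, RNA-covered when measured).
Per-gene alterations (mutation classes, structural variants, allele losses)
are aggregated into per-group percentage tables; biallelic inactivation
patterns (one vs two distinct mechanisms) are compared between groups by
Fisher's test. SNVs are binned into the fixed 96 trinucleotide-context
order on the pyrimidine strand, and per-patient signature exposures are
obtained by non-negative least squares over the catalog signatures similar
enough (cosine > 0.75) to the observed profile.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .clinstats import fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "CONTEXTS_96",
    "MUTATION_CLASSES",
    "filter_somatic",
    "aggregate_alterations",
    "biallelic_pattern",
    "tmb",
    "context_matrix",
    "fit_signatures",
    "cosine_similarity",
]

_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
#: Fixed 96-context order: substitution-major, then 5' and 3' flanks
#: (A[C>A]A, A[C>A]C, ..., T[T>G]T), pyrimidine reference strand.
CONTEXTS_96 = [
    f"{five}[{sub}]{three}"
    for sub in _SUBS
    for five in "ACGT"
    for three in "ACGT"
]

MUTATION_CLASSES = {"missense", "nonsense", "frameshift", "nonFS", "splicing"}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def filter_somatic(
    v: pd.DataFrame,
    min_t_depth: int = 14,
    min_n_depth: int = 8,
    min_t_af: float = 0.3,
    max_n_af: float = 0.0,
    max_pop_af: float = 0.001,
    min_rna_depth: int = 5,
) -> pd.DataFrame:
    """Retain somatic variants passing all filter rules.

    A record passes when tumor depth >= ``min_t_depth``, normal depth >=
    ``min_n_depth``, tumor allele fraction >= ``min_t_af``, normal allele
    fraction <= ``max_n_af`` (default: exactly zero), population allele
    frequency < ``max_pop_af``, located in coding sequence and
    non-synonymous; records with an RNA coverage below ``min_rna_depth``
    (when measured) are dropped. The first failing rule of each rejected
    record is logged. Idempotent.
    """
    rules = [
        ("t_depth", lambda r: r.t_depth >= min_t_depth),
        ("n_depth", lambda r: r.n_depth >= min_n_depth),
        ("t_af", lambda r: r.t_af >= min_t_af),
        ("n_af", lambda r: r.n_af <= max_n_af),
        ("pop_af", lambda r: r.pop_af < max_pop_af),
        ("coding", lambda r: bool(r.coding)),
        ("synonymous", lambda r: not bool(r.synonymous)),
        (
            "rna_depth",
            lambda r: (
                pd.isna(getattr(r, "rna_depth", np.nan))
                or getattr(r, "rna_depth") >= min_rna_depth
            ),
        ),
    ]
    keep = np.ones(len(v), dtype=bool)
    for i, rec in enumerate(v.itertuples(index=False)):
        for name, ok in rules:
            if not ok(rec):
                keep[i] = False
                logger.debug("variant %s:%s rejected by rule %s", rec.chrom, rec.pos, name)
                break
    return v.loc[keep].reset_index(drop=True)


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def aggregate_alterations(
    v: pd.DataFrame,
    groups: pd.Series,
    genes_of_interest: list,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-gene, per-group alteration summary (percent and count).

    ``v`` holds one row per (patient_id, gene, class) alteration; classes
    in ``MUTATION_CLASSES`` count as "mutation", plus "SV" and "loss".
    For each group (and the pooled "all"), the table reports the number and
    percentage of patients carrying at least one record per category and at
    least one of any category ("total"); a patient is counted once per
    category regardless of multiplicity. Percentages are rounded half away
    from zero to ``decimals``.
    """
    known = groups.dropna()
    orphan = set(v.patient_id) - set(known.index)
    if orphan:
        logger.warning("%d patient(s) in no group excluded", len(orphan))
        v = v[v.patient_id.isin(known.index)]
    group_levels = sorted(known.unique())
    cohorts = {g: set(known.index[known == g]) for g in group_levels}
    cohorts["all"] = set(known.index)

    def cat(cls: str) -> str:
        if cls in MUTATION_CLASSES:
            return "mutation"
        if cls in ("SV", "loss"):
            return cls
        raise ValueError(f"unknown alteration class {cls!r}")

    v = v.assign(category=v["class"].map(cat))
    rows = []
    for gene in genes_of_interest:
        sub = v[v.gene == gene]
        for gname, members in cohorts.items():
            gsub = sub[sub.patient_id.isin(members)]
            by_cat = {
                c: set(gsub.patient_id[gsub.category == c])
                for c in ("mutation", "SV", "loss")
            }
            by_cat["total"] = set(gsub.patient_id)
            for c, pats in by_cat.items():
                n = len(members)
                count = len(pats)
                rows.append(
                    {
                        "gene": gene,
                        "group": gname,
                        "category": c,
                        "count": count,
                        "group_size": n,
                        "percent": _round_half_away(100.0 * count / n, decimals) if n else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def biallelic_pattern(statuses: pd.DataFrame, groups: pd.Series):
    """One- vs two-mechanism biallelic inactivation, compared across groups.

    ``statuses`` has columns ``allele1`` and ``allele2`` indexed by patient,
    values in {"L", "MS", "FS", "WT"} (loss, missense, frameshift, intact).
    Patients with an intact allele are excluded; among biallelically
    inactivated patients, both alleles hit by the same class count as
    one-mechanism, different classes as two-mechanism. Returns the 2x2
    contingency (rows: one/two mechanism; columns: groups in sorted order)
    and the two-sided Fisher p.
    """
    groups = groups.reindex(statuses.index).dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    bi = statuses.loc[groups.index]
    bi = bi[(bi.allele1 != "WT") & (bi.allele2 != "WT")]
    one = bi.allele1 == bi.allele2
    table = np.array(
        [
            [int((one & (groups.loc[bi.index] == g)).sum()) for g in levels],
            [int((~one & (groups.loc[bi.index] == g)).sum()) for g in levels],
        ]
    )
    p = fisher_exact_2x2(table, alternative="two-sided")
    contingency = pd.DataFrame(
        table, index=["one_mechanism", "two_mechanism"], columns=levels
    )
    return contingency, p


def tmb(v: pd.DataFrame, genome_length_bp: float) -> pd.Series:
    """Per-patient tumor mutation burden: somatic variants per megabase."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    counts = v.groupby("patient_id").size()
    return counts / (genome_length_bp / 1e6)


def context_matrix(v: pd.DataFrame, ref_contexts: dict) -> pd.DataFrame:
    """Bin SNVs into the 96 trinucleotide contexts per patient.

    ``ref_contexts`` maps (chrom, pos) -> reference-strand trinucleotide
    centered on the variant. Purine-reference SNVs are reverse-complemented
    onto the pyrimidine strand. Non-SNV records are ignored; lookup
    failures are skipped with a log message.
    """
    patients = sorted(v.patient_id.unique())
    out = pd.DataFrame(0, index=CONTEXTS_96, columns=patients)
    skipped = 0
    for rec in v.itertuples(index=False):
        ref, alt = str(rec.ref), str(rec.alt)
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            continue
        tri = ref_contexts.get((rec.chrom, rec.pos))
        if tri is None or len(tri) != 3 or tri[1] != ref:
            skipped += 1
            continue
        if ref in "AG":  # purine: flip to pyrimidine strand
            tri = _revcomp(tri)
            ref = _COMPLEMENT[rec.ref]
            alt = _COMPLEMENT[rec.alt]
        key = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
        out.loc[key, rec.patient_id] += 1
    if skipped:
        logger.warning("%d SNV(s) skipped: unresolvable trinucleotide context", skipped)
    return out


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def fit_signatures(
    counts: pd.DataFrame, catalog: pd.DataFrame, cos_min: float = 0.75
):
    """Refit catalog signatures to per-patient mutation profiles.

    ``counts`` is 96 contexts x patients; ``catalog`` 96 contexts x
    signatures (each column summing to one). Per patient, candidate
    signatures are those with cosine similarity above ``cos_min`` to the
    observed profile; exposures are the non-negative least-squares fit of
    the count vector on the candidates (zero elsewhere). Returns
    (exposures, reconstruction_cosine): signatures x patients exposures and
    a per-patient cosine between observed and reconstructed profiles
    (NaN when no signature qualifies; such patients are flagged in the log).
    """
    counts = counts.reindex(CONTEXTS_96).fillna(0)
    catalog = catalog.reindex(CONTEXTS_96).fillna(0)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative mutation counts")
    cat = catalog.to_numpy(dtype=float)
    exposures = pd.DataFrame(0.0, index=catalog.columns, columns=counts.columns)
    recon = pd.Series(np.nan, index=counts.columns, dtype=float)
    for patient in counts.columns:
        y = counts[patient].to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        sims = np.array([cosine_similarity(y, cat[:, j]) for j in range(cat.shape[1])])
        cand = np.where(sims > cos_min)[0]
        if len(cand) == 0:
            logger.warning("patient %s: no catalog signature with cosine > %g", patient, cos_min)
            continue
        coef, _ = nnls(cat[:, cand], y)
        exposures.loc[catalog.columns[cand], patient] = coef
        recon[patient] = cosine_similarity(y, cat[:, cand] @ coef)
    return exposures, recon
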