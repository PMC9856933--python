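"""Synthetic multi-omic cohorts with known ground truth.

Every input the pipeline consumes can be generated here with the
statistical structure the downstream analyses assume: two latent
expression subtypes (h more homogeneous than o) with platform batch
effects, implanted co-expression modules, anti-correlated miRNA/target
pairs, per-patient copy-number segments with group-enriched altered
cytobands, and somatic SNVs drawn from mixtures of trinucleotide-context
signatures. All randomness flows from ``SimConfig.seed`` through named
per-generator streams, so identical configurations give byte-identical
outputs.

The defaults state a world resembling the cohorts the analyses were
designed for: a 42 vs 56 two-group expression cohort with clinical
contrasts (abdominal location, sex, grade, differentiation, mitotic
count), an 87-sample dual-platform design, and 28 vs 11 genomic cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import CONTEXTS_96, _COMPLEMENT, _revcomp

__all__ = [
    "SimConfig",
    "TruthBundle",
    "gen_dual_platform_cohort",
    "gen_subtype_cohort",
    "gen_mirna_cohort",
    "gen_cnv_cohort",
    "gen_variant_cohort",
    "make_signature_catalog",
    "gen_alteration_scenario",
]

# salts for the independent per-generator random streams
_SALT_DUAL, _SALT_SUBTYPE, _SALT_MIRNA, _SALT_CNV, _SALT_VARIANT = 11, 23, 37, 53, 71


@dataclass
class SimConfig:
    """Configuration for all synthetic generators.

    Unstated knobs default to what the downstream analyses assume:
    log2-normal expression noise, negative-binomial miRNA counts with
    gene-wise dispersion, a toy genome of 2 chromosomes x 10 cytobands
    (1 Mb each, 1 kb genes), clinical contrasts matching the cohort
    frequencies the enrichment tests were designed around.
    """

    seed: int = 0
    #: seed of the latent disease "world" (which genes are differential,
    #: their directions, baseline means, module membership, miRNA targets).
    #: Cohorts drawn with different ``seed`` but the same ``world_seed`` are
    #: independent samples of the same disease, so a classifier trained on
    #: one draw transfers to another.
    world_seed: int = 2023

    # expression cohort
    n_genes: int = 2000
    n_samples_per_group: tuple = (42, 56)  # (h, o)
    de_fraction: float = 0.18
    effect_size: float = 2.0  # log2 units
    variance_ratio_o_vs_h: float = 1.5
    base_noise_sd: float = 0.8

    # implanted co-expression modules
    n_modules: int = 6
    module_size: int = 15
    module_factor_sd: float = 2.0
    module_noise_sd: float = 1.0

    # dual-platform design
    n_shared_samples: int = 87
    n_concordant: int | None = None  # default: half the genes
    platform_shift_sd: float = 0.5  # log2 units
    measurement_noise_sd: float = 0.2

    # clinical annotation: per-group probability of the reference level
    clinical_probs: dict = field(
        default_factory=lambda: {
            "location": ("internal_trunk", "other", 0.60, 0.07),
            "sex": ("F", "M", 0.76, 0.48),
            "grade": ("low", "high", 0.58, 0.24),
            "differentiation": ("well", "poor", 0.88, 0.24),
        }
    )
    mitotic_mean: tuple = (17.0, 24.5)  # (h, o)
    hazard_ratio: float = 2.0  # h vs o event hazard
    median_survival_o: float = 60.0  # months
    censor_range: tuple = (36.0, 180.0)  # months, uniform administrative censoring

    # miRNA cohort
    n_mirnas: int = 300
    n_mirna_de: int = 60
    mirna_lfc: float = 2.0
    mirna_dispersion: float = 10.0
    n_true_interactions: int = 50
    n_decoys: int = 200
    interaction_pcc: float = -0.8
    n_background_genes: int = 200
    two_mature_fraction: float = 0.3

    # genomic cohorts
    n_patients_per_group: tuple = (28, 11)
    n_segments: int = 6  # random balanced noise alterations per patient
    enriched_bands: dict = field(
        default_factory=lambda: {"chr1.b03": ("loss", 0.8, 0.2)}
    )

    # mutational signatures
    n_signatures: int = 3
    signature_mixture: tuple = (0.6, 0.4, 0.0)
    mutations_per_patient: int = 1000
    variant_pass_fraction: float = 0.8

    def __post_init__(self):
        if self.n_genes < 20:
            raise ValueError("n_genes must be >= 20")
        if not 0 < self.de_fraction < 1:
            raise ValueError("de_fraction must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.variance_ratio_o_vs_h < 1:
            raise ValueError("variance_ratio_o_vs_h must be >= 1")
        if not -1 <= self.interaction_pcc < 0:
            raise ValueError("interaction_pcc must lie in [-1, 0)")
        if min(self.n_samples_per_group) < 3:
            raise ValueError("each expression group needs >= 3 samples")
        if self.n_shared_samples < 3:
            raise ValueError("need >= 3 shared dual-platform samples")
        mix = np.atleast_2d(np.asarray(self.signature_mixture, dtype=float))
        if not np.allclose(mix.sum(axis=1), 1.0):
            raise ValueError("signature_mixture rows must sum to 1")

    @property
    def enriched_band_ids(self) -> list:
        return sorted(self.enriched_bands)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthBundle:
    """Ground truth of a generated cohort, for recovery checks."""

    true_group_labels: pd.Series | None = None
    true_de_genes: list = field(default_factory=list)
    true_module_partition: dict = field(default_factory=dict)
    true_interactions: list = field(default_factory=list)
    true_enriched_bands: dict = field(default_factory=dict)
    true_signature_exposures: pd.DataFrame | None = None
    true_concordant_genes: list = field(default_factory=list)


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def _world_rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.world_seed, salt + 1]))


# ---------------------------------------------------------------------------
# dual-platform expression
# ---------------------------------------------------------------------------

def gen_dual_platform_cohort(cfg: SimConfig):
    """Two platform measurements of the same samples.

    Concordant genes share a latent expression profile (plus platform B's
    per-gene additive shift and independent measurement noise); the
    complement is scrambled, i.e. platform B measures an independent
    profile. Returns (matrix_a, matrix_b, shared_sample_ids, truth).
    """
    rng = _rng(cfg, _SALT_DUAL)
    n_g, n_s = cfg.n_genes, cfg.n_shared_samples
    n_conc = cfg.n_concordant if cfg.n_concordant is not None else n_g // 2
    if not 0 <= n_conc <= n_g:
        raise ValueError("n_concordant out of range")
    genes = [f"G{i:04d}" for i in range(1, n_g + 1)]
    samples = [f"S{i:03d}" for i in range(1, n_s + 1)]

    mean = rng.normal(8.0, 2.0, size=n_g)
    latent = mean[:, None] + rng.normal(0.0, 1.0, size=(n_g, n_s))
    noise = cfg.measurement_noise_sd
    a = latent + rng.normal(0.0, noise, size=(n_g, n_s)) if noise > 0 else latent.copy()
    shift = rng.normal(0.0, cfg.platform_shift_sd, size=n_g) if cfg.platform_shift_sd > 0 else np.zeros(n_g)
    b = latent + shift[:, None]
    scrambled = np.arange(n_conc, n_g)
    b[scrambled] = (
        mean[scrambled, None]
        + shift[scrambled, None]
        + rng.normal(0.0, 1.0, size=(len(scrambled), n_s))
    )
    if noise > 0:
        b = b + rng.normal(0.0, noise, size=(n_g, n_s))

    ma = pd.DataFrame(a, index=genes, columns=samples)
    mb = pd.DataFrame(b, index=genes, columns=samples)
    truth = TruthBundle(true_concordant_genes=genes[:n_conc])
    return ma, mb, samples, truth


# ---------------------------------------------------------------------------
# two-subtype expression cohort with clinical annotation
# ---------------------------------------------------------------------------

def gen_subtype_cohort(cfg: SimConfig):
    """Two-group expression cohort with clinical/survival annotation.

    Group h is transcriptionally more homogeneous (group o per-gene noise
    variance is ``variance_ratio_o_vs_h`` times larger); a ``de_fraction``
    of genes is shifted by ``effect_size`` log2 units between groups (half
    up, half down in h); disjoint gene blocks share a latent factor and
    form implanted co-expression modules. Returns (matrix, annotation,
    truth).
    """
    rng = _rng(cfg, _SALT_SUBTYPE)
    world = _world_rng(cfg, _SALT_SUBTYPE)
    n_h, n_o = cfg.n_samples_per_group
    n = n_h + n_o
    samples = [f"P{i:03d}" for i in range(1, n + 1)]
    labels = pd.Series(["h"] * n_h + ["o"] * n_o, index=samples, name="group")
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    n_mod_genes = cfg.n_modules * cfg.module_size
    if n_de + n_mod_genes > cfg.n_genes:
        raise ValueError("de_fraction plus module genes exceed n_genes")
    order = world.permutation(cfg.n_genes)
    de_idx = order[:n_de]
    mod_idx = order[n_de : n_de + n_mod_genes]

    mean = world.normal(8.0, 1.5, size=cfg.n_genes)
    sd = np.full(n, cfg.base_noise_sd)
    sd[n_h:] *= np.sqrt(cfg.variance_ratio_o_vs_h)
    x = mean[:, None] + rng.normal(0.0, 1.0, size=(cfg.n_genes, n)) * sd[None, :]

    sign = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    x[de_idx[:, None], np.arange(n_h)[None, :]] += (sign * cfg.effect_size)[:, None]

    partition = {}
    for m in range(cfg.n_modules):
        rows = mod_idx[m * cfg.module_size : (m + 1) * cfg.module_size]
        factor = rng.normal(0.0, cfg.module_factor_sd, size=n)
        x[rows] = (
            mean[rows][:, None]
            + factor[None, :]
            + rng.normal(0.0, cfg.module_noise_sd, size=(len(rows), n)) * (sd / cfg.base_noise_sd)[None, :]
        )
        partition[f"M{m + 1:02d}"] = [genes[i] for i in sorted(rows)]

    matrix = pd.DataFrame(x, index=genes, columns=samples)

    ann = pd.DataFrame(index=samples)
    ann["group"] = labels
    is_h = (labels == "h").to_numpy()
    for feat, (ref, other, p_h, p_o) in cfg.clinical_probs.items():
        p = np.where(is_h, p_h, p_o)
        ann[feat] = np.where(rng.random(n) < p, ref, other)
    ann["histotype"] = "LMS"
    lam = np.where(is_h, cfg.mitotic_mean[0], cfg.mitotic_mean[1])
    ann["mitotic_count"] = rng.poisson(lam)
    rate_o = np.log(2.0) / cfg.median_survival_o
    rate = np.where(is_h, rate_o * cfg.hazard_ratio, rate_o)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(*cfg.censor_range, size=n)
    ann["survival_time"] = np.minimum(t_event, t_cens)
    ann["survival_event"] = (t_event <= t_cens).astype(int)

    truth = TruthBundle(
        true_group_labels=labels,
        true_de_genes=[genes[i] for i in sorted(de_idx)],
        true_module_partition=partition,
    )
    return matrix, ann, truth


# ---------------------------------------------------------------------------
# miRNA cohort with anti-correlated targets
# ---------------------------------------------------------------------------

def _nb_counts(rng, mean, dispersion):
    """Negative-binomial counts with gamma-Poisson parametrization."""
    mean = np.clip(mean, 1e-9, None)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def gen_mirna_cohort(cfg: SimConfig):
    """Mature-miRNA counts, target-gene expression and an interaction DB.

    A subset of precursors is differentially expressed with |log2FC| =
    ``mirna_lfc``; for each true interaction the target gene's log
    expression tracks the negative of its precursor's log2-CPM at pooled
    Pearson correlation ``interaction_pcc``. The database lists all true
    pairs plus decoys against non-differential background genes. A mapping
    with two mature forms for a fraction of precursors and an all-zero
    mature miRNA are included. Returns (counts, gene_expr, db, mapping,
    truth); ``db`` has columns pre_mirna_id/gene_id/source.
    """
    rng = _rng(cfg, _SALT_MIRNA)
    world = _world_rng(cfg, _SALT_MIRNA)
    n_h, n_o = cfg.n_samples_per_group
    n = n_h + n_o
    samples = [f"P{i:03d}" for i in range(1, n + 1)]
    labels = pd.Series(["h"] * n_h + ["o"] * n_o, index=samples, name="group")

    # precursors and mature forms
    n_pre = cfg.n_mirnas
    pres = [f"pre-mir-{i:04d}" for i in range(1, n_pre + 1)]
    mature, mapping = [], {}
    for i, pre in enumerate(pres):
        arms = ("-5p", "-3p") if world.random() < cfg.two_mature_fraction else ("-5p",)
        for arm in arms:
            mid = pre.replace("pre-", "miR-") + arm
            mature.append(mid)
            mapping[mid] = pre
    mapping = pd.Series(mapping, name="pre_mirna_id")

    if cfg.n_mirna_de > n_pre:
        raise ValueError("n_mirna_de exceeds n_mirnas")
    de_pres = list(world.choice(pres, size=cfg.n_mirna_de, replace=False))
    de_sign = {p: (1.0 if i % 2 == 0 else -1.0) for i, p in enumerate(de_pres)}

    base_mean = pd.Series(
        np.exp(world.normal(np.log(200.0), 1.2, size=len(mature))), index=mature
    )
    counts = np.zeros((len(mature), n), dtype=int)
    for i, mid in enumerate(mature):
        mu = np.full(n, base_mean[mid])
        pre = mapping[mid]
        if pre in de_sign:
            mu[:n_h] *= 2.0 ** (de_sign[pre] * cfg.mirna_lfc)
        counts[i] = _nb_counts(rng, mu, cfg.mirna_dispersion)
    counts = pd.DataFrame(counts, index=mature, columns=samples)
    counts.loc["miR-zero-5p"] = 0  # survives generation, removed by expression filter
    mapping.loc["miR-zero-5p"] = "pre-mir-zero"

    # precursor log2-CPM drives the targets
    lib = counts.sum(axis=0).astype(float)
    log_cpm = np.log2(counts.div(lib, axis=1) * 1e6 + 0.5)
    pre_log = log_cpm.groupby(mapping.reindex(log_cpm.index)).mean()

    if cfg.n_true_interactions > len(de_pres):
        raise ValueError("n_true_interactions exceeds the number of DE precursors")
    true_pres = de_pres[: cfg.n_true_interactions]
    target_genes = [f"T{i:04d}" for i in range(1, cfg.n_true_interactions + 1)]
    rho = abs(cfg.interaction_pcc)
    sd_g = 1.5
    rows = {}
    for gene, pre in zip(target_genes, true_pres):
        m = pre_log.loc[pre].to_numpy()
        z = (m - m.mean()) / m.std()
        eps = rng.normal(0.0, 1.0, size=n)
        rows[gene] = 9.0 - sd_g * (rho * z + np.sqrt(1 - rho**2) * eps)
    bg_genes = [f"B{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    for gene in bg_genes:
        rows[gene] = rng.normal(8.0, 1.0, size=n) + rng.normal(0.0, 0.3)
    gene_expr = pd.DataFrame.from_dict(rows, orient="index", columns=samples)

    sources = ("db1", "db2", "both")
    db_rows = [
        {"pre_mirna_id": pre, "gene_id": gene, "source": sources[world.integers(3)]}
        for gene, pre in zip(target_genes, true_pres)
    ]
    seen = {(r["pre_mirna_id"], r["gene_id"]) for r in db_rows}
    while len(db_rows) < cfg.n_true_interactions + cfg.n_decoys:
        pair = (pres[world.integers(n_pre)], bg_genes[world.integers(len(bg_genes))])
        if pair in seen:
            continue
        seen.add(pair)
        db_rows.append(
            {"pre_mirna_id": pair[0], "gene_id": pair[1], "source": sources[world.integers(3)]}
        )
    db = pd.DataFrame(db_rows)

    truth = TruthBundle(
        true_group_labels=labels,
        true_interactions=list(zip(true_pres, target_genes)),
    )
    return counts, gene_expr, db, mapping, truth


# ---------------------------------------------------------------------------
# copy-number cohort on a toy genome
# ---------------------------------------------------------------------------

_CHROM_LEN = 1_000_000
_N_BANDS = 10
_GENE_LEN = 1_000
_GENE_SPACING = 4_000


def toy_genome():
    """Gene model and cytoband map of the 2 x 1 Mb toy genome.

    10 cytobands of 100 kb per chromosome; 250 genes of 1 kb per
    chromosome, one every 4 kb; BED half-open 0-based.
    """
    genes, bands = [], []
    gid = 0
    for chrom in ("chr1", "chr2"):
        band_len = _CHROM_LEN // _N_BANDS
        for b in range(_N_BANDS):
            bands.append(
                {"chrom": chrom, "start": b * band_len, "end": (b + 1) * band_len,
                 "band_id": f"{chrom}.b{b + 1:02d}"}
            )
        pos = 1_000
        while pos + _GENE_LEN <= _CHROM_LEN:
            gid += 1
            genes.append(
                {"chrom": chrom, "start": pos, "end": pos + _GENE_LEN,
                 "gene_id": f"CN{gid:04d}"}
            )
            pos += _GENE_SPACING
    return pd.DataFrame(genes), pd.DataFrame(bands)


def _complement_intervals(intervals, chrom_len):
    """Gaps of the union of [start, end) intervals within [0, chrom_len)."""
    out, cur = [], 0
    for s, e in sorted((max(0, s), min(chrom_len, e)) for s, e in intervals):
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < chrom_len:
        out.append((cur, chrom_len))
    return out


def gen_cnv_cohort(cfg: SimConfig):
    """Per-patient copy-number segments with group-enriched altered bands.

    Each patient's genome is partitioned into CN=2 baseline and altered
    segments: balanced random noise alterations plus, per configured
    enriched band, a whole-band loss (CN 1) or gain (CN 3/6) drawn with a
    higher rate in group h. Deliberate artifacts: CN=128 segments, one
    patient with a coverage gap (missing genes) and a gene straddling a
    CN 1 / CN 3 boundary. Returns (segments, gene_model, cytobands, truth).
    """
    rng = _rng(cfg, _SALT_CNV)
    genes, bands = toy_genome()
    n_h, n_o = cfg.n_patients_per_group
    patients = [f"LMS{i:02d}" for i in range(1, n_h + n_o + 1)]
    labels = pd.Series(["h"] * n_h + ["o"] * n_o, index=patients, name="group")
    band_lookup = bands.set_index("band_id")

    noise_cns = np.array([0, 1, 1, 3, 3, 6])
    recs = []
    for pi, patient in enumerate(patients):
        altered = {"chr1": [], "chr2": []}

        for band_id, (direction, rate_h, rate_o) in sorted(cfg.enriched_bands.items()):
            rate = rate_h if labels[patient] == "h" else rate_o
            if rng.random() < rate:
                row = band_lookup.loc[band_id]
                cn = 1 if direction == "loss" else int(rng.choice([3, 6]))
                altered[row.chrom].append((int(row.start), int(row.end), cn))

        for _ in range(cfg.n_segments):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            length = int(rng.integers(10_000, 80_000))
            start = int(rng.integers(0, _CHROM_LEN - length))
            cn = int(noise_cns[rng.integers(len(noise_cns))])
            altered[chrom].append((start, start + length, cn))

        if pi == 0:
            # gene straddling a CN 1 / CN 3 boundary (exercises the min-CN rule)
            g = genes.iloc[100]
            mid = int((g.start + g.end) // 2)
            altered[g.chrom].append((int(g.start) - 500, mid, 1))
            altered[g.chrom].append((mid, int(g.end) + 500, 3))
        if pi in (1, n_h + 1):
            altered["chr2"].append((450_000, 480_000, 128))  # artifact segment

        gap = (900_000, _CHROM_LEN) if pi == n_h else None  # missing-gene patient
        for chrom in ("chr1", "chr2"):
            ivs = [(s, e) for s, e, _cn in altered[chrom]]
            if gap and chrom == "chr2":
                ivs.append(gap)
            for s, e in _complement_intervals(ivs, _CHROM_LEN):
                recs.append((patient, chrom, s, e, 2))
            for s, e, cn in altered[chrom]:
                recs.append((patient, chrom, s, e, cn))

    segs = pd.DataFrame(
        recs, columns=["patient_id", "chrom", "start", "end", "copy_number"]
    ).sort_values(["patient_id", "chrom", "start"], kind="mergesort").reset_index(drop=True)
    truth = TruthBundle(
        true_group_labels=labels,
        true_enriched_bands={b: d for b, (d, _, _) in cfg.enriched_bands.items()},
    )
    return segs, genes, bands, truth


# ---------------------------------------------------------------------------
# somatic variants from signature mixtures
# ---------------------------------------------------------------------------

def make_signature_catalog(n_signatures: int = 3, seed: int = 0) -> pd.DataFrame:
    """Synthetic catalog of dissimilar trinucleotide-context signatures.

    Each signature concentrates its mass on the 16 contexts of two
    substitution classes (Dirichlet within the block, a small floor
    elsewhere), so distinct signatures are nearly orthogonal
    (pairwise cosine << 0.75). Columns sum to one.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    background = rng.dirichlet(np.full(96, 8.0))  # broad mass shared by all
    sigs = {}
    for k in range(n_signatures):
        peak = np.zeros(96)
        blocks = [(2 * k) % 6, (2 * k + 1) % 6]
        for b in blocks:
            peak[b * 16 : (b + 1) * 16] = rng.dirichlet(np.full(16, 0.8)) * 0.5
        prob = 0.65 * background + 0.35 * peak / peak.sum()
        prob /= prob.sum()
        sigs[f"SBS_S{k + 1}"] = prob
    return pd.DataFrame(sigs, index=CONTEXTS_96)


_FAIL_MODES = (
    "t_depth", "n_depth", "t_af", "n_af", "pop_af", "coding", "synonymous", "rna_depth",
)


def gen_variant_cohort(cfg: SimConfig):
    """Somatic SNV table drawn from signature mixtures, with filter traps.

    Context counts follow the per-patient ``signature_mixture`` over the
    synthetic catalog. A ``variant_pass_fraction`` of records passes the
    somatic filter; the rest each fail exactly one rule (low tumor/normal
    depth, low tumor AF, normal contamination, common population allele,
    non-coding, synonymous, or poor RNA coverage), cycling through the
    failure modes. Returns (variant_table, catalog, ref_contexts, truth).
    """
    rng = _rng(cfg, _SALT_VARIANT)
    # the catalog is external reference knowledge: fixed by the world seed
    catalog = make_signature_catalog(cfg.n_signatures, seed=cfg.world_seed)
    n_h, n_o = cfg.n_patients_per_group
    patients = [f"LMS{i:02d}" for i in range(1, n_h + n_o + 1)]
    labels = pd.Series(["h"] * n_h + ["o"] * n_o, index=patients, name="group")

    mix = np.atleast_2d(np.asarray(cfg.signature_mixture, dtype=float))
    if mix.shape[0] == 1:
        mix = np.repeat(mix, len(patients), axis=0)
    if mix.shape != (len(patients), catalog.shape[1]):
        raise ValueError("signature_mixture must be one simplex row or one per patient")

    cat = catalog.to_numpy()
    recs = []
    contexts = {}
    fail_cycle = 0
    used_pos = set()
    for pi, patient in enumerate(patients):
        probs = cat @ mix[pi]
        ctx_idx = rng.choice(96, size=cfg.mutations_per_patient, p=probs / probs.sum())
        for j in ctx_idx:
            ctx = CONTEXTS_96[j]
            five, ref, alt, three = ctx[0], ctx[2], ctx[4], ctx[6]
            tri = five + ref + three
            while True:
                chrom = "chr1" if rng.random() < 0.5 else "chr2"
                pos = int(rng.integers(2, _CHROM_LEN - 2))
                if (chrom, pos) not in used_pos:
                    used_pos.add((chrom, pos))
                    break
            if rng.random() < 0.5:  # record on the purine strand
                tri = _revcomp(tri)
                ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            contexts[(chrom, pos)] = tri
            rec = {
                "patient_id": patient, "chrom": chrom, "pos": pos,
                "ref": ref, "alt": alt,
                "gene": f"CN{int(rng.integers(1, 499)):04d}",
                "class": "missense",
                "t_depth": int(rng.integers(20, 120)), "n_depth": int(rng.integers(10, 60)),
                "t_af": float(np.round(rng.uniform(0.3, 0.95), 3)), "n_af": 0.0,
                "pop_af": 0.0, "coding": True, "synonymous": False,
                "rna_depth": float(rng.integers(5, 80)),
            }
            if rng.random() > cfg.variant_pass_fraction:
                mode = _FAIL_MODES[fail_cycle % len(_FAIL_MODES)]
                fail_cycle += 1
                if mode == "t_depth":
                    rec["t_depth"] = 13
                elif mode == "n_depth":
                    rec["n_depth"] = 5
                elif mode == "t_af":
                    rec["t_af"] = 0.29
                elif mode == "n_af":
                    rec["n_af"] = 0.05
                elif mode == "pop_af":
                    rec["pop_af"] = 0.002
                elif mode == "coding":
                    rec["coding"] = False
                elif mode == "synonymous":
                    rec["synonymous"] = True
                elif mode == "rna_depth":
                    rec["rna_depth"] = 4.0
                rec["fails"] = mode
            else:
                rec["fails"] = ""
            recs.append(rec)
    table = pd.DataFrame(recs)
    exposures = pd.DataFrame(
        (mix * cfg.mutations_per_patient).T, index=catalog.columns, columns=patients
    )
    truth = TruthBundle(true_group_labels=labels, true_signature_exposures=exposures)
    return table, catalog, contexts, truth


# ---------------------------------------------------------------------------
# alteration scenarios (per-gene aggregation fixtures)
# ---------------------------------------------------------------------------

def gen_alteration_scenario(scenario: dict, group_sizes: dict, seed: int = 0) -> pd.DataFrame:
    """Per-patient alteration records matching prescribed per-group counts.

    ``scenario`` maps gene -> group -> {"mutation": k, "SV": k, "loss": k,
    "total": k}; ``group_sizes`` maps group -> patient count. Patients are
    assigned so that exactly ``total`` distinct patients in the group carry
    at least one alteration of the gene while each category reaches its
    count (a patient may carry several categories). Mutation records are
    emitted with class "missense". Returns a (patient_id, gene, class)
    table consumable by ``variants.aggregate_alterations``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 131]))
    patients = {
        g: [f"{g}{i:02d}" for i in range(1, n + 1)] for g, n in group_sizes.items()
    }
    class_of = {"mutation": "missense", "SV": "SV", "loss": "loss"}
    rows = []
    for gene, per_group in scenario.items():
        for group, counts in per_group.items():
            pool = list(patients[group])
            rng.shuffle(pool)
            cats = {c: counts.get(c, 0) for c in ("mutation", "SV", "loss")}
            total = counts.get("total", 0)
            if total > len(pool) or max(cats.values(), default=0) > total:
                raise ValueError(f"infeasible counts for {gene}/{group}")
            if sum(cats.values()) < total:
                raise ValueError(f"category counts below total for {gene}/{group}")
            covered: list = []
            uncovered = list(pool)
            for cat_name, cnt in sorted(cats.items(), key=lambda kv: -kv[1]):
                newly = min(cnt, max(0, total - len(covered)))
                chosen = uncovered[:newly]
                uncovered = uncovered[newly:]
                covered.extend(chosen)
                extra = cnt - newly
                if extra > len(covered) - newly:
                    raise ValueError(f"cannot overlap categories for {gene}/{group}")
                chosen = chosen + [p for p in covered if p not in chosen][:extra]
                for p in chosen:
                    rows.append({"patient_id": p, "gene": gene, "class": class_of[cat_name]})
    return pd.DataFrame(rows)
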