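# Methods

This note records the models, numerical conventions and design choices
behind `lmsubtype`, and what the synthetic-data tests do and do not
establish.

## Cross-platform harmonization

Two genes-x-samples log2 matrices measured on different platforms are
merged in three steps. (1) *Gene selection*: over the samples present on
both platforms, the full cross-correlation matrix C[g, h] =
ρ(a_g, b_h) is computed; gene g is kept when its self-correlation
C[g, g] exceeds 0.8, or when it beats every cross-correlation in both its
row and its column ("best reciprocal" — the weaker clause rescues genes
whose absolute reproducibility is modest but which are still each other's
unambiguous counterparts). Requiring best-reciprocal in both directions
rather than one is a genuine open choice; both are available via
`both_directions`. Genes measured at constant level on either platform
have undefined correlation and are excluded with a warning. (2) *Quantile
normalization*, per experiment and again after column-wise merging. The
reference distribution is the mean of the per-column sorted vectors; tied
input values receive the mean of the reference values at their tied ranks,
so the map is well defined and idempotent. (3) *Median alignment*: per
gene, each experiment's median is subtracted and the mean of the two
experiment medians is added back; afterwards the per-gene medians of the
two platforms agree exactly, by construction.

## Co-expression modules and sample clustering

Genes with sample variance > 2 (log2 scale, ddof = 1) are nodes; edges
join pairs with Pearson r > 0.7. Communities come from Girvan-Newman
edge-betweenness removal; among the nested partitions (starting from the
connected components) the one maximizing Newman modularity is kept, with
ties broken toward the first-encountered (coarsest) partition so the
result is deterministic. Communities with at least 5 genes are flagged as
modules.

Sample clustering mirrors the HCPC procedure: PCA on the feature
submatrix (samples as observations, centered, unscaled), retaining the
smallest number of components reaching 95% explained variance; Ward
linkage on the component scores; the tree cut at the number of clusters
k (2 ≤ k ≤ 10) maximizing the ratio of successive merge heights (the
largest relative loss of within-cluster inertia); one k-means pass seeded
at the cluster means consolidates the labels. Clustering features default
to the member genes of the flagged modules; per-module mean scores are a
caller-side alternative (pass the averaged matrix).

## Signature and centroid classifier

Differential expression uses the two-tailed Welch t statistic with
Satterthwaite degrees of freedom, oriented h minus o, with Holm step-down
family-wise correction across all tested genes; genes with zero variance
in both groups are reported as t = 0, p = 1. Centroids are per-gene group
means over the signature genes (median optional). A sample's distance to
a centroid is 1 − Spearman ρ over the shared signature genes (average
ranks on ties), bounded in [0, 2] and invariant to any strictly monotone
transform of the sample profile. Threshold mode assigns the nearest group
when the minimum distance is below 0.6, else "unclassified". GMM mode
fits 1-D Gaussian mixtures (1..3 components; tied and free variances) to
the h-distance distribution, selects by BIC, and labels the lowest-mean
component h, the highest-mean o, intermediates unclassified; with a
single selected component it falls back to the threshold rule. The two
modes are deliberately not reconciled — they answer slightly different
questions (fixed confidence radius vs data-driven density split) — and
threshold mode is the default. "High expression" of a gene means strictly
above the third quartile (linear-interpolation quantile) of the flattened
full matrix, computed per platform when a platform tag is supplied.

## Clinical statistics

Fisher's exact test is computed by direct hypergeometric enumeration of
the table support; the two-sided p sums all tables whose point
probability is at most the observed one within a 1 + 1e-7 relative
tolerance (the convention of the standard R/scipy implementations, which
protects exact ties against floating-point noise). Wilcoxon rank-sum
comparisons use exact enumeration for tie-free samples of at most 50 per
group, otherwise the normal approximation with tie correction.
Transcriptional homogeneity compares the per-gene within-group variance
vectors of the two subtypes by rank test — per-gene variance (not
per-patient) is the reading that yields a many-observation rank test.
Survival uses the product-limit estimator and the two-group log-rank test
(via lifelines); curves are emitted as (time, at-risk, survival) step
functions with S(0) = 1.

## miRNA normalization, DE and integration

Counts are normalized to CPM with TMM scale factors (M-trim 30%, A-trim
5%, precision weights, reference = library whose upper quartile is
closest to the mean; factors rescaled to geometric mean 1). Because the
precision weights use raw counts, TMM factors retain a sub-percent
dependence on sequencing depth; plain CPM is exactly depth-invariant.
Differential expression is Welch's t on log2(CPM + 0.5) with Holm
correction — a deliberate stand-in for the negative-binomial
quasi-likelihood fit: the published selection is driven by its three
cut-offs (|log2FC| > 1, adjusted p < 0.01, median normalized count > 1 in
at least one group — median CPM chosen as the normalized scale), not by
the test family, and the DE interface isolates the substitution so a
moderated test can be swapped in. Precursor expression is the arithmetic
mean of the mapped mature forms on the normalized scale, which preserves
a fold change shared by all mature forms. Integration keeps
database-supported pairs whose miRNA and gene both pass the DE filters,
tests Pearson correlation one-sided for negativity across shared samples,
adjusts by Benjamini-Hochberg across all candidate pairs (Holm optional),
and retains adjusted p < 0.01 with r < 0. Cross-cohort concordance is the
R² of an OLS fit between two log-fold-change vectors.

## Copy number

Intervals are BED: 0-based, half-open, for segments, genes and cytobands
alike. A gene's copy number per patient is the minimum over overlapping
segments (the conservative choice when a gene straddles a breakpoint);
CN = 128 segments are caller artifacts and treated as absent; genes
missing in more than a third of patients are dropped. Event classes are
0 homdel, 1 hetdel, 2 normal, 3-5 gain, ≥ 6 amp. "Gain of four copies or
more" is ambiguous between CN ≥ 4 and CN ≥ 6; CN ≥ 6 is chosen for
consistency with the in-situ-hybridization amplification rule, and the
boundary is configurable (`event_map`). Penetrance divides event counts
by non-missing patients per group. Enrichment is one-tailed toward group
h (swap labels for the other direction): per gene on merged losses
(homdel + hetdel) and gains (gain + amp) at p < 0.01; per cytoband on the
significant-gene sets, Holm-corrected across bands within each event
type, p < 0.01, keeping the most significant event per band. Genes are
assigned to the band containing their start position.

## Somatic variants and signatures

The somatic filter is a conjunction of depth, allele-fraction, population
frequency and annotation rules; "normal AF = 0" is enforced exactly, with
`max_n_af` available for noisy assays. Alteration summaries count a
patient once per category (mutation classes, SV, loss) and once in
"total"; percentages are count / group size, rounded half away from zero
to one decimal. Mutation classes are taken as labels from the input table
(annotation engines are out of scope). The 96-context order is
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G) with 5'/3' flanks in
ACGT order, on the pyrimidine strand; purine-reference SNVs are
reverse-complemented. Signature refitting selects, per patient, catalog
signatures with cosine similarity > 0.75 to the observed profile and
fits exposures by non-negative least squares on the counts; the
reconstruction cosine is reported, and patients with no qualifying
signature are flagged rather than force-fitted. Tumor mutation burden is
somatic count divided by genome megabases.

## Synthetic data: the stated world

All generators draw from two seeded streams. The *world* stream
(`world_seed`, default 2023) fixes what the disease is: per-gene baseline
means, which genes are differential and in which direction, module
membership, the miRNA target structure and decoy database, and the
signature catalog. The *cohort* stream (`seed`) draws patients from that
world. Two cohorts with different seeds therefore share biology — which
is what lets a classifier trained on one draw transfer to another, and
what makes cross-cohort log-fold-change concordance meaningful.

Defaults state the cohort conditions the analyses were designed around:
42 vs 56 samples (expression), 87 dual-platform samples, 28 vs 11
genomic patients; DE fraction 0.18 at effect size 2 (log2); group-o noise
variance 1.5x group h; clinical reference-level probabilities
(intra-abdominal 0.60/0.07, female 0.76/0.48, low grade 0.58/0.24, well
differentiated 0.88/0.24), mitotic-count means 17/24.5; exponential
survival with median 60 months in group o, hazard ratio 2 for h, and
uniform administrative censoring at 36-180 months (long follow-up typical
of sarcoma cohorts; it keeps the event fraction near 0.8, consistent with
the power the survival tests assume). Expression noise is Normal on the
log2 scale; miRNA counts are negative binomial (dispersion 10) with
anti-correlated targets built by mixing the standardized precursor
profile into the target gene at the configured correlation; the copy
number generator partitions a 2 x 1 Mb toy genome (10 cytobands per
chromosome, 1 kb genes every 4 kb) into CN = 2 baseline and altered
segments, with one loss-enriched band (80% of h vs 20% of o) over sparse
balanced noise (6 segments of 10-80 kb per patient) plus deliberate
artifacts (CN = 128 segments, a coverage-gap patient, a gene straddling a
CN 1/CN 3 breakpoint). Synthetic mutational signatures combine a shared
broad background (weight 0.65) with disjoint substitution-class peaks, so
that distinct signatures have pairwise cosine ≈ 0.53 — similar enough
that a 0.6/0.4 mixture passes the 0.75 candidate gate for both
components, dissimilar enough that refitting recovers proportions within
±0.05 at 5000 mutations.

What a green test establishes: that each stage recovers the structure it
assumes, at the published thresholds, under favorable noise. What it does
not: platform effects here are additive and Gaussian (no intensity-
dependent dye bias), counts have a single dispersion, copy-number noise
is group-balanced by construction, clinical features are independent
given the group, and no batch confounding or tumor purity variation is
simulated. Recovery on this world is a necessary, not sufficient,
condition for performance on real cohorts.

## Known limitations

- Girvan-Newman is O(m²n)-ish and intended for the post-filter graph
  sizes here (hundreds of nodes), not genome-wide graphs.
- The Welch-on-log-CPM stand-in loses power versus a moderated
  count-model test at very small group sizes.
- The GMM mode's single-component fallback and the 0.6 threshold are not
  reconciled; callers choosing gmm mode should inspect the component
  structure.
- Percentages in alteration summaries use half-away-from-zero rounding;
  published tables occasionally truncate instead, so 1-decimal agreement
  with historical tables can differ in the last digit for ties.
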