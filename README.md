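# lmsubtype

Multi-omic subtyping of leiomyosarcoma-style tumor cohorts.

Leiomyosarcomas (LMS) are aggressive smooth-muscle tumors that split into a
transcriptionally homogeneous subtype (**hLMS** — typically intra-abdominal,
well differentiated, with a vascular-smooth-muscle expression program and a
worse metastatic outcome) and a heterogeneous remainder (**oLMS**). This
package re-implements, as a tested and reusable library plus CLI, the
analysis chain used to define and characterize such subtypes:

- **harmonize** — merge expression matrices from two microarray platforms:
  keep genes whose cross-platform self-correlation exceeds 0.8 (or is best
  reciprocal), quantile-normalize per experiment and after merging, then
  per-gene median-center each experiment and restore the mean of the
  experiment medians.
- **coexpression** — build the gene co-expression graph (variance > 2,
  Pearson r > 0.7), detect modules by Girvan-Newman edge betweenness cut at
  maximum modularity, and cluster samples HCPC-style (PCA to 95% variance,
  Ward on scores, inertia-gap cut, k-means consolidation).
- **classifier** — per-gene Welch *t* tests with Holm correction define the
  subtype signature; group centroids are per-gene means and samples are
  assigned by distance d(x, c) = 1 − ρ_Spearman(x, c), either with the 0.6
  cutoff (unclassified above it) or by a BIC-selected 1-D Gaussian mixture
  on the distance distribution.
- **clinstats** — two-sided Fisher exact tests (one level vs rest) for
  clinical categories, Wilcoxon rank-sum for continuous features, per-gene
  within-group variance comparison for transcriptional homogeneity, and
  Kaplan-Meier curves with the two-group log-rank test.
- **mirna** — miRNA expression filtering (total count > 10, ≥ 5 reads in one
  sample), TMM/CPM normalization, Welch DE on log2(CPM + 0.5), precursor
  summarization by averaging mature forms, and miRNA-target integration:
  keep database-supported pairs with |log2FC| > 1 and adjusted p < 0.01 on
  both sides plus significant Pearson anti-correlation (BH-adjusted
  p < 0.01).
- **cnv** — project copy-number segments onto genes (minimum CN across
  overlapping segments, CN = 128 artifacts discarded, genes missing in
  > 1/3 of patients dropped), classify events (0 homdel, 1 hetdel, 2
  normal, 3–5 gain, ≥ 6 amp), compute per-group penetrance, and test
  group and cytoband enrichment with one-tailed Fisher tests (Holm across
  bands).
- **variants** — somatic SNV filtering (tumor depth ≥ 14, normal ≥ 8,
  tumor AF ≥ 0.3, normal AF = 0, population AF < 0.1%, coding,
  non-synonymous), per-gene alteration summaries with per-group
  percentages, biallelic one- vs two-mechanism contrast, tumor mutation
  burden, 96-trinucleotide context matrices, and signature refitting by
  non-negative least squares over catalog signatures with cosine > 0.75.
- **synthetic** — generators for every input above with known ground truth
  (subtype labels, DE genes, modules, interactions, enriched bands,
  signature exposures), driven by a single seed; the test suite and the
  acceptance script run entirely on these.

## Worked example

Train the centroid classifier on one simulated cohort and classify an
independent draw from the same disease world:

```python
from lmsubtype import synthetic, classifier, clinstats

cfg = synthetic.SimConfig(seed=1)
expr, ann, truth = synthetic.gen_subtype_cohort(cfg)
de = classifier.welch_de(expr, ann.group)
signature = list(de.index[(de.p_holm < 0.01) & (de.log2fc.abs() > 1)])
model = classifier.build_centroids(expr, ann.group, signature)

expr2, ann2, _ = synthetic.gen_subtype_cohort(cfg.replace(seed=2))
calls = classifier.classify_samples(expr2, model)

print(f"signature size: {len(signature)}")
print(f"assignments: {(calls.label == 'h').sum()} h / {(calls.label == 'o').sum()} o "
      f"/ {(calls.label == 'unclassified').sum()} unclassified")
print(f"agreement with simulated labels: {(calls.label == ann2.group).mean():.3f}")
vh, vo, p = clinstats.homogeneity_test(expr2, calls.label)
print(f"median per-gene variance: h={vh:.2f}, o={vo:.2f} (Wilcoxon p={p:.2e})")
_, p_km = clinstats.km_logrank(ann2.survival_time, ann2.survival_event, calls.label)
print(f"metastasis-free-survival log-rank p={p_km:.4f}")
```

Output:

```
signature size: 360
assignments: 42 h / 56 o / 0 unclassified
agreement with simulated labels: 1.000
median per-gene variance: h=0.64, o=0.97 (Wilcoxon p=0.00e+00)
metastasis-free-survival log-rank p=0.0140
```

i.e. the 360-gene signature transfers perfectly to the independent cohort;
the h group is transcriptionally more homogeneous (the generator's
variance ratio is 1.5), and the survival contrast reflects the simulated
hazard ratio of 2.

The same stages are available from the shell:

```sh
lmsubtype simulate --outdir data --seed 1
lmsubtype harmonize --a data/platform_a.tsv --b data/platform_b.tsv \
    --shared data/shared_samples.txt --out data/merged.tsv
lmsubtype modules detect --expr data/expression.tsv --out data/modules.gmt
lmsubtype classify train ... && lmsubtype classify run ...
lmsubtype clinstats enrich --ann data/annotation.tsv --out data/table1.tsv
lmsubtype cnv analyze --segments data/segments.bed --genes data/genes.bed \
    --bands data/cytobands.bed --labels data/patient_labels.tsv --outdir data/cnv
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates every synthetic cohort from the given seed, runs the complete
pipeline (harmonization, module detection, classifier training and
transfer, clinical/survival enrichment, miRNA network integration,
copy-number enrichment, somatic filtering and signature refitting), prints
a per-stage summary, and writes the results JSON.
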