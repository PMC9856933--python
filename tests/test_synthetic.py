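"""Generator contracts: determinism, stated structure, truth consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lmsubtype import synthetic
from lmsubtype.clinstats import km_logrank
from lmsubtype.synthetic import SimConfig


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_genes": 10},
            {"de_fraction": 0.0},
            {"de_fraction": 1.0},
            {"effect_size": -1.0},
            {"variance_ratio_o_vs_h": 0.5},
            {"interaction_pcc": 0.2},
            {"n_samples_per_group": (2, 30)},
            {"n_shared_samples": 2},
            {"signature_mixture": (0.5, 0.2, 0.1)},
        ],
    )
    def test_invalid_configuration_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestDeterminism:
    def test_all_generators_reproduce_exactly(self):
        cfg = SimConfig(
            seed=77, n_genes=120, n_samples_per_group=(8, 8), n_shared_samples=10,
            n_mirnas=40, n_mirna_de=12, n_true_interactions=8, n_decoys=20,
            n_background_genes=30, n_modules=2, module_size=5,
            n_patients_per_group=(4, 3), mutations_per_patient=100,
        )
        for gen in (
            synthetic.gen_dual_platform_cohort,
            synthetic.gen_subtype_cohort,
            synthetic.gen_mirna_cohort,
            synthetic.gen_cnv_cohort,
            synthetic.gen_variant_cohort,
        ):
            first = gen(cfg)
            second = gen(cfg)
            for x, y in zip(first, second):
                if isinstance(x, pd.DataFrame):
                    pd.testing.assert_frame_equal(x, y)
                elif isinstance(x, pd.Series):
                    pd.testing.assert_series_equal(x, y)
                elif isinstance(x, dict):
                    assert x == y
                elif isinstance(x, list):
                    assert x == y


class TestDualPlatform:
    def test_truth_flags_concordant_construction(self):
        cfg = SimConfig(seed=1, n_genes=100, n_concordant=80)
        a, b, shared, truth = synthetic.gen_dual_platform_cohort(cfg)
        assert len(truth.true_concordant_genes) == 80
        assert set(truth.true_concordant_genes) <= set(a.index) & set(b.index)
        assert list(a.columns) == shared and list(b.columns) == shared

    def test_noiseless_concordant_genes_correlate_perfectly(self):
        cfg = SimConfig(
            seed=2, n_genes=30, n_concordant=30, platform_shift_sd=0.0,
            measurement_noise_sd=0.0, n_shared_samples=20,
        )
        a, b, _, _ = synthetic.gen_dual_platform_cohort(cfg)
        for g in a.index:
            assert np.corrcoef(a.loc[g], b.loc[g])[0, 1] == pytest.approx(1.0)

    def test_platform_shift_is_additive_per_gene(self):
        cfg = SimConfig(
            seed=3, n_genes=30, n_concordant=30, platform_shift_sd=1.0,
            measurement_noise_sd=0.0, n_shared_samples=25,
        )
        a, b, _, _ = synthetic.gen_dual_platform_cohort(cfg)
        diff = (b - a).to_numpy()
        np.testing.assert_allclose(diff.std(axis=1), 0, atol=1e-12)  # constant per gene
        assert diff.mean(axis=1).std() > 0.3  # but varying across genes


class TestSubtypeCohort:
    def test_truth_entities_exist(self, subtype_cohort):
        m, ann, truth = subtype_cohort
        assert set(truth.true_de_genes) <= set(m.index)
        assert set(truth.true_group_labels.index) == set(m.columns)
        for genes in truth.true_module_partition.values():
            assert set(genes) <= set(m.index)

    def test_de_gene_count_follows_fraction(self):
        cfg = SimConfig(seed=4, n_genes=2000, de_fraction=0.1)
        _, _, truth = synthetic.gen_subtype_cohort(cfg)
        assert len(truth.true_de_genes) == 200

    def test_variance_ratio_realized(self):
        cfg = SimConfig(seed=5, variance_ratio_o_vs_h=2.0, n_samples_per_group=(40, 40))
        m, ann, _ = synthetic.gen_subtype_cohort(cfg)
        vh = m.loc[:, ann.group == "h"].var(axis=1, ddof=1).median()
        vo = m.loc[:, ann.group == "o"].var(axis=1, ddof=1).median()
        assert vo / vh == pytest.approx(2.0, rel=0.15)

    def test_survival_fields_wellformed(self, subtype_cohort):
        _, ann, _ = subtype_cohort
        assert (ann.survival_time > 0).all()
        assert set(ann.survival_event.unique()) <= {0, 1}
        assert set(ann.mitotic_count) == set(ann.mitotic_count.astype(int))

    def test_null_hazard_gives_uniform_logrank_p(self):
        """Under hazard ratio 1 the log-rank p is uniform across seeds."""
        ps = []
        for seed in range(500):
            cfg = SimConfig(
                seed=seed, n_genes=20, de_fraction=0.05, n_modules=0,
                n_samples_per_group=(20, 20), hazard_ratio=1.0,
            )
            _, ann, _ = synthetic.gen_subtype_cohort(cfg)
            _, p = km_logrank(ann.survival_time, ann.survival_event, ann.group)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_world_is_shared_across_cohort_draws(self):
        t1 = synthetic.gen_subtype_cohort(SimConfig(seed=1))[2]
        t2 = synthetic.gen_subtype_cohort(SimConfig(seed=2))[2]
        assert t1.true_de_genes == t2.true_de_genes
        assert t1.true_module_partition == t2.true_module_partition


class TestMirnaCohort:
    def test_db_size_and_truth_membership(self, mirna_cohort):
        counts, gene_expr, db, mapping, truth = mirna_cohort
        cfg_true, cfg_decoys = 50, 200
        assert len(db) == cfg_true + cfg_decoys
        pairs = set(zip(db.pre_mirna_id, db.gene_id))
        for pre, gene in truth.true_interactions:
            assert (pre, gene) in pairs
            assert gene in gene_expr.index
            assert (mapping == pre).any()

    def test_zero_count_mirna_included(self, mirna_cohort):
        counts = mirna_cohort[0]
        assert (counts.loc["miR-zero-5p"] == 0).all()

    def test_some_precursors_have_two_mature_forms(self, mirna_cohort):
        mapping = mirna_cohort[3]
        assert (mapping.value_counts() >= 2).any()

    def test_true_pairs_strongly_anticorrelated(self, mirna_cohort):
        """Target pcc -0.8: empirical pair correlation below -0.6 for at
        least 90% of the true pairs at n=40."""
        counts, gene_expr, db, mapping, truth = mirna_cohort
        lib = counts.sum(axis=0).astype(float)
        log_cpm = np.log2(counts.div(lib, axis=1) * 1e6 + 0.5)
        pre = log_cpm.groupby(mapping.reindex(log_cpm.index)).mean()
        rs = [
            np.corrcoef(pre.loc[p], gene_expr.loc[g])[0, 1]
            for p, g in truth.true_interactions
        ]
        assert np.mean(np.array(rs) < -0.6) >= 0.9

    def test_counts_are_nonnegative_integers(self, mirna_cohort):
        counts = mirna_cohort[0]
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)


class TestCnvCohort:
    def test_truth_bands_exist_and_deliberate_artifacts_present(self, cnv_cohort):
        segs, genes, bands, truth = cnv_cohort
        assert set(truth.true_enriched_bands) <= set(bands.band_id)
        assert (segs.copy_number == 128).any()  # artifact fixture
        assert (segs.start < segs.end).all()

    def test_enriched_band_rates_differ_by_group(self, cnv_cohort):
        segs, genes, bands, truth = cnv_cohort
        band = bands.set_index("band_id").loc["chr1.b03"]
        lab = truth.true_group_labels
        lost = {
            p: ((sub.chrom == band.chrom) & (sub.start <= band.start)
                & (sub.end >= band.end) & (sub.copy_number < 2)).any()
            for p, sub in segs.groupby("patient_id")
        }
        lost = pd.Series(lost)
        assert lost[lab == "h"].mean() > lost[lab == "o"].mean() + 0.3

    def test_straddling_gene_fixture_present(self, cnv_cohort):
        """First patient carries adjacent CN 1 / CN 3 segments inside one
        gene (the lowest-CN attribution fixture)."""
        segs, genes, bands, _ = cnv_cohort
        p1 = segs[segs.patient_id == "LMS01"]
        g = genes.iloc[100]
        over = p1[(p1.chrom == g.chrom) & (p1.start < g.end) & (p1.end > g.start)]
        assert {1, 3} <= set(over.copy_number)


class TestVariantCohort:
    def test_failure_fixtures_present(self):
        cfg = SimConfig(seed=6, n_patients_per_group=(2, 2), mutations_per_patient=200)
        vt, _, _, _ = synthetic.gen_variant_cohort(cfg)
        assert (vt.t_depth == 13).any()  # coverage-failure fixture
        assert set(vt.fails) > {""}

    def test_mixture_histogram_matches_analytic_expectation(self):
        """Sampled context histogram vs the analytic mixture: cosine >= 0.95
        at 1000 mutations per patient."""
        from lmsubtype.variants import context_matrix, cosine_similarity

        cfg = SimConfig(
            seed=8, n_patients_per_group=(2, 1), mutations_per_patient=1000,
            signature_mixture=(0.7, 0.3, 0.0), variant_pass_fraction=1.0,
        )
        vt, catalog, ctx, truth = synthetic.gen_variant_cohort(cfg)
        cm = context_matrix(vt, ctx)
        expected = catalog.to_numpy() @ np.array([0.7, 0.3, 0.0])
        for patient in cm.columns:
            assert cosine_similarity(cm[patient].to_numpy(), expected) >= 0.95

    def test_exposure_truth_recorded(self):
        cfg = SimConfig(seed=6, n_patients_per_group=(2, 1), mutations_per_patient=100)
        _, catalog, _, truth = synthetic.gen_variant_cohort(cfg)
        exp = truth.true_signature_exposures
        assert list(exp.index) == list(catalog.columns)
        np.testing.assert_allclose(exp.sum(axis=0), 100.0)


class TestAlterationScenario:
    def test_counts_reproduced_exactly(self):
        scenario = {"TP53": {"h": {"mutation": 17, "SV": 7, "loss": 25, "total": 28}}}
        recs = synthetic.gen_alteration_scenario(scenario, {"h": 28}, seed=0)
        by_class = recs.groupby("class").patient_id.nunique()
        assert by_class["missense"] == 17
        assert by_class["SV"] == 7
        assert by_class["loss"] == 25
        assert recs.patient_id.nunique() == 28

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_alteration_scenario(
                {"G": {"h": {"mutation": 1, "total": 5}}}, {"h": 10}, seed=0
            )
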