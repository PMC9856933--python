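"""Somatic filtering, alteration aggregation, TMB, contexts, signatures."""

import numpy as np
import pandas as pd
import pytest

from lmsubtype import synthetic
from lmsubtype.variants import (
    CONTEXTS_96,
    aggregate_alterations,
    biallelic_pattern,
    context_matrix,
    cosine_similarity,
    filter_somatic,
    fit_signatures,
    tmb,
)


def _variant(**kw):
    base = dict(
        patient_id="p1", chrom="chr1", pos=100, ref="C", alt="T", gene="TP53",
        class_="missense", t_depth=20, n_depth=10, t_af=0.4, n_af=0.0,
        pop_af=0.0, coding=True, synonymous=False, rna_depth=np.nan,
    )
    base.update(kw)
    base["class"] = base.pop("class_")
    return base


class TestFilterSomatic:
    def test_clean_record_kept(self):
        v = pd.DataFrame([_variant()])
        assert len(filter_somatic(v)) == 1

    @pytest.mark.parametrize(
        "field, value",
        [
            ("t_depth", 13),
            ("n_depth", 7),
            ("t_af", 0.29),
            ("n_af", 0.01),
            ("pop_af", 0.002),  # >= 0.1% in the population
            ("coding", False),
            ("synonymous", True),
            ("rna_depth", 4.0),
        ],
    )
    def test_each_rule_rejects(self, field, value):
        v = pd.DataFrame([_variant(**{field if field != "class" else "class_": value})])
        assert filter_somatic(v).empty

    @pytest.mark.parametrize(
        "field, value",
        [("t_depth", 14), ("n_depth", 8), ("t_af", 0.3), ("pop_af", 0.0009), ("rna_depth", 5.0)],
    )
    def test_boundary_values_kept(self, field, value):
        v = pd.DataFrame([_variant(**{field: value})])
        assert len(filter_somatic(v)) == 1

    def test_subset_and_idempotent(self):
        cfg = synthetic.SimConfig(seed=9, n_patients_per_group=(2, 1), mutations_per_patient=300)
        vt, *_ = synthetic.gen_variant_cohort(cfg)
        som = filter_somatic(vt)
        assert set(map(tuple, som[["chrom", "pos"]].to_numpy())) <= set(
            map(tuple, vt[["chrom", "pos"]].to_numpy())
        )
        pd.testing.assert_frame_equal(filter_somatic(som), som)
        # generator's failure labels agree with the filter
        assert set(som.fails) == {""}
        assert len(som) == (vt.fails == "").sum()


class TestAggregateAlterations:
    @staticmethod
    def _groups():
        pats = [f"h{i:02d}" for i in range(1, 29)] + [f"o{i:02d}" for i in range(1, 12)]
        return pd.Series(["h"] * 28 + ["o"] * 11, index=pats)

    def test_percentage_arithmetic(self):
        groups = self._groups()
        v = pd.DataFrame(
            [{"patient_id": f"h{i:02d}", "gene": "TP53", "class": "missense"}
             for i in range(1, 18)]
        )
        summary = aggregate_alterations(v, groups, ["TP53"])
        row = summary[(summary.group == "h") & (summary.category == "mutation")].iloc[0]
        assert row["count"] == 17 and row.percent == 60.7  # 17/28

    def test_patient_with_two_categories_counted_once_in_total(self):
        groups = self._groups()
        v = pd.DataFrame(
            [
                {"patient_id": "h01", "gene": "RB1", "class": "SV"},
                {"patient_id": "h01", "gene": "RB1", "class": "loss"},
            ]
        )
        summary = aggregate_alterations(v, groups, ["RB1"])
        total = summary[(summary.group == "h") & (summary.category == "total")].iloc[0]
        assert total["count"] == 1

    def test_orphan_patient_excluded_with_warning(self, caplog):
        groups = self._groups()
        v = pd.DataFrame([{"patient_id": "zz", "gene": "TP53", "class": "loss"}])
        with caplog.at_level("WARNING"):
            summary = aggregate_alterations(v, groups, ["TP53"])
        assert (summary["count"] == 0).all()

    def test_rounding_half_away_from_zero(self):
        groups = pd.Series(["h"] * 8, index=[f"h{i}" for i in range(8)])
        v = pd.DataFrame([{"patient_id": "h0", "gene": "G", "class": "loss"}])
        summary = aggregate_alterations(v, groups, ["G"])
        loss = summary[(summary.group == "h") & (summary.category == "loss")].iloc[0]
        assert loss.percent == 12.5  # 1/8 exactly


class TestBiallelic:
    @staticmethod
    def _statuses(rows):
        df = pd.DataFrame(rows, columns=["patient", "allele1", "allele2", "group"])
        statuses = df.set_index("patient")[["allele1", "allele2"]]
        groups = df.set_index("patient")["group"]
        return statuses, groups

    def test_classification_rules(self):
        statuses, groups = self._statuses(
            [
                ("p1", "L", "L", "h"),    # one mechanism
                ("p2", "MS", "L", "h"),   # two mechanisms
                ("p3", "WT", "MS", "h"),  # intact allele: excluded
                ("p4", "L", "L", "o"),
                ("p5", "FS", "L", "o"),
            ]
        )
        table, _ = biallelic_pattern(statuses, groups)
        assert table.loc["one_mechanism", "h"] == 1
        assert table.loc["two_mechanism", "h"] == 1
        assert table.to_numpy().sum() == 4  # p3 dropped

    def test_group_contrast_p_value(self):
        rows = (
            [(f"h{i}", "MS", "L", "h") for i in range(18)]
            + [(f"h{i+20}", "L", "L", "h") for i in range(10)]
            + [(f"o{i}", "FS", "L", "o") for i in range(2)]
            + [(f"o{i+20}", "L", "L", "o") for i in range(9)]
        )
        statuses, groups = self._statuses(rows)
        table, p = biallelic_pattern(statuses, groups)
        assert round(p, 2) == 0.01


class TestTMB:
    def test_per_megabase_arithmetic(self):
        v = pd.DataFrame({"patient_id": ["p1"] * 3000})
        assert tmb(v, 3e9).loc["p1"] == pytest.approx(1.0)

    def test_toy_genome_outlier_magnitude(self):
        v = pd.DataFrame({"patient_id": ["p1"] * 120})
        assert tmb(v, 1e6).loc["p1"] == pytest.approx(120.0)

    def test_no_variants(self):
        assert tmb(pd.DataFrame({"patient_id": []}), 1e6).empty

    def test_invalid_genome_length(self):
        with pytest.raises(ValueError):
            tmb(pd.DataFrame({"patient_id": ["p"]}), 0)


class TestContextMatrix:
    def test_purine_reference_reverse_complemented(self):
        v = pd.DataFrame([_variant(chrom="chr1", pos=5, ref="G", alt="T")])
        # reference-strand AGA centered on the G; pyrimidine strand: TCT
        cm = context_matrix(v, {("chr1", 5): "AGA"})
        assert cm.loc["T[C>A]T", "p1"] == 1
        assert cm.to_numpy().sum() == 1

    def test_column_sums_conserve_usable_snvs(self):
        cfg = synthetic.SimConfig(seed=2, n_patients_per_group=(2, 1), mutations_per_patient=400)
        vt, _, ctx, _ = synthetic.gen_variant_cohort(cfg)
        cm = context_matrix(vt, ctx)
        per_patient = vt.groupby("patient_id").size()
        assert (cm.sum(axis=0) == per_patient.reindex(cm.columns)).all()

    def test_mismatched_context_skipped(self, caplog):
        v = pd.DataFrame([_variant(pos=9)])
        with caplog.at_level("WARNING"):
            cm = context_matrix(v, {("chr1", 9): "AAA"})  # center != ref C
        assert cm.to_numpy().sum() == 0

    def test_pure_signature_sampling(self):
        """A patient drawn from one pure signature reproduces it (cosine
        >= 0.99 at 10^4 mutations)."""
        cfg = synthetic.SimConfig(
            seed=11, n_patients_per_group=(1, 1), mutations_per_patient=10_000,
            signature_mixture=(1.0, 0.0, 0.0), variant_pass_fraction=1.0,
        )
        vt, catalog, ctx, _ = synthetic.gen_variant_cohort(cfg)
        cm = context_matrix(vt, ctx)
        for patient in cm.columns:
            cos = cosine_similarity(cm[patient].to_numpy(), catalog.iloc[:, 0].to_numpy())
            assert cos >= 0.99


class TestFitSignatures:
    def test_pure_profile_exact_exposure(self):
        catalog = synthetic.make_signature_catalog(3, seed=0)
        counts = pd.DataFrame({"p1": catalog.iloc[:, 0] * 1000})
        exp, recon = fit_signatures(counts, catalog)
        assert exp.loc[catalog.columns[0], "p1"] == pytest.approx(1000, rel=1e-6)
        assert exp.drop(index=catalog.columns[0])["p1"].max() < 1e-6
        assert recon["p1"] == pytest.approx(1.0)

    def test_unrelated_profile_flagged(self, caplog):
        catalog = synthetic.make_signature_catalog(2, seed=0)
        # spike on the context where the catalog carries least mass
        spike = np.zeros(96)
        spike[int(catalog.sum(axis=1).to_numpy().argmin())] = 500
        counts = pd.DataFrame({"p1": spike}, index=CONTEXTS_96)
        with caplog.at_level("WARNING"):
            exp, recon = fit_signatures(counts, catalog)
        assert exp["p1"].sum() == 0 and np.isnan(recon["p1"])

    def test_nnls_beats_grid_search(self):
        """NNLS residual is minimal against a coarse non-negative grid."""
        catalog = synthetic.make_signature_catalog(2, seed=1)
        rng = np.random.default_rng(0)
        y = 600 * catalog.iloc[:, 0] + 400 * catalog.iloc[:, 1]
        y = y + rng.normal(0, 1.0, size=96).clip(-y.to_numpy())
        counts = pd.DataFrame({"p1": y.clip(lower=0)}, index=CONTEXTS_96)
        exp, _ = fit_signatures(counts, catalog, cos_min=0.0)
        cat = catalog.to_numpy()
        target = counts["p1"].to_numpy()
        best_res = np.linalg.norm(cat @ exp["p1"].to_numpy() - target)
        grid = np.linspace(0, 1200, 61)
        for e1 in grid:
            for e2 in grid:
                res = np.linalg.norm(cat @ np.array([e1, e2]) - target)
                assert best_res <= res + 1e-9

    def test_negative_counts_rejected(self):
        catalog = synthetic.make_signature_catalog(2, seed=0)
        counts = pd.DataFrame({"p1": np.full(96, -1.0)}, index=CONTEXTS_96)
        with pytest.raises(ValueError):
            fit_signatures(counts, catalog)
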