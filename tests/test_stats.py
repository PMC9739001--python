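"""Fisher exact (point-probability rule), Mann-Whitney U, density summaries,
prevalence bookkeeping and the integration table."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from angiomics.filters import VariantRecord
from angiomics.panel import GeneSets, SampleMeta
from angiomics.stats import (
    ContingencyTable,
    build_integration_table,
    feature_prevalence,
    fisher_exact_two_sided,
    mann_whitney_u,
    sample_features,
    summarize_densities,
)


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected_3dp",
        [
            ((6, 19, 15, 10), 0.021),   # DDR-mutated: 24% vs 60% of 25
            ((20, 5, 22, 3), 0.702),    # pathogenic mutation: 80% vs 88%
            ((5, 5, 5, 5), 1.0),
            ((0, 25, 5, 20), 0.050),
        ],
    )
    def test_printed_cohort_tables(self, table, expected_3dp):
        p = fisher_exact_two_sided(ContingencyTable(*table))
        assert round(p, 3) == expected_3dp

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 0, 5, 5)) == 1.0
        assert fisher_exact_two_sided(ContingencyTable(3, 0, 4, 0)) == 1.0

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestMannWhitney:
    def test_identical_multisets(self):
        u, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n_a * n_b / 2
        assert p == pytest.approx(1.0, abs=0.01)

    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # exact two-sided at n=3,3

    def test_exact_small_sample(self):
        _, p = mann_whitney_u((1, 2, 3), (4, 5, 6))
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_large_sample_uses_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        _, p = mann_whitney_u(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


def _meta(n_prim=4, n_sec=4):
    meta = [SampleMeta(f"p{i}", "visceral", 0.5) for i in range(n_prim)]
    meta += [SampleMeta(f"s{i}", "rt", 0.5) for i in range(n_sec)]
    return meta


class TestDensitySummaries:
    def test_median_and_iqr_convention(self):
        meta = _meta(4, 4)
        rows = {m.sample_id: {"CD3": v} for m, v in
                zip(meta, [10, 20, 30, 40, 10, 20, 30, 40])}
        comps = summarize_densities(
            pd.DataFrame.from_dict(rows, orient="index"), meta, markers=("CD3",)
        )
        s = comps[0].summaries["primary"]
        # type-7 quantiles: Q1 = 17.5, Q3 = 32.5
        assert s["median"] == 25.0 and s["iqr"] == 15.0

    def test_identical_groups_not_significant(self):
        meta = _meta(6, 6)
        vals = [1, 2, 3, 4, 5, 6] * 2
        rows = {m.sample_id: {"CD3": v} for m, v in zip(meta, vals)}
        comps = summarize_densities(
            pd.DataFrame.from_dict(rows, orient="index"), meta, markers=("CD3",)
        )
        assert comps[0].p_value > 0.9

    def test_missing_marker_drops_sample(self):
        meta = _meta(2, 2)
        df = pd.DataFrame.from_dict(
            {"p0": {"CD3": 1.0}, "p1": {"CD3": np.nan},
             "s0": {"CD3": 3.0}, "s1": {"CD3": 4.0}},
            orient="index",
        )
        comps = summarize_densities(df, meta, markers=("CD3",))
        assert comps[0].summaries["primary"]["n"] == 1


class TestPrevalence:
    def test_printed_percentages_reproduced(self):
        meta = [SampleMeta(f"p{i}", "visceral", 0.5) for i in range(25)]
        meta += [SampleMeta(f"s{i}", "rt", 0.5) for i in range(25)]
        flags = {m.sample_id: {"ddr_mutation": False, "amp_MYC": False}
                 for m in meta}
        for i in range(6):
            flags[f"p{i}"]["ddr_mutation"] = True
        for i in range(15):
            flags[f"s{i}"]["ddr_mutation"] = True
        for i in range(4):
            flags[f"p{i}"]["amp_MYC"] = True
        for i in range(17):
            flags[f"s{i}"]["amp_MYC"] = True
        df = feature_prevalence(pd.DataFrame.from_dict(flags, orient="index"), meta)
        ddr = df[(df.feature == "ddr_mutation") & (df.level == "cluster")]
        assert list(ddr["percent"]) == [24.0, 60.0]
        assert round(ddr["fisher_p"].iloc[0], 3) == 0.021
        myc = df[(df.feature == "amp_MYC") & (df.level == "cluster")]
        assert list(myc["percent"]) == [16.0, 68.0]
        assert myc["fisher_p"].iloc[0] < 0.001

    def test_all_false_feature(self):
        meta = _meta(3, 3)
        flags = {m.sample_id: {"x": False} for m in meta}
        df = feature_prevalence(pd.DataFrame.from_dict(flags, orient="index"), meta)
        cl = df[df.level == "cluster"]
        assert (cl["percent"] == 0.0).all()
        assert (cl["fisher_p"] == 1.0).all()


def kept_variant(sample, gene, cls=5, pos=100):
    return VariantRecord(
        contig="panel1", pos_1based=pos, ref="C", alt="T", gene=gene,
        consequence="missense", pop_af=0.0, depth=500, alt_depth=150,
        sample_id=sample, pathogenicity_class=cls,
    )


class TestIntegrationTable:
    def _inputs(self):
        meta = _meta(2, 2)
        variants = {
            "p0": [kept_variant("p0", "TP53")],
            "s0": [kept_variant("s0", "TP53", pos=200),
                   kept_variant("s0", "SINGLETON")],
            "p1": [], "s1": [],
        }
        tmb_df = pd.DataFrame({
            "sample_id": [m.sample_id for m in meta],
            "n_eligible": [1, 0, 2, 0], "mb": [1.0] * 4,
            "tmb": [1.0, 0.0, 2.0, 0.0], "tmb_high": [False] * 4,
        })
        amp_df = pd.DataFrame({
            "sample_id": ["s0", "s1"], "gene": ["MYC", "MYC"],
            "relative_coverage": [4.0, 3.5], "amplified": [True, True],
            "estimated_copies": [8.0, 7.0],
        })
        allelic_df = pd.DataFrame(
            columns=["sample_id", "gene", "state", "mechanism", "observed_vaf",
                     "expected_het_vaf", "expected_loh_vaf", "snp_deviation"]
        )
        dens = pd.DataFrame.from_dict(
            {m.sample_id: {k: 10.0 for k in ("CD3", "CD8", "FoxP3", "CD4", "CD20")}
             for m in meta}, orient="index",
        )
        return meta, variants, tmb_df, amp_df, allelic_df, dens

    def test_recurrent_gene_filter(self):
        meta, variants, tmb_df, amp_df, allelic_df, dens = self._inputs()
        table = build_integration_table(meta, tmb_df, amp_df, allelic_df,
                                        variants, dens)
        # TP53 mutated in two samples and MYC amplified in two: retained;
        # SINGLETON altered once: dropped from the default view
        assert "mut_TP53" in table.columns and "amp_MYC" in table.columns
        assert not any("SINGLETON" in c for c in table.columns)
        full = build_integration_table(meta, tmb_df, amp_df, allelic_df,
                                       variants, dens, min_samples_per_gene=1)
        assert any("SINGLETON" in c for c in full.columns)

    def test_schema_arithmetic(self):
        meta, variants, tmb_df, amp_df, allelic_df, dens = self._inputs()
        table = build_integration_table(meta, tmb_df, amp_df, allelic_df,
                                        variants, dens)
        n_genes = 2  # TP53, MYC
        fixed = 6    # cluster, subgroup, purity, tmb, tmb_high, ddr_mutation
        assert table.shape == (4, fixed + 2 * n_genes + 5)

    def test_sample_without_alterations_keeps_densities(self):
        meta, variants, tmb_df, amp_df, allelic_df, dens = self._inputs()
        table = build_integration_table(meta, tmb_df, amp_df, allelic_df,
                                        variants, dens)
        row = table.loc["p1"]
        assert row["mut_TP53"] == "" or pd.isna(row["mut_TP53"])
        assert row["CD3"] == 10.0

    def test_prevalence_rederivable_from_features(self):
        meta, variants, tmb_df, amp_df, allelic_df, dens = self._inputs()
        feats = sample_features(meta, variants, amp_df, tmb_df, GeneSets())
        prev = feature_prevalence(feats, meta)
        tp53 = prev[(prev.feature == "ddr_mutation") & (prev.level == "cluster")]
        # one TP53-mutated sample in each cluster of two
        assert list(tp53["n_present"]) == [1, 1]
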