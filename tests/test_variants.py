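"""Variant-burden statistics and coreness-stratified integration."""

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modcore import enrichment as en
from modcore import simulate
from modcore import variants as va


def make_table(rows):
    defaults = {"consequence": "nonsynonymous", "case_an": 1010,
                "control_alt": np.nan, "control_an": np.nan,
                "ref_af": np.nan, "ref_an": 5008}
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("variant_id", f"v{i}")
        recs.append(rec)
    return pd.DataFrame(recs)


class TestRareFraction:
    def test_cohort_fraction(self):
        # 153 nonsynonymous variants on the module, 30 absent from the panel
        rows = [{"gene": "g", "case_alt": 1, "ref_af": np.nan if i < 30 else 0.01}
                for i in range(153)]
        res = va.rare_fraction(make_table(rows))
        assert res == (30, 153, pytest.approx(0.196, abs=5e-4))

    def test_all_in_reference_is_zero(self):
        rows = [{"gene": "g", "case_alt": 1, "ref_af": 0.1} for _ in range(10)]
        assert va.rare_fraction(make_table(rows)).fraction == 0.0

    def test_constructed_seven_of_twenty(self):
        rows = [{"gene": "g", "case_alt": 0,
                 "ref_af": np.nan if i < 7 else 0.2} for i in range(20)]
        assert va.rare_fraction(make_table(rows)).fraction == pytest.approx(0.35)

    def test_silent_class_filter(self):
        rows = [{"gene": "g", "case_alt": 0, "consequence": "silent",
                 "ref_af": np.nan}]
        with pytest.raises(ValueError):
            va.rare_fraction(make_table(rows), class_filter="nonsynonymous")


class TestRareEnrichmentPermutation:
    def test_planted_enrichment_detected(self):
        genes = [f"G{i:04d}" for i in range(500)]
        module = genes[:50]
        hits = 0
        for seed in range(20):
            vt, _ = simulate.gen_variant_table(
                genes, rare_rate=0.10, rare_enriched_genes=module,
                rare_rate_enriched=0.30, seed=seed)
            pool = en.MatchedBackground(genes=tuple(genes[50:]), balance={})
            _, _, p = va.rare_enrichment_permutation(
                en.GeneSet("m", frozenset(module)), vt, pool,
                n_perm=1000, seed=seed)
            if p <= 0.01:
                hits += 1
        assert hits >= 19

    def test_null_below_every_permutation_is_one(self):
        genes = [f"G{i:04d}" for i in range(80)]
        rows = ([{"gene": genes[0], "case_alt": 1, "ref_af": 0.1}] +
                [{"gene": g, "case_alt": 1, "ref_af": np.nan}
                 for g in genes[1:]])
        vt = make_table(rows)
        pool = en.MatchedBackground(genes=tuple(genes[1:]), balance={})
        _, _, p = va.rare_enrichment_permutation(
            en.GeneSet("m", frozenset({genes[0]})), vt, pool,
            n_perm=200, seed=0)
        assert p == 1.0


class TestAfCaseVsReference:
    def test_strong_variant_survives_bh_in_null_family(self):
        rng = np.random.default_rng(0)
        rows = [{"gene": "HIT", "variant_id": "sig", "case_alt": 10,
                 "case_an": 50, "ref_af": 0.01, "ref_an": 5008}]
        for i in range(100):  # null variants at matched frequencies
            f = float(rng.uniform(0.05, 0.3))
            rows.append({"gene": f"N{i}", "case_alt": int(round(f * 50)),
                         "case_an": 50, "ref_af": f, "ref_an": 5008})
        results, table = va.af_case_vs_reference(make_table(rows), fdr_target=0.1)
        assert table.loc[table["variant_id"] == "sig", "p"].item() < 1e-6
        assert "HIT" in {r.gene for r in results}

    def test_matched_frequency_not_reported(self):
        rows = [{"gene": "g", "case_alt": 101, "case_an": 1010,
                 "ref_af": 0.1, "ref_an": 5008}]
        results, table = va.af_case_vs_reference(make_table(rows))
        assert table["p"].item() > 0.9
        assert results == []

    def test_missing_reference_routed_out(self):
        rows = [{"gene": "g", "case_alt": 5, "ref_af": np.nan},
                {"gene": "g", "case_alt": 5, "ref_af": 0.01}]
        _, table = va.af_case_vs_reference(make_table(rows))
        assert len(table) == 1

    def test_symmetry_under_role_swap(self):
        # swapping case and reference roles leaves the two-sided p unchanged
        p1 = en.fisher_2x2([[30, 70], [10, 90]])
        p2 = en.fisher_2x2([[10, 90], [30, 70]])
        assert p1 == pytest.approx(p2)

    def test_planted_gene_recovery(self):
        recovered = []
        for seed in range(20):
            genes = [f"G{i:04d}" for i in range(300)]
            vt, truth = simulate.gen_variant_table(
                genes, planted_genes=genes[:10], af_shift=0.1, seed=seed)
            results, _ = va.af_case_vs_reference(vt, fdr_target=0.1)
            recovered.append(
                len({r.gene for r in results} & set(truth.planted["shifted_genes"])))
        assert min(recovered) >= 8


class TestReciprocalRegression:
    @staticmethod
    def _cohort(seed, n_null=500, n_planted=10, shift=0.10):
        rng = np.random.default_rng(seed)
        n = n_null + n_planted
        f = np.clip(rng.beta(0.2, 2, n), 0.001, 0.5)
        case_p = f.copy()
        case_p[:n_planted] = np.clip(case_p[:n_planted] + shift, 0, 1)
        rows = [{"gene": f"G{i}", "variant_id": f"v{i}",
                 "case_alt": int(rng.binomial(1010, case_p[i])), "case_an": 1010,
                 "control_alt": int(rng.binomial(982, f[i])), "control_an": 982,
                 "ref_af": f[i]} for i in range(n)]
        return make_table(rows)

    def test_planted_excess_recovered_with_null_control(self):
        rec, nullfrac = [], []
        for seed in range(20):
            vt = self._cohort(seed)
            res = va.reciprocal_regression_outliers(vt, tail=0.05)
            flagged = set(res.outliers)
            rec.append(sum(1 for i in range(10) if f"v{i}" in flagged))
            nullfrac.append(
                sum(1 for i in range(10, 510) if f"v{i}" in flagged) / 500)
        assert min(rec) >= 8
        assert np.mean(nullfrac) <= 0.05

    def test_collinear_degenerate_path(self, caplog):
        rows = [{"gene": f"g{i}", "variant_id": f"v{i}",
                 "case_alt": 10 * i, "case_an": 1000,
                 "control_alt": 10 * i, "control_an": 1000,
                 "ref_af": 0.1} for i in range(1, 25)]
        res = va.reciprocal_regression_outliers(make_table(rows))
        assert res.outliers == ()

    def test_calibration_on_exact_t_residuals(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0.1, 0.05, 2000)
        y = x + stats.t.rvs(5, scale=0.01, size=2000, random_state=rng)
        rows = [{"gene": f"g{i}", "variant_id": f"v{i}",
                 "case_alt": 0, "case_an": 10,
                 "control_alt": 0, "control_an": 10, "ref_af": 0.1}
                for i in range(2000)]
        vt = make_table(rows)
        vt["case_alt"] = np.clip((y * 1000).round(), 0, 1000).astype(int)
        vt["case_an"] = 1000
        vt["control_alt"] = np.clip((x * 1000).round(), 0, 1000).astype(int)
        vt["control_an"] = 1000
        res = va.reciprocal_regression_outliers(vt, tail=0.05)
        frac = res.table["outlier"].mean()
        assert 0.03 <= frac <= 0.07

    def test_too_few_variants_errors(self):
        vt = self._cohort(0).head(10)
        with pytest.raises(ValueError):
            va.reciprocal_regression_outliers(vt)


class TestAfDifferenceRankCurve:
    @staticmethod
    def _module_table(seed, shift_candidates=True, n_genes=150, shift=0.15):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:04d}" for i in range(n_genes)]
        cand = genes[:15]
        rows = []
        for i, g in enumerate(genes):
            for j in range(3):
                f = float(np.clip(rng.beta(0.5, 3), 0.001, 0.6))
                fc = f + shift if (shift_candidates and g in cand) else f
                rows.append({"gene": g, "variant_id": f"v{i}_{j}",
                             "case_alt": int(rng.binomial(1010, min(fc, 1.0))),
                             "case_an": 1010,
                             "control_alt": int(rng.binomial(982, f)),
                             "control_an": 982, "ref_af": f})
        return make_table(rows), genes, cand

    def test_candidates_equal_module_curve_is_one(self):
        vt, genes, _ = self._module_table(0, shift_candidates=False)
        curve, p = va.af_difference_rank_curve(vt, genes, genes, n_perm=99, seed=0)
        assert np.allclose(curve["fraction_candidate"], 1.0)
        assert p == 1.0

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(20):
            vt, genes, cand = self._module_table(seed)
            _, p = va.af_difference_rank_curve(vt, cand, genes,
                                               n_perm=999, seed=seed)
            if p <= 0.01:
                hits += 1
        assert hits >= 19

    def test_too_few_variants_errors(self):
        vt, genes, cand = self._module_table(1)
        with pytest.raises(ValueError):
            va.af_difference_rank_curve(vt.head(2), cand, genes,
                                        n_perm=9, seed=0, k_grid=[5, 10])


class TestCorenessBurden:
    @staticmethod
    def _module_scene(seed):
        graph, truth = simulate.gen_modular_network(
            4, 50, 0.25, 0.01, seed=seed, degree_heterogeneity=0.6)
        K = nx.core_number(graph)
        module = sorted(g for g, b in truth.planted["partition"].items() if b == 0)
        bins = va.quantile_coreness_bins([K[g] for g in module])
        return graph, K, module, bins

    def test_top_concentration_detected(self):
        # synthetic coreness map with 5 genes per K level 1..12
        module = [f"g{i}" for i in range(60)]
        K = {g: 1 + i % 12 for i, g in enumerate(module)}
        top = [g for g in module if K[g] >= 10]
        mutated = set(top[:10])
        prof = va.coreness_burden_profile(
            mutated, module, K, bins=va.DEFAULT_CORENESS_BINS,
            n_perm=999, seed=0)
        assert prof.table["p_enrich"].iloc[-1] < 0.05
        assert prof.p_curve < 0.05

    def test_uniform_mutations_calibrated(self):
        graph, K, module, bins = self._module_scene(1)
        rng = np.random.default_rng(7)
        ok = 0
        for rep in range(20):
            mutated = set(rng.choice(module, 12, replace=False))
            prof = va.coreness_burden_profile(mutated, module, K, bins=bins,
                                              n_perm=199, seed=rep)
            pvals = prof.table["p_enrich"].dropna()
            if (pvals > 0.05).mean() >= 0.8:
                ok += 1
        assert ok >= 16

    def test_everything_mutated_s_zero(self):
        graph, K, module, bins = self._module_scene(2)
        prof = va.coreness_burden_profile(set(module), module, K, bins=bins,
                                          n_perm=49, seed=0)
        assert np.allclose(prof.table["fraction"].dropna(), 1.0)
        assert prof.s_observed == pytest.approx(0.0)

    def test_fraction_conservation(self):
        graph, K, module, bins = self._module_scene(3)
        rng = np.random.default_rng(5)
        mutated = set(rng.choice(module, 15, replace=False))
        prof = va.coreness_burden_profile(mutated, module, K, bins=bins,
                                          n_perm=9, seed=0)
        t = prof.table.dropna(subset=["fraction"])
        overall = (t["fraction"] * t["n_genes"]).sum() / t["n_genes"].sum()
        assert overall == pytest.approx(len(mutated) / len(module))


class TestCoreGroupBias:
    def test_enumeration_oracle_small_module(self):
        module = [f"g{i}" for i in range(20)]
        group1 = set(module[:10])
        core = set(module[:6])  # core entirely inside group 1
        res = va.core_group_bias(core, group1, module)
        # P(X >= 6), X ~ Hypergeom(N=20, K=10, n=6), by enumeration
        expect = comb(10, 6) / comb(20, 6)
        assert res.p_value == pytest.approx(expect, rel=1e-9)

    def test_group_equals_module_p_one(self):
        module = [f"g{i}" for i in range(10)]
        res = va.core_group_bias(set(module[:4]), set(module), module)
        assert res.p_value == 1.0

    def test_empty_intersection_near_one(self):
        module = [f"g{i}" for i in range(30)]
        res = va.core_group_bias(set(module[:5]), set(module[5:25]), module)
        assert res.p_value > 0.99


class TestCorenessExpressionCorrelation:
    def test_monotone_extremes(self):
        K = {f"g{i}": i + 1 for i in range(20)}
        expr = {f"g{i}": float(i) for i in range(20)}
        r, _ = va.coreness_expression_correlation(K, expr)
        assert r == pytest.approx(1.0)
        anti = {f"g{i}": float(-i) for i in range(20)}
        r2, _ = va.coreness_expression_correlation(K, anti)
        assert r2 == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            K = {f"g{i}": int(rng.integers(1, 12)) for i in range(300)}
            expr = {f"g{i}": float(rng.normal()) for i in range(300)}
            r, _ = va.coreness_expression_correlation(K, expr)
            if abs(r) < 0.15:
                ok += 1
        assert ok >= 18

    def test_constant_errors(self):
        K = {f"g{i}": 3 for i in range(15)}
        expr = {f"g{i}": float(i) for i in range(15)}
        with pytest.raises(ValueError):
            va.coreness_expression_correlation(K, expr)


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        genes = [f"G{i}" for i in range(20)]
        vt, _ = simulate.gen_variant_table(genes, seed=0)
        p = tmp_path / "v.tsv"
        va.write_variant_table(vt, p)
        back = va.read_variant_table(p)
        assert len(back) == len(vt)
        assert back["case_alt"].tolist() == vt["case_alt"].tolist()
        assert back["ref_af"].isna().sum() == vt["ref_af"].isna().sum()

    def test_vcf_ingestion(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="class">\n'
            '##INFO=<ID=AC,Number=1,Type=Integer,Description="case alt">\n'
            '##INFO=<ID=AN,Number=1,Type=Integer,Description="case an">\n'
            '##INFO=<ID=REF_AF,Number=1,Type=Float,Description="panel af">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\trs1\tA\tG\t.\t.\tGENE=BRCA2;CSQ_CLASS=nonsynonymous;"
            "AC=12;AN=1010;REF_AF=0.01\n"
            "1\t200\t.\tC\tT\t.\t.\tGENE=LRP2;CSQ_CLASS=silent;AC=3;AN=1010\n"
        )
        df = va.read_variants_vcf(vcf)
        assert df.loc[0, "gene"] == "BRCA2"
        assert df.loc[0, "ref_af"] == pytest.approx(0.01)
        assert np.isnan(df.loc[1, "ref_af"])
        assert df.loc[1, "variant_id"] == "1:200:C>T"

    def test_invalid_counts_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        pd.DataFrame({"variant_id": ["v1"], "gene": ["g"],
                      "consequence": ["nonsynonymous"],
                      "case_alt": [60], "case_an": [50]}).to_csv(
            p, sep="\t", index=False)
        with pytest.raises(ValueError):
            va.read_variant_table(p)
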