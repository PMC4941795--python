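"""SNP QC, window gene scoring, ES/SPES permutation machinery, QQ/lambda."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stratanet.gwas import (
    GwasError,
    build_snp_assignment,
    enrichment_score,
    fdr_across_sets,
    map_snps_to_genes,
    permutation_test,
    qq_lambda,
    significant_mask,
    snp_qc,
    spes,
)
from stratanet.synthetic import SyntheticGwasDesign, generate_snp_dataset, gwas_gene_ids


def _snp_table(positions, pvalues):
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(len(positions))],
            "CHR": 1,
            "BP": positions,
            "P": pvalues,
            "MAF": 0.2,
            "F_MISS": 0.01,
            "HWE_P": 0.5,
        }
    )


class TestSnpQc:
    def test_boundary_rules_are_strict(self):
        snps = _snp_table([100, 200, 300, 400], [0.5] * 4)
        snps.loc[0, "MAF"] = 0.005  # < 0.01 -> removed
        snps.loc[1, "F_MISS"] = 0.10  # == 0.1 -> retained (strict >)
        snps.loc[2, "HWE_P"] = 0.0005  # < 0.001 -> removed
        snps.loc[3, "MAF"] = 0.01  # == 0.01 -> retained
        kept, log = snp_qc(snps)
        assert set(kept["SNP"]) == {"rs1", "rs3"}
        assert log["fail_maf"] == 1 and log["fail_hwe"] == 1 and log["fail_missing"] == 0

    def test_all_removed_is_reported(self):
        snps = _snp_table([100], [0.5])
        snps["MAF"] = 0.0
        with pytest.raises(GwasError):
            snp_qc(snps)


class TestGeneScoring:
    GENES = pd.DataFrame(
        {"gene": ["gA", "gB"], "chrom": "chr1",
         "start": [50_000, 200_000], "end": [60_000, 210_000]}
    )

    def test_window_boundary_inclusive(self):
        snps = _snp_table([30_000, 29_999], [0.5, 0.5])
        scores = map_snps_to_genes(snps, self.GENES.iloc[[0]], window_bp=20_000)
        assign = build_snp_assignment(snps, self.GENES.iloc[[0]], 20_000)
        # start - 20000 = 30000 assigned; 29999 not
        assert list(assign.snp_idx) == [0]
        assert scores.loc["gA", "n_snps"] == 1

    def test_score_is_max_neglog10(self):
        snps = _snp_table([55_000, 56_000], [0.1, 0.001])
        scores = map_snps_to_genes(snps, self.GENES, window_bp=20_000)
        assert scores.loc["gA", "score"] == pytest.approx(3.0)
        assert "gB" not in scores.index  # no SNPs -> excluded

    def test_adding_weaker_snp_never_changes_score(self):
        snps = _snp_table([55_000], [0.001])
        base = map_snps_to_genes(snps, self.GENES, 20_000).loc["gA", "score"]
        snps2 = _snp_table([55_000, 56_000], [0.001, 0.5])
        grown = map_snps_to_genes(snps2, self.GENES, 20_000).loc["gA", "score"]
        assert grown == base

    def test_agrees_with_all_pairs_oracle(self, rng):
        n_snps, n_genes, w = 300, 30, 5_000
        positions = np.sort(rng.choice(np.arange(1, 500_000), n_snps, replace=False))
        p = rng.uniform(size=n_snps)
        snps = _snp_table(positions, p)
        starts = rng.choice(np.arange(1, 450_000), n_genes, replace=False)
        genes = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(n_genes)], "chrom": "chr1",
             "start": starts, "end": starts + 8_000}
        )
        scores = map_snps_to_genes(snps, genes, w)
        for _, g in genes.iterrows():
            in_win = (positions >= g["start"] - w) & (positions <= g["end"] + w)
            if not in_win.any():
                assert g["gene"] not in scores.index
            else:
                assert scores.loc[g["gene"], "score"] == pytest.approx(
                    (-np.log10(p[in_win])).max(), abs=1e-12
                )


class TestEnrichmentScore:
    def test_single_top_gene_scores_one(self):
        scores = pd.Series({"a": 5.0, "b": 3.0, "c": 1.0, "d": 0.5})
        assert enrichment_score(scores, {"a"}) == pytest.approx(1.0)

    def test_matches_manual_running_sum(self):
        # independent step-by-step evaluation on a 10-gene example
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.uniform(0, 5, 10), index=[f"g{i}" for i in range(10)])
        gene_set = {"g1", "g4", "g7"}
        w = 1.0
        order = scores.sort_values(ascending=False).index
        nr = sum(scores[g] ** w for g in gene_set)
        running, best = 0.0, -np.inf
        n_out = 10 - len(gene_set)
        for g in order:
            if g in gene_set:
                running += scores[g] ** w / nr
            else:
                running -= 1.0 / n_out
            best = max(best, running)
        assert enrichment_score(scores, gene_set) == pytest.approx(best, abs=1e-12)

    def test_all_genes_set_is_nonnegative(self):
        scores = pd.Series({"a": 2.0, "b": 1.0})
        assert enrichment_score(scores, {"a", "b"}) >= 0

    def test_rank_only_mode_invariant_to_monotone_rescaling(self):
        scores = pd.Series({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        s2 = scores**3 + 7
        assert enrichment_score(scores, {"a", "c"}, 0.0) == pytest.approx(
            enrichment_score(s2, {"a", "c"}, 0.0)
        )

    def test_empty_intersection_rejected(self):
        with pytest.raises(GwasError):
            enrichment_score(pd.Series({"a": 1.0}), {"zz"})


class TestSpes:
    def test_reduces_to_es_when_k_equals_K(self):
        assert spes(0.7, 0.05, 0.05) == pytest.approx(0.7)

    def test_zero_k(self):
        assert spes(0.7, 0.0, 0.05) == 0.0

    def test_arithmetic(self):
        assert spes(0.5, 0.2, 0.05) == pytest.approx(2.0)

    def test_zero_K_rejected(self):
        with pytest.raises(GwasError):
            spes(0.5, 0.1, 0.0)

    def test_significant_mask_is_top_alpha(self):
        scores = np.array([5.0, 1.0, 3.0, 0.5])
        mask = significant_mask(scores, alpha=0.25)
        assert mask.tolist() == [True, False, False, False]


class TestPermutationTest:
    def _dataset(self, enriched=(), signal=0.0, seed=0, n_snps=2000, n_genes=200):
        design = SyntheticGwasDesign(
            n_snps=n_snps, n_genes=n_genes, enriched_set=tuple(enriched),
            signal_strength=signal, seed=seed,
        )
        return generate_snp_dataset(design)

    def test_fixed_seed_reproduces(self):
        snps, genes, _ = self._dataset()
        a = permutation_test(snps, genes, gwas_gene_ids(200)[:30], n_perm=100, seed=4)
        b = permutation_test(snps, genes, gwas_gene_ids(200)[:30], n_perm=100, seed=4)
        assert a.p_value == b.p_value and a.spes_value == b.spes_value

    def test_planted_signal_hits_permutation_floor(self):
        enriched = gwas_gene_ids(200)[:30]
        snps, genes, _ = self._dataset(enriched, signal=8.0, seed=1)
        res = permutation_test(snps, genes, enriched, n_perm=200, seed=2)
        assert res.p_value == pytest.approx(1.0 / 201.0)

    def test_small_n_perm_warns(self):
        snps, genes, _ = self._dataset()
        with pytest.warns(UserWarning):
            permutation_test(snps, genes, gwas_gene_ids(200)[:20], n_perm=50, seed=0)

    def test_fdr_orders_enriched_before_null_sets(self):
        enriched = gwas_gene_ids(300)[:30]
        snps, genes, _ = self._dataset(enriched, signal=8.0, seed=3, n_snps=3000,
                                       n_genes=300)
        rng = np.random.default_rng(0)
        results = [
            permutation_test(snps, genes, enriched, n_perm=200, seed=5,
                             gene_set_id="planted")
        ]
        for i in range(3):
            null_set = rng.choice(gwas_gene_ids(300)[30:], 30, replace=False)
            results.append(
                permutation_test(snps, genes, null_set, n_perm=200, seed=6 + i,
                                 gene_set_id=f"null{i}")
            )
        fdr_across_sets(results)
        assert all(0.0 <= r.fdr_q <= 1.0 for r in results)
        assert results[0].fdr_q <= min(r.fdr_q for r in results[1:])


class TestQqLambda:
    def test_single_median_p_gives_unit_lambda(self):
        with pytest.warns(UserWarning):  # < 20 p-values
            rep = qq_lambda([0.5])
        assert rep.lam == pytest.approx(1.0)

    def test_uniform_grid_lambda_is_one_both_methods(self):
        L = 10_000
        p = np.arange(1, L + 1) / (L + 1)
        assert qq_lambda(p, method="median").lam == pytest.approx(1.0, abs=0.01)
        assert qq_lambda(p, method="regression").lam == pytest.approx(1.0, abs=0.02)

    def test_doubled_chi2_doubles_lambda(self):
        L = 10_000
        p = np.arange(1, L + 1) / (L + 1)
        chi = stats.chi2.isf(p, 1)
        p2 = stats.chi2.sf(2 * chi, 1)
        assert qq_lambda(p2).lam == pytest.approx(2.0, abs=0.1)

    def test_expected_order_statistic_definition(self):
        p = np.array([0.5, 0.01, 0.2, 0.9])
        rep = qq_lambda(p)
        assert np.allclose(rep.expected, -np.log10(np.arange(1, 5) / 5.0))
        assert np.allclose(rep.observed, sorted(-np.log10(p), reverse=True))

    def test_subset_uses_all_gene_expectation(self):
        p = np.array([0.001, 0.5, 0.6, 0.7, 0.8])
        rep = qq_lambda(p, subset=[0])
        # the subset point keeps its global rank (1 of L=5)
        assert rep.expected[0] == pytest.approx(-np.log10(1 / 6))
        assert rep.n == 1

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            qq_lambda([0.0, 0.5])
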