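"""Cross-tabulation matching, Z_summary preservation, specificity calls,
subsampling replication and the adjusted differential-ME test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_expr, preservation_pair
from stratanet.modules import ModulePartition
from stratanet.specificity import (
    PreservationReport,
    classify_specific,
    crosstab_match,
    differential_me,
    replicate_by_subsampling,
    zsummary_preservation,
)
from stratanet.synthetic import (
    PlantedModule,
    SyntheticDesign,
    generate_stratified_expression,
)


def _partition(labels_dict):
    return ModulePartition(pd.Series(labels_dict))


class TestCrosstabMatch:
    def test_identical_partitions_match_diagonally(self):
        labels = {f"g{i}": 1 if i < 20 else (2 if i < 40 else 0) for i in range(100)}
        part = _partition(labels)
        pairs, matched = crosstab_match(part, part)
        assert matched == {1: True, 2: True}
        diag = pairs[(pairs.module_a == pairs.module_b)]
        assert (diag["p"] < 1e-10).all()

    def test_disjoint_small_modules_are_unmatched(self):
        a = _partition({f"g{i}": 1 if i < 5 else 0 for i in range(200)})
        b = _partition({f"g{i}": 1 if 100 <= i < 105 else 0 for i in range(200)})
        pairs, matched = crosstab_match(a, b)
        assert matched == {1: False}
        assert pairs["p"].iloc[0] > 0.5

    def test_fisher_equals_hypergeometric_tail(self, rng):
        # independent oracle: sum of hypergeometric point masses >= x
        for _ in range(20):
            N = int(rng.integers(20, 60))
            m = int(rng.integers(3, 10))
            k = int(rng.integers(3, 10))
            x = int(rng.integers(0, min(m, k) + 1))
            table = [[x, m - x], [k - x, N - m - k + x]]
            if min(min(row) for row in table) < 0:
                continue
            p_fisher = stats.fisher_exact(table, alternative="greater")[1]
            p_oracle = sum(
                stats.hypergeom.pmf(j, N, m, k) for j in range(x, min(m, k) + 1)
            )
            assert p_fisher == pytest.approx(p_oracle, rel=1e-9)

    def test_no_shared_genes_rejected(self):
        a = _partition({"g1": 1})
        b = _partition({"h1": 1})
        with pytest.raises(ValueError):
            crosstab_match(a, b)


class TestZsummary:
    def test_preserved_module_scores_high(self):
        ref, test, module = preservation_pair(seed=0, planted_test=True)
        rep = zsummary_preservation(ref, test, module, 6, n_perm=50, seed=1)
        assert rep.z_summary > 10
        assert rep.specificity_class == "none"

    def test_absent_module_scores_low(self):
        ref, test, module = preservation_pair(seed=0, planted_test=False)
        rep = zsummary_preservation(ref, test, module, 6, n_perm=50, seed=1)
        assert abs(rep.z_summary) < 2
        assert rep.specificity_class == "strong"

    def test_fixed_seed_reproduces_exactly(self):
        ref, test, module = preservation_pair(seed=3, planted_test=True)
        a = zsummary_preservation(ref, test, module, 6, n_perm=30, seed=9)
        b = zsummary_preservation(ref, test, module, 6, n_perm=30, seed=9)
        assert a.z_summary == b.z_summary
        pd.testing.assert_frame_equal(a.statistics, b.statistics)

    def test_tiny_module_rejected(self):
        ref, test, module = preservation_pair(seed=1, planted_test=True)
        with pytest.raises(ValueError):
            zsummary_preservation(ref, test, module[:2], 6)

    def test_missing_module_genes_rejected(self):
        ref, test, module = preservation_pair(seed=1, planted_test=True)
        with pytest.raises(ValueError):
            zsummary_preservation(ref, test, module + ["nonexistent"], 6)


class TestClassifySpecific:
    def _report(self, z):
        return PreservationReport(1, z, z, z, 10, pd.DataFrame())

    def test_specific_requires_unmatched_and_low_z(self):
        part = _partition({f"g{i}": 1 if i < 30 else 0 for i in range(60)})
        matched = {"consA": {1: False}, "consB": {1: False}}
        pres = {1: {"other1": self._report(0.5), "other2": self._report(-1.0)}}
        calls = classify_specific(part, matched, pres)
        assert calls[0].specific is True

    def test_matched_module_not_specific(self):
        part = _partition({f"g{i}": 1 if i < 30 else 0 for i in range(60)})
        matched = {"consA": {1: True}, "consB": {1: False}}
        pres = {1: {"other1": self._report(0.5), "other2": self._report(0.5)}}
        assert classify_specific(part, matched, pres)[0].specific is False

    def test_preserved_module_not_specific(self):
        part = _partition({f"g{i}": 1 if i < 30 else 0 for i in range(60)})
        matched = {"consA": {1: False}, "consB": {1: False}}
        pres = {1: {"other1": self._report(15.0), "other2": self._report(0.5)}}
        assert classify_specific(part, matched, pres)[0].specific is False

    def test_missing_evidence_is_undetermined(self):
        part = _partition({f"g{i}": 1 if i < 30 else 0 for i in range(60)})
        matched = {"consA": {1: False}}  # only one consensus comparison
        pres = {1: {"other1": self._report(0.5)}}
        assert classify_specific(part, matched, pres)[0].specific is None

    def test_empty_partition_yields_no_calls(self):
        part = _partition({f"g{i}": 0 for i in range(10)})
        assert classify_specific(part, {}, {}) == []


class TestReplication:
    def _planted(self, seed=0, rho=0.9):
        design = SyntheticDesign(
            n_genes=150,
            n_samples_per_stratum={"AD-carrier": 60},
            planted_modules=[PlantedModule(1, 50, ("AD-carrier",), rho)],
            seed=seed,
        )
        strata, truth = generate_stratified_expression(design)
        module = [g for g, m in truth["gene_module"].items() if m == 1]
        labels = pd.Series(
            [1 if g in set(module) else 0 for g in strata["AD-carrier"].gene_ids],
            index=strata["AD-carrier"].gene_ids,
        )
        return strata["AD-carrier"], ModulePartition(labels)

    def test_full_fraction_recovers_module_exactly(self):
        expr, part = self._planted()
        rep = replicate_by_subsampling(
            expr, part, 1, beta=6, fractions=(1.0,), runs=1, seed=0
        )
        assert rep.runs["best_overlap"].iloc[0] == pytest.approx(1.0)

    def test_strong_module_replicates_at_half_sampling(self):
        expr, part = self._planted()
        rep = replicate_by_subsampling(
            expr, part, 1, beta=6, fractions=(0.5, 0.75), runs=5, seed=1
        )
        assert rep.replicated

    def test_zero_overlap_threshold_is_vacuous_on_planted_data(self):
        expr, part = self._planted(seed=2)
        rep = replicate_by_subsampling(
            expr, part, 1, beta=6, fractions=(0.75,), runs=2,
            overlap_frac=0.0, seed=2
        )
        assert rep.replicated

    def test_empty_module_rejected(self):
        expr, part = self._planted()
        with pytest.raises(ValueError):
            replicate_by_subsampling(expr, part, 99, beta=6, seed=0)


class TestDifferentialMe:
    def _cov(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "phenotype": rng.permutation(["case"] * (n // 2) + ["control"] * (n - n // 2)),
                "carrier": rng.permutation(["yes"] * (n // 2) + ["no"] * (n - n // 2)),
                "age": rng.normal(78, 6, n),
                "sex": rng.choice(["M", "F"], n),
            },
            index=[f"s{j}" for j in range(n)],
        )

    def test_group_indicator_has_minimal_p(self):
        cov = self._cov()
        me = pd.Series(
            (cov["phenotype"] == "case").astype(float), index=cov.index
        )
        coef, p = differential_me(me, cov, "phenotype")
        assert p < 1e-20
        assert abs(coef) == pytest.approx(1.0, abs=1e-8)

    def test_coefficient_matches_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        cov = self._cov(seed=5)
        me = pd.Series(rng.normal(size=60), index=cov.index)
        coef, _ = differential_me(me, cov, "carrier")
        # direct normal equations on the same design
        X = np.column_stack(
            [
                np.ones(60),
                (cov["carrier"] == "no").astype(float),
                (cov["phenotype"] == "case").astype(float),
                cov["age"].to_numpy(),
                (cov["sex"] == "M").astype(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ me.to_numpy())
        assert coef == pytest.approx(beta[1], abs=1e-10)

    def test_null_type_one_error_is_nominal(self):
        # 1000 null eigengenes against a fixed covariate design
        cov = self._cov(seed=7)
        rng = np.random.default_rng(7)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            me = pd.Series(rng.normal(size=60), index=cov.index)
            _, p = differential_me(me, cov, "phenotype")
            rejections += p < 0.05
        lo = stats.binom.ppf(0.005, n_reps, 0.05)
        hi = stats.binom.ppf(0.995, n_reps, 0.05)
        assert lo <= rejections <= hi

    def test_single_level_grouping_rejected(self):
        cov = self._cov()
        cov["carrier"] = "yes"
        me = pd.Series(np.zeros(60), index=cov.index)
        with pytest.raises(ValueError):
            differential_me(me, cov, "carrier")
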