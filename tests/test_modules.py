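"""Dendrogram construction, tree cutting, eigengenes, merging, consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from conftest import make_expr
from stratanet.modules import (
    cluster_dendrogram,
    consensus_modules,
    consensus_tom,
    detect_modules,
    dynamic_tree_cut,
    eigengene,
    eigengenes,
    merge_close_modules,
)
from stratanet.network import adjacency, pairwise_correlation, topological_overlap
from stratanet.synthetic import (
    PlantedModule,
    SyntheticDesign,
    generate_stratified_expression,
)


def _block_tom(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    ids = [f"g{i}" for i in range(n)]
    t = np.full((n, n), between)
    start = 0
    for s in sizes:
        t[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=ids, columns=ids)


def _planted_tom(seed, n_genes=100, module_sizes=(50, 50), n=60, rho=0.8, beta=6):
    mods = [
        PlantedModule(i + 1, s, ("AD-carrier",), rho)
        for i, s in enumerate(module_sizes)
    ]
    design = SyntheticDesign(
        n_genes=n_genes,
        n_samples_per_stratum={"AD-carrier": n},
        planted_modules=mods,
        seed=seed,
    )
    strata, truth = generate_stratified_expression(design)
    expr = strata["AD-carrier"]
    tom = topological_overlap(adjacency(pairwise_correlation(expr), beta))
    return expr, tom, truth


class TestDendrogram:
    def test_two_separated_blocks_merge_at_zero_then_one(self):
        tom = _block_tom([4, 4])
        link = cluster_dendrogram(tom)
        heights = np.sort(link[:, 2])
        assert np.allclose(heights[:-1], 0.0)
        assert heights[-1] == pytest.approx(1.0)

    def test_two_genes_merge_at_dissimilarity(self):
        ids = ["a", "b"]
        tom = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=ids, columns=ids)
        link = cluster_dendrogram(tom)
        assert link[0, 2] == pytest.approx(0.7)

    def test_matches_textbook_average_linkage(self, rng):
        # naive O(n^3) agglomeration as the independent oracle
        n = 15
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        tom = pd.DataFrame(1.0 - d)

        clusters = {i: [i] for i in range(n)}
        dist = {
            (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
        }
        heights = []
        next_id = n
        while len(clusters) > 1:
            (a, b), h = min(dist.items(), key=lambda kv: kv[1])
            heights.append(h)
            merged = clusters.pop(a) + clusters.pop(b)
            for c in list(clusters):
                pair_d = np.mean([d[x, y] for x in merged for y in clusters[c]])
                dist[(min(c, next_id), max(c, next_id))] = pair_d
            dist = {k: v for k, v in dist.items() if a not in k and b not in k}
            clusters[next_id] = merged
            next_id += 1

        link = cluster_dendrogram(tom)
        assert np.allclose(np.sort(link[:, 2]), np.sort(heights), atol=1e-12)

    def test_nonfinite_rejected(self):
        tom = _block_tom([3, 3])
        tom.iloc[0, 1] = np.nan
        with pytest.raises(ValueError):
            cluster_dendrogram(tom)


class TestDynamicTreeCut:
    @pytest.mark.parametrize("seed", range(3))
    def test_planted_blocks_recovered(self, seed):
        _, tom, truth = _planted_tom(seed)
        part = dynamic_tree_cut(tom, min_module_size=30)
        labels_true = [truth["gene_module"][g] for g in part.gene_ids]
        assert part.n_modules() == 2
        assert adjusted_rand_score(labels_true, part.labels.tolist()) >= 0.9

    @pytest.mark.parametrize("seed", range(2))
    def test_pure_noise_stays_grey(self, seed):
        design = SyntheticDesign(
            n_genes=100, n_samples_per_stratum={"AD-carrier": 60}, seed=seed
        )
        strata, _ = generate_stratified_expression(design)
        tom = topological_overlap(
            adjacency(pairwise_correlation(strata["AD-carrier"]), 6)
        )
        part = dynamic_tree_cut(tom, min_module_size=30)
        assert (part.labels == 0).mean() >= 0.9

    def test_cut_at_max_height_yields_single_module(self):
        _, tom, _ = _planted_tom(1)
        link = cluster_dendrogram(tom)
        part = dynamic_tree_cut(
            tom, min_module_size=1, cut_height=float(link[:, 2].max()), deep_split=0
        )
        assert part.n_modules() == 1
        assert (part.labels == 1).all()

    def test_oversized_minimum_leaves_all_grey(self):
        tom = _block_tom([5, 5])
        with pytest.warns(UserWarning):
            part = dynamic_tree_cut(tom, min_module_size=50)
        assert (part.labels == 0).all()

    def test_gene_relabeling_is_consistent(self, rng):
        _, tom, _ = _planted_tom(2)
        perm = list(rng.permutation(tom.index))
        part = dynamic_tree_cut(tom, min_module_size=30)
        part_perm = dynamic_tree_cut(tom.loc[perm, perm], min_module_size=30)
        aligned = part_perm.labels.loc[part.labels.index]
        assert adjusted_rand_score(part.labels.tolist(), aligned.tolist()) == 1.0


class TestEigengenes:
    def test_rank_one_module(self):
        profile = np.linspace(-1, 1, 20)
        vals = np.vstack([2.0 * profile, -3.0 * profile + 1.0, profile])
        me = eigengene(pd.DataFrame(vals, index=list("abc")), list("abc"))
        assert me.prop_var_explained == pytest.approx(1.0)
        r = np.corrcoef(me.scores, profile)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_sign_convention(self, rng):
        for _ in range(5):
            vals = pd.DataFrame(rng.normal(size=(10, 25)))
            me = eigengene(vals, list(range(10)))
            z = ((vals.T - vals.mean(axis=1)) / vals.std(axis=1, ddof=1)).T
            assert np.corrcoef(me.scores, z.mean(axis=0))[0, 1] >= 0

    def test_matches_eigendecomposition_oracle(self, rng):
        vals = pd.DataFrame(rng.normal(size=(8, 30)))
        me = eigengene(vals, list(range(8)))
        z = ((vals.T - vals.mean(axis=1)) / vals.std(axis=1, ddof=1)).to_numpy()
        w, v = np.linalg.eigh(z @ z.T)  # samples x samples outer product
        lead = v[:, np.argmax(w)]
        align = np.sign(np.dot(lead, me.scores))
        assert np.abs(align * lead - me.scores.to_numpy()).max() < 1e-10
        assert me.prop_var_explained == pytest.approx(w.max() / w.sum())

    def test_zero_variance_module_fails(self):
        vals = pd.DataFrame(np.ones((3, 10)), index=list("abc"))
        with pytest.raises(ValueError):
            eigengene(vals, list("abc"))

    def test_small_module_rejected(self, rng):
        from stratanet.modules import ModulePartition

        labels = pd.Series([1, 1, 0], index=list("abc"))
        with pytest.raises(ValueError):
            eigengenes(pd.DataFrame(rng.normal(size=(3, 10)), index=list("abc")),
                       ModulePartition(labels))


class TestMergeCloseModules:
    def _expr_two_modules(self, shared_latent: bool, seed=0, n=60, size=40):
        rng = np.random.default_rng(seed)
        e1 = rng.standard_normal(n)
        e2 = e1 if shared_latent else rng.standard_normal(n)
        rho = 0.9
        block = lambda e, k: rho * e + np.sqrt(1 - rho**2) * rng.standard_normal((k, n))
        vals = np.vstack([block(e1, size), block(e2, size)])
        expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(2 * size)])
        from stratanet.modules import ModulePartition

        labels = pd.Series([1] * size + [2] * size, index=expr.index)
        return expr, ModulePartition(labels)

    def test_same_latent_modules_merge(self):
        expr, part = self._expr_two_modules(shared_latent=True)
        merged = merge_close_modules(expr, part, 0.25)
        assert merged.n_modules() == 1
        assert len(merged.merge_history) == 1

    def test_orthogonal_modules_unchanged(self):
        expr, part = self._expr_two_modules(shared_latent=False)
        merged = merge_close_modules(expr, part, 0.25)
        assert merged.n_modules() == 2

    def test_zero_threshold_is_identity(self):
        expr, part = self._expr_two_modules(shared_latent=True)
        merged = merge_close_modules(expr, part, 0.0)
        assert merged.labels.tolist() == part.labels.tolist()


class TestConsensus:
    def test_identical_toms_scale_to_identity(self, rng):
        _, tom, _ = _planted_tom(3)
        cons = consensus_tom([tom, tom.copy()])
        pd.testing.assert_frame_equal(cons, tom)

    def test_minimum_property(self, rng):
        _, tom_a, _ = _planted_tom(4)
        _, tom_b, _ = _planted_tom(5)
        cons = consensus_tom([tom_a, tom_b], scaling_quantile=0.95).to_numpy()
        iu = np.triu_indices(cons.shape[0], k=1)
        # consensus never exceeds either scaled input; scaling factors ~1 here
        q = 0.95
        qa = np.quantile(tom_a.to_numpy()[iu], q)
        qb = np.quantile(tom_b.to_numpy()[iu], q)
        scaled_b = np.clip(tom_b.to_numpy() * (qa / qb), 0, 1)
        assert (cons[iu] <= tom_a.to_numpy()[iu] + 1e-12).all()
        assert (cons[iu] <= scaled_b[iu] + 1e-12).all()

    def test_recovers_only_shared_module(self):
        design = SyntheticDesign(
            n_genes=200,
            n_samples_per_stratum={"AD-carrier": 60, "AD-noncarrier": 60},
            planted_modules=[
                PlantedModule(1, 50, ("AD-carrier",), 0.8),
                PlantedModule(2, 50, ("AD-carrier", "AD-noncarrier"), 0.8),
            ],
            seed=8,
        )
        strata, truth = generate_stratified_expression(design)
        toms, exprs = [], []
        for s in ("AD-carrier", "AD-noncarrier"):
            corr = pairwise_correlation(strata[s])
            toms.append(topological_overlap(adjacency(corr, 6)))
            exprs.append(strata[s])
        cons = consensus_modules(toms, exprs=exprs)
        shared = [g for g, m in truth["gene_module"].items() if m == 2]
        specific = [g for g, m in truth["gene_module"].items() if m == 1]
        labels_shared = cons.labels.loc[shared]
        # shared module recovered nearly intact as a single module
        top = labels_shared.value_counts().idxmax()
        assert top != 0
        assert (labels_shared == top).mean() >= 0.9
        # stratum-specific genes overwhelmingly grey
        assert (cons.labels.loc[specific] == 0).mean() >= 0.8

    def test_mismatched_gene_sets_rejected(self):
        a = _block_tom([4, 4])
        b = a.copy()
        b.index = b.columns = [f"x{i}" for i in range(8)]
        with pytest.raises(ValueError):
            consensus_tom([a, b])


class TestDetectModules:
    def test_end_to_end_partition_properties(self):
        expr, tom, truth = _planted_tom(6)
        part = detect_modules(expr, tom)
        sizes = part.sizes()
        assert (sizes >= 30).all()
        assert set(part.labels.unique()) <= set(range(0, part.n_modules() + 1))
        # labels ranked by size
        assert list(sizes.sort_values(ascending=False).index) == sorted(sizes.index)
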