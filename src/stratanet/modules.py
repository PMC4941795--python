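"""Module detection: average-linkage clustering of the TOM dissimilarity,
tree cutting with a minimum module size, module eigengenes, eigengene-based
merging, and consensus modules across strata."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import as_values

GREY = 0  # label for unassigned genes


@dataclass
class ModulePartition:
    """Gene -> module labelling. Module ids are positive integers ranked by
    decreasing size; 0 (grey) marks unassigned genes."""

    labels: pd.Series  # index = gene ids, values = int labels
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    def module_ids(self) -> list[int]:
        sizes = self.sizes()
        return sorted(sizes.index)

    def sizes(self) -> pd.Series:
        s = self.labels[self.labels != GREY].value_counts().sort_index()
        s.name = "size"
        return s

    def genes_of(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def n_modules(self) -> int:
        return len(self.sizes())

    def relabel_by_size(self) -> "ModulePartition":
        """Re-rank module ids so 1 = largest; grey stays 0. Ties break on the
        old id for determinism."""
        sizes = self.sizes()
        order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
        mapping = {old: new for new, old in enumerate(order, start=1)}
        mapping[GREY] = GREY
        return ModulePartition(self.labels.map(mapping), list(self.merge_history))


@dataclass
class ModuleEigengene:
    """First principal-component summary of a module's standardized expression.

    ``scores`` is the unit-norm per-sample score vector, with the sign fixed
    so it correlates non-negatively with the module's mean standardized
    expression. ``prop_var_explained`` is the leading eigenvalue share.
    """

    module_id: int
    scores: pd.Series
    prop_var_explained: float


def cluster_dendrogram(tom: pd.DataFrame) -> np.ndarray:
    """Average-linkage linkage matrix on the dissimilarity 1 - TOM."""
    d = 1.0 - tom.to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite dissimilarities")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def _cut_once(
    link: np.ndarray, gene_ids: list[str], cut_height: float, min_module_size: int
) -> list[list[str]]:
    flat = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for g, c in zip(gene_ids, flat):
        groups.setdefault(int(c), []).append(g)
    return [genes for genes in groups.values() if len(genes) >= min_module_size]


def dynamic_tree_cut(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height_frac: float = 0.99,
    deep_split: int = 2,
    cut_height: float | None = None,
) -> ModulePartition:
    """Cut the average-linkage dendrogram of 1 - TOM into modules.

    Static branch decomposition: the tree is cut at ``cut_height`` (by
    default ``cut_height_frac`` times the maximum merge height), branches
    with at least ``min_module_size`` members become modules, everything
    else is grey. With ``deep_split`` > 0 each module is recursively
    re-clustered and split when that yields two or more sub-branches that
    each satisfy the size minimum.
    """
    gene_ids = list(tom.index)
    if min_module_size > len(gene_ids):
        warnings.warn(
            "min_module_size exceeds the number of genes; all genes grey",
            stacklevel=2,
        )
        return ModulePartition(pd.Series(GREY, index=gene_ids, dtype=int))

    def recurse(sub_tom: pd.DataFrame, height: float | None, depth: int) -> list[list[str]]:
        ids = list(sub_tom.index)
        if len(ids) < max(2, min_module_size):
            return []
        link = cluster_dendrogram(sub_tom)
        h = height if height is not None else cut_height_frac * float(link[:, 2].max())
        modules = _cut_once(link, ids, h, min_module_size)
        if depth <= 0:
            return modules
        refined: list[list[str]] = []
        for genes in modules:
            if len(genes) >= 2 * min_module_size:
                sub = recurse(sub_tom.loc[genes, genes], None, depth - 1)
                if len(sub) >= 2:
                    refined.extend(sub)
                    continue
            refined.append(genes)
        return refined

    modules = recurse(tom, cut_height, deep_split)
    labels = pd.Series(GREY, index=gene_ids, dtype=int)
    # deterministic provisional ids: by size desc, then first gene id
    modules.sort(key=lambda genes: (-len(genes), sorted(genes)[0]))
    for mid, genes in enumerate(modules, start=1):
        labels.loc[genes] = mid
    return ModulePartition(labels)


def _standardize(vals: pd.DataFrame) -> pd.DataFrame:
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    z = vals.sub(mu, axis=0).div(sd, axis=0)
    return z


def eigengene(expr, genes, module_id: int = 0) -> ModuleEigengene:
    """Eigengene of one gene set: first left-singular vector of the
    samples x genes standardized submatrix."""
    vals = as_values(expr).loc[list(genes)]
    sd = vals.std(axis=1, ddof=1)
    ok = sd.index[(sd > 0) & sd.notna()]
    if len(ok) == 0:
        raise ValueError(f"module {module_id}: only zero-variance genes")
    z = _standardize(vals.loc[ok]).fillna(0.0)
    x = z.to_numpy().T  # samples x genes
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    me = u[:, 0]
    mean_profile = x.mean(axis=1)
    if np.dot(me, mean_profile) < 0:
        me = -me
    pve = float(s[0] ** 2 / (s**2).sum())
    return ModuleEigengene(
        module_id, pd.Series(me, index=vals.columns, name=f"ME{module_id}"), pve
    )


def eigengenes(expr, partition: ModulePartition) -> dict[int, ModuleEigengene]:
    """Eigengene for every (non-grey) module of a partition."""
    out: dict[int, ModuleEigengene] = {}
    for mid in partition.module_ids():
        genes = partition.genes_of(mid)
        if len(genes) < 3:
            raise ValueError(f"module {mid} has {len(genes)} genes; need >= 3")
        out[mid] = eigengene(expr, genes, mid)
    return out


def merge_close_modules(
    expr, partition: ModulePartition, me_diss_threshold: float = 0.25
) -> ModulePartition:
    """Iteratively merge module pairs whose eigengene dissimilarity
    1 - cor(ME_a, ME_b) falls below the threshold, recomputing eigengenes
    after every merge. The surviving id is the larger module's (ties break
    to the smaller id); labels are re-ranked by size at the end."""
    labels = partition.labels.copy()
    history = list(partition.merge_history)
    while True:
        part = ModulePartition(labels, history)
        mids = part.module_ids()
        if len(mids) < 2:
            break
        mes = eigengenes(expr, part)
        me_mat = pd.DataFrame({m: mes[m].scores for m in mids})
        diss = 1.0 - me_mat.corr()
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(mids):
            for b in mids[i + 1 :]:
                d = float(diss.loc[a, b])
                if d < me_diss_threshold and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            break
        d, a, b = best
        sizes = part.sizes()
        survive, absorb = (a, b) if (sizes[a], -a) >= (sizes[b], -b) else (b, a)
        labels[labels == absorb] = survive
        history.append((absorb, survive, d))
    return ModulePartition(labels, history).relabel_by_size()


def detect_modules(
    expr,
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height_frac: float = 0.99,
    deep_split: int = 2,
    me_diss_threshold: float = 0.25,
) -> ModulePartition:
    """Tree cut followed by eigengene merging — the per-stratum detection
    pipeline applied after TOM construction."""
    part = dynamic_tree_cut(tom, min_module_size, cut_height_frac, deep_split)
    if part.n_modules() < 2 or me_diss_threshold <= 0:
        return part.relabel_by_size()
    return merge_close_modules(expr, part, me_diss_threshold)


def consensus_tom(
    toms: list[pd.DataFrame], scaling_quantile: float = 0.95
) -> pd.DataFrame:
    """Elementwise minimum of quantile-scaled TOMs.

    Each TOM is multiplied by the factor that matches its ``scaling_quantile``
    off-diagonal quantile to the first TOM's (clipped back into [0, 1]), so
    no dataset dominates the minimum through a different overall TOM scale.
    """
    if not toms:
        raise ValueError("no TOMs given")
    ref_index = toms[0].index
    for t in toms[1:]:
        if list(t.index) != list(ref_index):
            raise ValueError("TOMs must share the same gene ids in order")
    iu = np.triu_indices(len(ref_index), k=1)
    q_ref = float(np.quantile(toms[0].to_numpy()[iu], scaling_quantile))
    cons = None
    for t in toms:
        arr = t.to_numpy(dtype=float)
        q = float(np.quantile(arr[iu], scaling_quantile))
        if q > 0 and q_ref > 0:
            arr = np.clip(arr * (q_ref / q), 0.0, 1.0)
        cons = arr if cons is None else np.minimum(cons, arr)
    np.fill_diagonal(cons, 1.0)
    return pd.DataFrame(cons, index=ref_index, columns=ref_index)


def consensus_modules(
    toms: list[pd.DataFrame],
    scaling_quantile: float = 0.95,
    min_module_size: int = 30,
    cut_height_frac: float = 0.99,
    deep_split: int = 2,
    exprs: list | None = None,
    me_diss_threshold: float = 0.25,
) -> ModulePartition:
    """Modules of the consensus (minimum of scaled) TOM across datasets.

    When the matching expression matrices are supplied, close modules are
    merged using the consensus eigengene dissimilarity (the maximum of
    1 - cor(ME) over datasets); otherwise merging is skipped.
    """
    cons = consensus_tom(toms, scaling_quantile)
    part = dynamic_tree_cut(cons, min_module_size, cut_height_frac, deep_split)
    if exprs is None or part.n_modules() < 2 or me_diss_threshold <= 0:
        return part.relabel_by_size()

    labels = part.labels.copy()
    history: list[tuple[int, int, float]] = []
    while True:
        cur = ModulePartition(labels, history)
        mids = cur.module_ids()
        if len(mids) < 2:
            break
        diss = None
        for expr in exprs:
            mes = eigengenes(expr, cur)
            me_mat = pd.DataFrame({m: mes[m].scores for m in mids})
            d = 1.0 - me_mat.corr()
            diss = d if diss is None else np.maximum(diss, d)
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(mids):
            for b in mids[i + 1 :]:
                d = float(diss.loc[a, b])
                if d < me_diss_threshold and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            break
        d, a, b = best
        sizes = cur.sizes()
        survive, absorb = (a, b) if (sizes[a], -a) >= (sizes[b], -b) else (b, a)
        labels[labels == absorb] = survive
        history.append((absorb, survive, d))
    return ModulePartition(labels, history).relabel_by_size()
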