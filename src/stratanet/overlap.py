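"""Cross-disease module overlap and time-course co-expression validation.

Disease-specific module gene sets from two studies are compared with
upper-tail hypergeometric tests over a declared common gene universe;
clique co-expression is validated quantitatively as the mean absolute
pairwise Pearson correlation across time-course profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import TimeCourseMatrix


@dataclass
class OverlapResult:
    N: int  # universe size
    m: int  # module size (collection a)
    n: int  # module size (collection b)
    x: int  # overlap count
    p: float  # P(X >= x), upper-tail hypergeometric
    p_adjusted: float | None = None


def hypergeometric_overlap(N: int, m: int, n: int, x: int) -> OverlapResult:
    """Upper-tail hypergeometric probability of an overlap at least x.

    p = sum_{j=x}^{min(m,n)} C(m, j) C(N - m, n - j) / C(N, n), evaluated
    in log space by scipy's hypergeometric survival function.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError("module sizes must lie in [0, N]")
    if not (0 <= x <= min(m, n)):
        raise ValueError("overlap x must lie in [0, min(m, n)]")
    p = float(stats.hypergeom.sf(x - 1, N, m, n))
    return OverlapResult(N, m, n, x, min(p, 1.0))


def compare_disease_modules(
    modules_a: dict[str, set],
    modules_b: dict[str, set],
    universe,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """All pairwise overlaps between two module collections.

    Both collections must be drawn from ``universe``; genes outside it are
    an error, not silently dropped. Returns one row per pair with the
    hypergeometric p, the multiplicity-adjusted p (Bonferroni by default,
    Benjamini-Hochberg optional) and, for significant pairs, the
    overlapping gene ids.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    for name, coll in (("a", modules_a), ("b", modules_b)):
        for mid, genes in coll.items():
            extra = set(genes) - universe
            if extra:
                raise ValueError(
                    f"collection {name} module {mid!r} has genes outside the "
                    f"universe: {sorted(extra)[:5]}"
                )
    rows = []
    for ida, ga in modules_a.items():
        for idb, gb in modules_b.items():
            inter = set(ga) & set(gb)
            res = hypergeometric_overlap(len(universe), len(ga), len(gb), len(inter))
            rows.append(
                {"module_a": ida, "module_b": idb, "N": res.N, "m": res.m,
                 "n": res.n, "x": res.x, "p": res.p,
                 "overlap_genes": sorted(inter)}
            )
    table = pd.DataFrame(rows)
    n_tests = len(table)
    if adjust == "bonferroni":
        table["p_adjusted"] = (table["p"] * n_tests).clip(upper=1.0)
    elif adjust == "bh":
        order = np.argsort(table["p"].to_numpy())
        q = np.empty(n_tests)
        prev = 1.0
        for rank, idx in list(enumerate(order, start=1))[::-1]:
            prev = min(prev, table["p"].iloc[idx] * n_tests / rank)
            q[idx] = prev
        table["p_adjusted"] = q
    else:
        raise ValueError("adjust must be 'bonferroni' or 'bh'")
    table["significant"] = table["p_adjusted"] < alpha
    table.loc[~table["significant"], "overlap_genes"] = table.loc[
        ~table["significant"], "overlap_genes"
    ].apply(lambda _: [])
    return table


def timecourse_coexpression(
    tc: TimeCourseMatrix, gene_subset=None
) -> tuple[pd.DataFrame, float, int]:
    """Pairwise Pearson correlation of time-course profiles.

    Correlations are computed across the replicate-mean timepoint values of
    each gene pair; the summary is the mean of |r| over all defined pairs.
    Constant profiles have no defined correlation: such pairs are excluded
    from the mean and counted.

    Returns (correlation matrix, mean |r|, number of excluded pairs).
    """
    vals = tc.values if gene_subset is None else tc.values.loc[list(gene_subset)]
    if vals.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    if vals.shape[1] < 3:
        raise ValueError("need >= 3 timepoints")
    x = vals.to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    m = x.shape[0]
    iu = np.triu_indices(m, k=1)
    flat = corr[iu]
    const_pair = (sd[iu[0]] == 0) | (sd[iu[1]] == 0)
    defined = np.isfinite(flat) & ~const_pair
    n_excluded = int((~defined).sum())
    if not defined.any():
        raise ValueError("no gene pair has a defined correlation")
    mean_abs_r = float(np.abs(flat[defined]).mean())
    corr_df = pd.DataFrame(corr, index=vals.index, columns=vals.index)
    return corr_df, mean_abs_r, n_excluded
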