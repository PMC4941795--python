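"""Stratum-specificity calls for co-expression modules.

A module detected in one stratum is called SPECIFIC when (a) it matches no
module of either relevant consensus partition (Fisher-exact cross-tabulation,
Bonferroni-corrected) and (b) its permutation preservation statistic
Z_summary is below 2 in both comparison strata. Z_summary > 10 signals
strong preservation (no specificity); the 2-10 band is intermediate.
Subsampling replication (50% / 75% of samples, five runs each, >80% module
overlap required) and a covariate-adjusted differential eigengene test
complete the evidence trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import as_values
from .modules import (
    ModulePartition,
    detect_modules,
    eigengene,
)
from .network import adjacency, pairwise_correlation, topological_overlap

Z_WEAK = 2.0
Z_STRONG = 10.0


# ---------------------------------------------------------------------------
# cross-tabulation matching


def crosstab_match(
    partition_a: ModulePartition,
    partition_b: ModulePartition,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[int, bool]]:
    """Fisher-exact overlap of every module pair across two partitions.

    Returns the pair table (module_a, module_b, overlap, p) and, per module
    of ``partition_a``, whether it matched any module of ``partition_b`` at
    the Bonferroni-corrected threshold alpha / n_pairs.
    """
    genes_a = set(partition_a.gene_ids)
    genes_b = set(partition_b.gene_ids)
    universe = sorted(genes_a & genes_b)
    if not universe:
        raise ValueError("partitions share no genes")
    la = partition_a.labels.loc[universe]
    lb = partition_b.labels.loc[universe]
    mids_a = partition_a.module_ids()
    mids_b = partition_b.module_ids()
    if not mids_a:
        raise ValueError("partition_a has no modules")
    n = len(universe)
    rows = []
    for a in mids_a:
        in_a = la == a
        m = int(in_a.sum())
        for b in mids_b:
            in_b = lb == b
            k = int(in_b.sum())
            x = int((in_a & in_b).sum())
            table = [[x, m - x], [k - x, n - m - k + x]]
            p = stats.fisher_exact(table, alternative="greater")[1]
            rows.append({"module_a": a, "module_b": b, "overlap": x, "p": float(p)})
    pairs = pd.DataFrame(rows, columns=["module_a", "module_b", "overlap", "p"])
    n_pairs = max(len(pairs), 1)
    threshold = alpha / n_pairs
    matched = {
        a: bool((pairs.loc[pairs["module_a"] == a, "p"] < threshold).any())
        for a in mids_a
    }
    return pairs, matched


# ---------------------------------------------------------------------------
# permutation Z_summary preservation


@dataclass
class PreservationReport:
    module_id: int
    z_density: float
    z_connectivity: float
    z_summary: float
    n_permutations: int
    statistics: pd.DataFrame  # per statistic: observed, perm mean, perm sd, Z

    @property
    def specificity_class(self) -> str:
        """strong (Z<2) / modest (2<=Z<=10) / none (Z>10) specificity."""
        if self.z_summary < Z_WEAK:
            return "strong"
        if self.z_summary <= Z_STRONG:
            return "modest"
        return "none"


_DENSITY = ("mean_adj", "mean_abs_kme", "prop_var_explained")
_CONNECTIVITY = ("cor_kim", "cor_kme", "cor_cor")


def _preservation_stats(
    ref: np.ndarray, test: np.ndarray, beta: int
) -> dict[str, float]:
    """The six preservation statistics for one gene set.

    ``ref`` and ``test`` are genes x samples arrays restricted to the set.
    Density statistics are computed in the test data; connectivity
    statistics correlate reference-derived and test-derived per-gene
    quantities.
    """

    def net(x: np.ndarray):
        c = np.corrcoef(x)
        a = np.abs(c) ** beta
        np.fill_diagonal(a, 1.0)
        kim = a.sum(axis=0) - 1.0
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        u, s, _ = np.linalg.svd(xs.T, full_matrices=False)
        me = u[:, 0]
        if np.dot(me, xs.T.mean(axis=1)) < 0:
            me = -me
        kme = np.array([np.corrcoef(row, me)[0, 1] for row in x])
        pve = float(s[0] ** 2 / (s**2).sum())
        return c, a, kim, kme, pve

    c_ref, _, kim_ref, kme_ref, _ = net(ref)
    c_test, a_test, kim_test, kme_test, pve_test = net(test)
    m = ref.shape[0]
    iu = np.triu_indices(m, k=1)

    def cor(u: np.ndarray, v: np.ndarray) -> float:
        if np.std(u) == 0 or np.std(v) == 0:
            return float("nan")
        return float(np.corrcoef(u, v)[0, 1])

    return {
        "mean_adj": float(a_test[iu].mean()),
        "mean_abs_kme": float(np.abs(kme_test).mean()),
        "prop_var_explained": pve_test,
        "cor_kim": cor(kim_ref, kim_test),
        "cor_kme": cor(kme_ref, kme_test),
        "cor_cor": cor(c_ref[iu], c_test[iu]),
    }


def zsummary_preservation(
    expr_ref,
    expr_test,
    module_genes,
    beta: int,
    n_perm: int = 200,
    seed: int | None = None,
    module_id: int = 0,
    min_module_size: int = 10,
) -> PreservationReport:
    """Permutation Z_summary of one module's preservation in a test stratum.

    Each observed statistic is standardized against ``n_perm`` random gene
    sets of the same size drawn from the test data's gene universe:
    Z = (obs - mean_perm) / sd_perm. Z_density and Z_connectivity are the
    medians of their three-statistic groups; Z_summary is their mean.
    """
    ref_vals = as_values(expr_ref)
    test_vals = as_values(expr_test)
    module_genes = list(module_genes)
    if len(module_genes) < min_module_size:
        raise ValueError(
            f"module has {len(module_genes)} genes; need >= {min_module_size}"
        )
    common = [g for g in ref_vals.index if g in set(test_vals.index)]
    missing = set(module_genes) - set(common)
    if missing:
        raise ValueError(f"module genes absent from a stratum: {sorted(missing)[:5]}")

    ref_arr = ref_vals.loc[common].to_numpy()
    test_arr = test_vals.loc[common].to_numpy()
    pos = {g: i for i, g in enumerate(common)}
    mod_idx = np.array([pos[g] for g in module_genes])

    observed = _preservation_stats(ref_arr[mod_idx], test_arr[mod_idx], beta)

    rng = np.random.default_rng(seed)
    m = len(mod_idx)
    perm = {name: np.empty(n_perm) for name in observed}
    for p in range(n_perm):
        idx = rng.choice(len(common), size=m, replace=False)
        st = _preservation_stats(ref_arr[idx], test_arr[idx], beta)
        for name, v in st.items():
            perm[name][p] = v

    rows = []
    zs: dict[str, float] = {}
    for name, obs in observed.items():
        vals = perm[name]
        vals = vals[np.isfinite(vals)]
        mean_p = float(vals.mean()) if vals.size else float("nan")
        sd_p = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        if not np.isfinite(obs) or not np.isfinite(sd_p) or sd_p == 0:
            warnings.warn(
                f"preservation statistic {name!r} dropped (undefined or "
                "zero permutation spread)",
                stacklevel=2,
            )
            z = float("nan")
        else:
            z = (obs - mean_p) / sd_p
            zs[name] = z
        rows.append(
            {"statistic": name, "observed": obs, "perm_mean": mean_p,
             "perm_sd": sd_p, "z": z}
        )

    def group_median(names) -> float:
        vals = [zs[n] for n in names if n in zs]
        if not vals:
            raise RuntimeError("all statistics of a group were dropped")
        return float(np.median(vals))

    z_density = group_median(_DENSITY)
    z_connectivity = group_median(_CONNECTIVITY)
    z_summary = (z_density + z_connectivity) / 2.0
    return PreservationReport(
        module_id,
        z_density,
        z_connectivity,
        z_summary,
        n_perm,
        pd.DataFrame(rows).set_index("statistic"),
    )


# ---------------------------------------------------------------------------
# specificity classification


@dataclass
class SpecificityCall:
    module_id: int
    specific: bool | None  # None = undetermined (missing evidence)
    evidence: dict = field(default_factory=dict)


def classify_specific(
    partition: ModulePartition,
    matched_in_consensus: dict[str, dict[int, bool]],
    preservation: dict[int, dict[str, PreservationReport]],
) -> list[SpecificityCall]:
    """Combine cross-tabulation and Z_summary evidence into per-module calls.

    ``matched_in_consensus`` maps a consensus-partition name to the matched
    flags from :func:`crosstab_match`; ``preservation`` maps module id ->
    comparison-stratum name -> report. A module is specific iff unmatched in
    both consensus partitions and Z_summary < 2 in both comparison strata.
    Modules with missing evidence are marked undetermined, never specific.
    """
    calls: list[SpecificityCall] = []
    for mid in partition.module_ids():
        evidence: dict = {"crosstab": {}, "z_summary": {}}
        complete = len(matched_in_consensus) >= 2
        unmatched = True
        for name, matched in matched_in_consensus.items():
            if mid not in matched:
                complete = False
                continue
            evidence["crosstab"][name] = bool(matched[mid])
            unmatched &= not matched[mid]
        reports = preservation.get(mid, {})
        if len(reports) < 2:
            complete = False
        low_z = True
        for name, rep in reports.items():
            evidence["z_summary"][name] = float(rep.z_summary)
            low_z &= rep.z_summary < Z_WEAK
        specific = (unmatched and low_z) if complete else None
        calls.append(SpecificityCall(mid, specific, evidence))
    return calls


# ---------------------------------------------------------------------------
# subsampling replication


@dataclass
class ReplicationReport:
    module_id: int
    runs: pd.DataFrame  # fraction, run, best_overlap, n_modules
    overlap_frac: float
    replicated: bool


def replicate_by_subsampling(
    expr,
    partition: ModulePartition,
    module_id: int,
    beta: int,
    fractions=(0.5, 0.75),
    runs: int = 5,
    overlap_frac: float = 0.8,
    seed: int | None = None,
    min_module_size: int = 30,
    cut_height_frac: float = 0.99,
    deep_split: int = 2,
    me_diss_threshold: float = 0.25,
    require_all_runs: bool = True,
) -> ReplicationReport:
    """Re-detect modules on random sample subsets and score module recovery.

    Per fraction and run, samples are drawn without replacement, the full
    detection pipeline (correlation -> adjacency -> TOM -> cut -> merge) is
    re-run, and the best single-module overlap fraction with the target
    module is recorded. Replication requires overlap > ``overlap_frac`` in
    every run at every fraction (an any-run mode is available).
    """
    vals = as_values(expr)
    module_genes = set(partition.genes_of(module_id))
    if not module_genes:
        raise ValueError(f"module {module_id} is empty")
    rng = np.random.default_rng(seed)
    records = []
    for frac in fractions:
        if not (0.0 < frac <= 1.0):
            raise ValueError("sampling fraction must be in (0, 1]")
        n_sub = max(4, int(round(frac * vals.shape[1])))
        for run in range(runs):
            cols = rng.choice(vals.shape[1], size=min(n_sub, vals.shape[1]),
                              replace=False)
            sub = vals.iloc[:, np.sort(cols)]
            try:
                corr = pairwise_correlation(sub)
                tom = topological_overlap(adjacency(corr, beta))
                part = detect_modules(
                    sub.loc[corr.index],
                    tom,
                    min_module_size=min_module_size,
                    cut_height_frac=cut_height_frac,
                    deep_split=deep_split,
                    me_diss_threshold=me_diss_threshold,
                )
                best = 0.0
                for mid in part.module_ids():
                    ov = len(module_genes & set(part.genes_of(mid))) / len(module_genes)
                    best = max(best, ov)
                records.append(
                    {"fraction": frac, "run": run, "best_overlap": best,
                     "n_modules": part.n_modules(), "failed": False}
                )
            except Exception as exc:  # a failed run counts as non-replication
                records.append(
                    {"fraction": frac, "run": run, "best_overlap": 0.0,
                     "n_modules": 0, "failed": True, "error": str(exc)}
                )
    table = pd.DataFrame(records)
    ok = table["best_overlap"] > overlap_frac
    replicated = bool(ok.all()) if require_all_runs else bool(ok.any())
    return ReplicationReport(module_id, table, overlap_frac, replicated)


# ---------------------------------------------------------------------------
# covariate-adjusted differential eigengene test


def differential_me(
    me_scores: pd.Series,
    covariates: pd.DataFrame,
    grouping: str,
) -> tuple[float, float]:
    """Linear-model test of an eigengene against phenotype or carrier status.

    Fits ME ~ grouping + (the other of phenotype/carrier) + age + sex by
    ordinary least squares and returns the grouping coefficient with its
    two-sided p-value. Collinear designs are reported via a warning.
    """
    if grouping not in ("phenotype", "carrier"):
        raise ValueError("grouping must be 'phenotype' or 'carrier'")
    cov = covariates.loc[me_scores.index]
    if cov[grouping].nunique() < 2:
        raise ValueError(f"grouping {grouping!r} has a single level")
    for level_counts in (cov[grouping].value_counts(),):
        if (level_counts < 2).any():
            raise ValueError("need >= 2 samples per group")
    other = "carrier" if grouping == "phenotype" else "phenotype"
    X = pd.DataFrame(index=me_scores.index)
    group_col = f"{grouping}_ind"
    X[group_col] = (cov[grouping] == sorted(cov[grouping].unique())[0]).astype(float)
    if cov[other].nunique() > 1:
        X[f"{other}_ind"] = (cov[other] == sorted(cov[other].unique())[0]).astype(float)
    X["age"] = cov["age"].astype(float)
    if cov["sex"].nunique() > 1:
        X["sex_ind"] = (cov["sex"] == "M").astype(float)
    X = sm.add_constant(X)
    model = sm.OLS(me_scores.astype(float), X)
    res = model.fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        warnings.warn("collinear covariates in differential-ME design", stacklevel=2)
    return float(res.params[group_col]), float(res.pvalues[group_col])
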