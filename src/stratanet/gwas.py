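"""Module-based GWAS signal enrichment.

SNP quality control (missingness > 0.1, MAF < 0.01, HWE p < 0.001 —
strict inequalities), min-P gene scoring over a +-20 kb window around each
gene boundary, a GSEA-style running-sum enrichment score assessed against a
SNP-label permutation null, the significance-proportion-based enrichment
score SPES = k/K x ES, a GSEA-style FDR across gene sets, and QQ / genomic
inflation (lambda) diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.45494...


class GwasError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# SNP quality control


def snp_qc(
    snps: pd.DataFrame,
    miss_max: float = 0.1,
    maf_min: float = 0.01,
    hwe_min: float = 0.001,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop SNPs with missing rate > miss_max, MAF < maf_min or HWE p <
    hwe_min. All inequalities are strict, so the boundary values survive
    (a missing rate of exactly 0.1 is retained). Returns the filtered table
    and per-criterion removal counts."""
    fail_miss = snps["F_MISS"] > miss_max
    fail_maf = snps["MAF"] < maf_min
    fail_hwe = snps["HWE_P"] < hwe_min
    keep = ~(fail_miss | fail_maf | fail_hwe)
    log = {
        "n_input": int(len(snps)),
        "fail_missing": int(fail_miss.sum()),
        "fail_maf": int(fail_maf.sum()),
        "fail_hwe": int(fail_hwe.sum()),
        "n_kept": int(keep.sum()),
    }
    if log["n_kept"] == 0:
        raise GwasError("no SNP passes quality control")
    return snps.loc[keep].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# gene scoring


@dataclass
class SnpAssignment:
    """Precomputed SNP -> gene assignment for fast permutation rescoring.

    ``snp_idx`` concatenates, gene by gene, the row indices (into the SNP
    table) of the SNPs assigned to each gene; ``offsets`` marks each gene's
    segment start, so per-gene maxima are one ``np.maximum.reduceat`` away.
    """

    gene_ids: list[str]
    snp_idx: np.ndarray
    offsets: np.ndarray
    n_snps: int

    def gene_scores(self, p: np.ndarray) -> np.ndarray:
        """max -log10(p) per gene for one p-value column."""
        neglogp = -np.log10(p)
        return np.maximum.reduceat(neglogp[self.snp_idx], self.offsets)


def build_snp_assignment(
    snps: pd.DataFrame, gene_map: pd.DataFrame, window_bp: int = 20_000
) -> SnpAssignment:
    """Assign each SNP to every gene whose +-window envelope contains it.

    A SNP at position bp belongs to gene g iff start_g - window <= bp <=
    end_g + window (inclusive both ends, 1-based coordinates). A SNP may
    score several overlapping genes; genes with no assigned SNP are
    excluded from scoring.
    """
    pos = snps["BP"].to_numpy(dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    pos_sorted = pos[order]
    gene_ids: list[str] = []
    chunks: list[np.ndarray] = []
    offsets: list[int] = []
    total = 0
    for _, g in gene_map.iterrows():
        lo = int(g["start"]) - window_bp
        hi = int(g["end"]) + window_bp
        i0 = np.searchsorted(pos_sorted, lo, side="left")
        i1 = np.searchsorted(pos_sorted, hi, side="right")
        if i1 <= i0:
            continue
        gene_ids.append(str(g["gene"]))
        chunks.append(order[i0:i1])
        offsets.append(total)
        total += i1 - i0
    if not gene_ids:
        raise GwasError("no gene received any SNP")
    return SnpAssignment(
        gene_ids,
        np.concatenate(chunks),
        np.array(offsets, dtype=np.int64),
        len(snps),
    )


def map_snps_to_genes(
    snps: pd.DataFrame, gene_map: pd.DataFrame, window_bp: int = 20_000
) -> pd.DataFrame:
    """GeneScoreTable: per gene, score = max -log10(p) over assigned SNPs
    and the number of assigned SNPs."""
    assign = build_snp_assignment(snps, gene_map, window_bp)
    scores = assign.gene_scores(snps["P"].to_numpy(dtype=float))
    n_assigned = np.diff(np.append(assign.offsets, len(assign.snp_idx)))
    return pd.DataFrame(
        {"gene": assign.gene_ids, "score": scores, "n_snps": n_assigned}
    ).set_index("gene")


# ---------------------------------------------------------------------------
# enrichment score and SPES


def _ranked_order(scores: np.ndarray) -> np.ndarray:
    """Descending-score order with a deterministic tie-break on position."""
    return np.lexsort((np.arange(scores.size), -scores))


def _es_from_arrays(
    scores: np.ndarray, in_set: np.ndarray, weight_exponent: float
) -> float:
    order = _ranked_order(scores)
    hit = in_set[order]
    if not hit.any():
        raise GwasError("gene set does not intersect the scored genes")
    w = np.where(hit, np.abs(scores[order]) ** weight_exponent, 0.0)
    nr = w.sum()
    inc = w / nr if nr > 0 else hit / hit.sum()
    n_miss = (~hit).sum()
    dec = np.where(~hit, 1.0 / n_miss if n_miss else 0.0, 0.0)
    running = np.cumsum(inc - dec)
    return float(running.max())


def enrichment_score(
    gene_scores: pd.Series, gene_set, weight_exponent: float = 1.0
) -> float:
    """Maximum deviation of the GSEA-style running sum over the descending
    gene-score ranking: in-set genes add score^weight (normalized over set
    members), all others subtract 1/(N - m). ``weight_exponent = 0`` gives
    the rank-only statistic."""
    scores = gene_scores.to_numpy(dtype=float)
    in_set = gene_scores.index.isin(set(gene_set))
    return _es_from_arrays(scores, in_set, weight_exponent)


def significant_mask(scores: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Top-alpha fraction of gene scores (rank-based, deterministic)."""
    n_sig = max(1, int(np.ceil(alpha * scores.size)))
    order = _ranked_order(scores)
    mask = np.zeros(scores.size, dtype=bool)
    mask[order[:n_sig]] = True
    return mask


def spes(es: float, k: float, K: float) -> float:
    """SPES = k/K x ES, with k (K) the proportion of significant genes in
    the set (genome-wide)."""
    if K <= 0:
        raise GwasError("K = 0: no significant genes genome-wide")
    return k / K * es


@dataclass
class EnrichmentResult:
    gene_set_id: str
    es: float
    k: float
    K: float
    spes_value: float
    p_value: float
    n_perm: int
    fdr_q: float | None = None
    perm_spes: np.ndarray | None = None


def _observed_and_perm_spes(
    p: np.ndarray,
    assign: SnpAssignment,
    set_mask: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float,
    weight_exponent: float,
) -> tuple[float, float, float, float, np.ndarray]:
    def one(pvec: np.ndarray) -> tuple[float, float, float, float]:
        scores = assign.gene_scores(pvec)
        es = _es_from_arrays(scores, set_mask, weight_exponent)
        sig = significant_mask(scores, alpha)
        k = float(sig[set_mask].mean())
        K = float(sig.mean())
        return es, k, K, spes(es, k, K)

    es_obs, k_obs, K_obs, spes_obs = one(p)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = one(rng.permutation(p))[3]
    return es_obs, k_obs, K_obs, spes_obs, perm


def permutation_test(
    snps: pd.DataFrame,
    gene_map: pd.DataFrame,
    gene_set,
    n_perm: int = 1000,
    seed: int | None = None,
    window_bp: int = 20_000,
    alpha: float = 0.05,
    weight_exponent: float = 1.0,
    gene_set_id: str = "set",
    assignment: SnpAssignment | None = None,
) -> EnrichmentResult:
    """SNP-label permutation test of one gene set's enrichment.

    Each permutation shuffles the association p-values over SNP labels
    (keeping the SNP -> gene assignment, hence per-gene SNP counts, fixed),
    recomputes gene scores, significance flags, ES and SPES. The reported
    p-value uses the +1 smoothing convention
    p = (1 + #{SPES* >= SPES_obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values are coarse", stacklevel=2)
    assign = assignment or build_snp_assignment(snps, gene_map, window_bp)
    set_mask = np.isin(np.array(assign.gene_ids), list(gene_set))
    if not set_mask.any():
        raise GwasError("gene set does not intersect the scored genes")
    rng = np.random.default_rng(seed)
    p = snps["P"].to_numpy(dtype=float)
    es, k, K, spes_obs, perm = _observed_and_perm_spes(
        p, assign, set_mask, n_perm, rng, alpha, weight_exponent
    )
    p_value = (1.0 + float((perm >= spes_obs).sum())) / (1.0 + n_perm)
    return EnrichmentResult(
        gene_set_id, es, k, K, spes_obs, p_value, n_perm, perm_spes=perm
    )


def fdr_across_sets(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """GSEA-style FDR over several gene sets.

    Observed and permutation SPES values are normalized per set by the mean
    positive permutation SPES; q for a set is the ratio of the pooled
    permutation exceedance proportion to the observed exceedance proportion
    at its normalized score, clipped to [0, 1].
    """
    if not results:
        return results
    nes_obs, nes_perm_all = [], []
    for r in results:
        if r.perm_spes is None:
            raise GwasError("permutation distributions required for FDR")
        pos = r.perm_spes[r.perm_spes > 0]
        norm = pos.mean() if pos.size else 1.0
        nes_obs.append(r.spes_value / norm)
        nes_perm_all.append(r.perm_spes / norm)
    pooled = np.concatenate(nes_perm_all)
    nes_obs_arr = np.array(nes_obs)
    for r, nes in zip(results, nes_obs):
        num = float((pooled >= nes).mean())
        den = float((nes_obs_arr >= nes).mean())
        r.fdr_q = float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))
    return results


# ---------------------------------------------------------------------------
# QQ / lambda diagnostics


@dataclass
class QQReport:
    observed: np.ndarray  # ranked observed -log10 p (descending p-rank 1 = smallest p)
    expected: np.ndarray  # -log10[i / (L + 1)]
    lam: float
    method: str
    n: int


def qq_lambda(
    p_values, subset=None, method: str = "median"
) -> QQReport:
    """Comparative QQ data and the genomic dispersion factor lambda.

    ``method='median'``: lambda = median(qchisq_1df(1 - p)) / 0.45494.
    ``method='regression'``: slope through the origin of the sorted observed
    1-df chi-square statistics on their expected null quantiles.

    With ``subset`` (a boolean mask or positional indices into
    ``p_values``), the subset's points are reported against the all-gene
    expectation: each subset p keeps the expected order statistic
    -log10[i/(L+1)] of its rank i among ALL L p-values, and lambda is
    computed from the subset's statistics alone.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 20:
        warnings.warn("fewer than 20 p-values; lambda is unstable", stacklevel=2)

    L = p.size
    ranks_all = stats.rankdata(p, method="ordinal")  # 1 = smallest p
    if subset is None:
        sel = np.ones(L, dtype=bool)
    else:
        sel = np.zeros(L, dtype=bool)
        sel[np.asarray(subset)] = True

    p_sel = p[sel]
    order = np.argsort(p_sel)
    observed = -np.log10(p_sel[order])
    expected = -np.log10(ranks_all[sel][order] / (L + 1.0))

    chi = stats.chi2.isf(p_sel, 1)
    if method == "median":
        lam = float(np.median(chi) / CHI2_MEDIAN_1DF)
    elif method == "regression":
        n = chi.size
        exp_q = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, 1)
        obs_q = np.sort(chi)
        lam = float((exp_q @ obs_q) / (exp_q @ exp_q))
    else:
        raise ValueError("method must be 'median' or 'regression'")
    return QQReport(observed, expected, lam, method, int(p_sel.size))
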