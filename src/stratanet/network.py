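"""Weighted co-expression network construction.

Pearson correlations over all gene pairs, soft-threshold (power) selection
against an approximate scale-free topology criterion, the powered adjacency
a_ij = |r_ij|^beta (or the signed variant), and the topological overlap
matrix

    TOM_ij = (sum_{u != i,j} a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

whose complement 1 - TOM is the clustering dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import as_values


@dataclass
class SoftThreshold:
    """Chosen soft-threshold power and its scale-free fit diagnostics."""

    beta: int
    fit_r2: float
    mean_connectivity: float
    fallback: bool = False  # True when no candidate reached the target fit

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")


def pairwise_correlation(expr) -> pd.DataFrame:
    """Pearson correlation for all gene pairs (genes x genes DataFrame).

    Missing entries are excluded pairwise. Genes with zero variance have no
    defined correlation; they are dropped with a warning.
    """
    vals = as_values(expr)
    if vals.shape[1] < 4:
        raise ValueError("need >= 4 samples for correlation")
    sd = vals.std(axis=1, ddof=1)
    zero_var = sd.index[(sd == 0) | sd.isna()]
    if len(zero_var) > 0:
        warnings.warn(
            f"dropping {len(zero_var)} zero-variance gene(s): "
            f"{list(zero_var)[:5]}",
            stacklevel=2,
        )
        vals = vals.drop(index=zero_var)
    if vals.isna().any().any():
        corr = vals.T.corr(min_periods=3)
    else:
        c = np.corrcoef(vals.to_numpy())
        corr = pd.DataFrame(c, index=vals.index, columns=vals.index)
    np.fill_diagonal(corr.values, 1.0)
    return corr.clip(-1.0, 1.0)


def adjacency(corr: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Powered adjacency. Unsigned: |r|^beta; signed: ((1 + r) / 2)^beta.

    The diagonal is set to 1. A high beta keeps strong co-expression close
    to 1 while pushing weak correlations toward 0.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if signed:
        a = ((1.0 + corr) / 2.0) ** beta
    else:
        a = corr.abs() ** beta
    a = a.copy()
    np.fill_diagonal(a.values, 1.0)
    return a


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> tuple[float, float]:
    """R^2 of log10(freq) vs log10(k) over linear connectivity bins.

    Returns (fit_r2, mean_connectivity); fit_r2 is NaN when the fit is
    undefined (degenerate connectivity or fewer than 3 occupied bins).
    """
    a = adj.to_numpy()
    k = a.sum(axis=0) - np.diag(a)
    mean_k = float(k.mean())
    if k.max() <= 0 or np.isclose(k.max(), k.min()):
        return float("nan"), mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        kb = float(k[mask].mean())
        if kb <= 0:
            continue
        xs.append(np.log10(kb))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return float("nan"), mean_k
    res = stats.linregress(xs, ys)
    return float(res.rvalue**2), mean_k


def pick_soft_threshold(
    corr: pd.DataFrame,
    candidate_betas=range(1, 21),
    target_r2: float = 0.8,
    signed: bool = False,
    n_bins: int = 10,
) -> SoftThreshold:
    """Smallest power whose scale-free fit reaches ``target_r2``.

    If no candidate qualifies the power with the best (largest) defined fit
    is returned with ``fallback=True``; if the fit is undefined for every
    candidate (e.g. a constant correlation matrix) the smallest candidate is
    returned, also flagged, with a warning.
    """
    candidates = list(candidate_betas)
    if not candidates:
        raise ValueError("candidate beta list is empty")
    fits: list[tuple[int, float, float]] = []
    for beta in candidates:
        r2, mean_k = scale_free_fit(adjacency(corr, beta, signed=signed), n_bins)
        fits.append((beta, r2, mean_k))
        if np.isfinite(r2) and r2 >= target_r2:
            return SoftThreshold(beta, r2, mean_k)
    defined = [f for f in fits if np.isfinite(f[1])]
    if defined:
        beta, r2, mean_k = max(defined, key=lambda f: f[1])
        warnings.warn(
            f"no power reached scale-free fit {target_r2}; "
            f"using beta={beta} with fit_r2={r2:.3f}",
            stacklevel=2,
        )
        return SoftThreshold(beta, r2, mean_k, fallback=True)
    beta, r2, mean_k = fits[0]
    warnings.warn(
        "scale-free fit undefined for all candidate powers; "
        f"falling back to beta={beta}",
        stacklevel=2,
    )
    return SoftThreshold(beta, float("nan"), mean_k, fallback=True)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a [0, 1] adjacency with unit diagonal.

    The shared-neighbor sum excludes u in {i, j}; the diagonal is 1 and
    TOM_ij lies in [0, 1].
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    # (A @ A)_ij counts u = i and u = j, each contributing a_ij (unit diag)
    shared = a @ a - 2.0 * a
    k = a.sum(axis=0) - 1.0
    k_min = np.minimum.outer(k, k)
    denom = k_min + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom[denom <= 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def tom_dissimilarity(tom: pd.DataFrame) -> pd.DataFrame:
    return 1.0 - tom
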