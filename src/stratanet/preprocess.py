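"""Pre-network filtering, outlier removal and stratification.

The order mirrors the study protocol: drop transcripts detected in less
than 90% of the case or of the control series, iteratively remove arrays
whose average inter-subject correlation falls more than 2 SD below the
mean, then split into the four phenotype x carrier strata.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import STRATA, ExpressionMatrix


class PreprocessError(RuntimeError):
    pass


def filter_transcripts(
    expr: ExpressionMatrix, min_detect_frac: float = 0.9
) -> ExpressionMatrix:
    """Keep genes detected (non-missing) in at least ``min_detect_frac`` of
    the case samples AND of the control samples.

    The boundary is inclusive: a gene detected in exactly 90% of cases is
    retained (the exclusion rule is "detected in less than 90%"). Gene order
    is preserved. Idempotent.
    """
    if not (0.0 < min_detect_frac <= 1.0):
        raise ValueError("min_detect_frac must be in (0, 1]")
    is_case = expr.covariates["phenotype"] == "case"
    case_ids = expr.covariates.index[is_case]
    ctrl_ids = expr.covariates.index[~is_case]

    keep = pd.Series(True, index=expr.values.index)
    for ids in (case_ids, ctrl_ids):
        if len(ids) == 0:
            continue
        detect_frac = expr.values[list(ids)].notna().mean(axis=1)
        keep &= detect_frac >= min_detect_frac
    if not keep.any():
        raise PreprocessError(
            "no transcript passes the detection filter "
            f"(min_detect_frac={min_detect_frac})"
        )
    return ExpressionMatrix(expr.values.loc[keep].copy(), expr.covariates.copy())


def remove_outlier_samples(
    expr: ExpressionMatrix, sd_k: float = 2.0
) -> tuple[ExpressionMatrix, list[dict]]:
    """Iteratively drop arrays with low average inter-subject correlation.

    Each round computes every sample's mean Pearson correlation with all
    other samples (pairwise-complete over genes), removes samples below
    mean - sd_k * SD of those means, and repeats until no sample qualifies.
    A zero SD round removes nothing (nothing is strictly below the mean).

    Returns the cleaned matrix and a removal log, one record per iteration.
    """
    if expr.n_samples < 4:
        raise ValueError("need >= 4 samples for outlier screening")
    current = expr
    log: list[dict] = []
    iteration = 0
    while True:
        iteration += 1
        vals = current.values
        if vals.isna().any().any():
            corr = vals.corr(min_periods=3)  # samples x samples, pairwise complete
        else:
            c = np.corrcoef(vals.to_numpy().T)
            corr = pd.DataFrame(c, index=vals.columns, columns=vals.columns)
        n = corr.shape[0]
        mean_r = (corr.sum(axis=1) - np.diag(corr.to_numpy())) / (n - 1)
        mu, sd = float(mean_r.mean()), float(mean_r.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            break
        cutoff = mu - sd_k * sd
        drop = mean_r.index[mean_r < cutoff]
        if len(drop) == 0:
            break
        if n - len(drop) <= 2:
            raise PreprocessError(
                f"outlier removal would leave {n - len(drop)} samples"
            )
        log.append(
            {
                "iteration": iteration,
                "removed": list(drop),
                "cutoff": cutoff,
                "mean_r": {s: float(mean_r[s]) for s in drop},
            }
        )
        keep = [s for s in current.sample_ids if s not in set(drop)]
        current = current.subset_samples(keep)
    return current, log


def stratify(expr: ExpressionMatrix) -> dict[str, ExpressionMatrix]:
    """Partition samples into the four phenotype x carrier strata.

    Every input sample lands in exactly one stratum and the gene set is
    identical across strata. Strata with fewer than 4 samples trigger a
    warning (they are unusable for network construction); empty strata are
    omitted from the result.
    """
    labels = expr.strata()
    out: dict[str, ExpressionMatrix] = {}
    for stratum in STRATA:
        ids = list(labels.index[labels == stratum])
        if len(ids) < 4:
            warnings.warn(
                f"stratum {stratum!r} has {len(ids)} samples (< 4); "
                "excluded from network construction",
                stacklevel=2,
            )
        if ids:
            out[stratum] = expr.subset_samples(ids)
    return out
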