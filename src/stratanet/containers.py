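"""Core in-memory containers shared across the pipeline.

Expression data travel as an :class:`ExpressionMatrix`: a genes x samples
matrix of log-scale values (NaN = missing) joined with per-sample covariates
(phenotype, APOE e4 carrier status, age, sex). Every network stage consumes
this object or a plain genes x samples :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The four analysis strata: phenotype (case = AD, control) x APOE e4 carriage.
STRATA = ("AD-carrier", "AD-noncarrier", "CTRL-carrier", "CTRL-noncarrier")

REQUIRED_COVARIATES = ("phenotype", "carrier", "age", "sex")

PHENOTYPES = ("case", "control")
CARRIER_LEVELS = ("yes", "no")
SEX_LEVELS = ("M", "F")


def stratum_of(phenotype: str, carrier: str) -> str:
    """Map a (phenotype, carrier) covariate pair to its stratum name."""
    if phenotype not in PHENOTYPES or carrier not in CARRIER_LEVELS:
        raise ValueError(f"unknown covariate levels: {phenotype!r}, {carrier!r}")
    prefix = "AD" if phenotype == "case" else "CTRL"
    suffix = "carrier" if carrier == "yes" else "noncarrier"
    return f"{prefix}-{suffix}"


@dataclass
class ExpressionMatrix:
    """Genes x samples log-expression with per-sample covariates.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns = sample ids. Missing entries
        are NaN (they are carried as missing, never imputed here).
    covariates
        DataFrame indexed by sample id with columns ``phenotype`` (case /
        control), ``carrier`` (yes / no), ``age`` (years) and ``sex`` (M / F).
    """

    values: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids")
        missing_cov = set(self.values.columns) - set(self.covariates.index)
        if missing_cov:
            raise ValueError(
                f"samples without covariates: {sorted(missing_cov)[:5]}"
            )
        for col in REQUIRED_COVARIATES:
            if col not in self.covariates.columns:
                raise ValueError(f"covariate column missing: {col!r}")
            if self.covariates[col].isna().any():
                bad = self.covariates.index[self.covariates[col].isna()]
                raise ValueError(
                    f"covariate {col!r} missing for sample {bad[0]!r}"
                )
        # keep covariates aligned to the sample order of the matrix
        self.covariates = self.covariates.loc[list(self.values.columns)]

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[sample_ids].copy(), self.covariates.loc[sample_ids].copy()
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)].copy(), self.covariates.copy()
        )

    def strata(self) -> pd.Series:
        """Per-sample stratum labels derived from phenotype x carrier."""
        return pd.Series(
            [
                stratum_of(p, c)
                for p, c in zip(self.covariates["phenotype"], self.covariates["carrier"])
            ],
            index=self.covariates.index,
            name="stratum",
        )


def as_values(expr) -> pd.DataFrame:
    """Accept an ExpressionMatrix or a genes x samples DataFrame."""
    if isinstance(expr, ExpressionMatrix):
        return expr.values
    if isinstance(expr, pd.DataFrame):
        return expr
    raise TypeError(f"expected ExpressionMatrix or DataFrame, got {type(expr)}")


def child_seed(seed_seq: np.random.SeedSequence | int, index: int) -> int:
    """Deterministic 31-bit sub-seed for stage ``index`` of a run.

    All stochastic stages derive their seeds this way from the global run
    seed, so stage-level reruns reproduce exactly.
    """
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(int(seed_seq))
    child = seed_seq.spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))
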