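import numpy as np
import pandas as pd
import pytest

from stratanet.containers import ExpressionMatrix
from stratanet.synthetic import (
    PlantedModule,
    SyntheticDesign,
    generate_stratified_expression,
)


def make_expr(values: np.ndarray, phenotypes=None, carriers=None, gene_ids=None,
              sample_ids=None, ages=None, sexes=None) -> ExpressionMatrix:
    """Construct an ExpressionMatrix from a raw array with minimal covariates."""
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    phenotypes = phenotypes or ["case"] * (n_samples // 2) + ["control"] * (
        n_samples - n_samples // 2
    )
    carriers = carriers or ["yes", "no"] * (n_samples // 2 + 1)
    sexes = sexes or ["M", "F"] * (n_samples // 2 + 1)
    cov = pd.DataFrame(
        {
            "phenotype": list(phenotypes)[:n_samples],
            "carrier": list(carriers)[:n_samples],
            "age": ages if ages is not None else np.linspace(60, 90, n_samples),
            "sex": list(sexes)[:n_samples],
        },
        index=pd.Index(sample_ids),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), cov
    )


def preservation_pair(seed: int, planted_test: bool, n_genes: int = 500,
                      module_size: int = 50, loading: float = 0.8, n: int = 60):
    """Reference/test stratum pair with one planted module; the module is
    present in the test stratum only when ``planted_test``."""
    strata_present = (
        ("AD-carrier", "AD-noncarrier") if planted_test else ("AD-carrier",)
    )
    design = SyntheticDesign(
        n_genes=n_genes,
        n_samples_per_stratum={"AD-carrier": n, "AD-noncarrier": n},
        planted_modules=[PlantedModule(1, module_size, strata_present, loading)],
        seed=seed,
    )
    strata, truth = generate_stratified_expression(design)
    module = [g for g, m in truth["gene_module"].items() if m == 1]
    return strata["AD-carrier"], strata["AD-noncarrier"], module


def random_adjacency(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random symmetric adjacency in [0, 1] with unit diagonal."""
    r = rng.uniform(0.0, 1.0, size=(n, n))
    a = (r + r.T) / 2.0
    np.fill_diagonal(a, 1.0)
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Naive triple-loop topological overlap, the independent reference."""
    n = a.shape[0]
    k = a.sum(axis=0) - np.diag(a)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


@pytest.fixture
def rng():
    return np.random.default_rng(20160712)
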