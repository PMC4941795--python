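"""Hub-gene ranking and complete-graph (clique) detection.

Hubs combine two centrality measures: intramodular connectivity kIM (the
sum of a gene's within-module adjacencies) and module membership kME (the
correlation of the gene's profile with the module eigengene). The top hubs
are then screened for a complete subgraph under a pairwise-correlation edge
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import as_values
from .modules import ModuleEigengene, ModulePartition


def intramodular_connectivity(
    adj: pd.DataFrame, partition: ModulePartition, module_id: int
) -> pd.Series:
    """kIM_i = sum over module co-members j != i of a_ij."""
    genes = partition.genes_of(module_id)
    if len(genes) < 2:
        raise ValueError(f"module {module_id} has < 2 genes")
    missing = set(genes) - set(adj.index)
    if missing:
        raise ValueError(f"genes outside adjacency: {sorted(missing)[:5]}")
    sub = adj.loc[genes, genes].to_numpy(dtype=float)
    kim = sub.sum(axis=0) - np.diag(sub)
    return pd.Series(kim, index=genes, name="kIM")


def module_membership(expr, me: ModuleEigengene) -> pd.Series:
    """kME_i = Pearson correlation of gene i's profile with the eigengene."""
    vals = as_values(expr)
    scores = me.scores.loc[vals.columns].to_numpy()
    x = vals.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = x - x.mean(axis=1, keepdims=True)
        sc = scores - scores.mean()
        kme = (xc @ sc) / (np.sqrt((xc**2).sum(axis=1) * (sc**2).sum()))
    bad = (sd == 0) | ~np.isfinite(kme)
    if bad.any():
        warnings.warn(
            f"kME undefined for {int(bad.sum())} zero-variance gene(s)", stacklevel=2
        )
        kme[bad] = np.nan
    return pd.Series(kme, index=vals.index, name="kME")


def select_hubs(
    kim: pd.Series,
    kme: pd.Series,
    n_hubs: int | None = None,
    quantile: float = 0.05,
    min_hubs: int = 5,
) -> pd.DataFrame:
    """Rank module genes by the sum of their kIM rank and |kME| rank.

    Returns the hub table (gene, kIM, kME, rank) for the top ``n_hubs``
    genes (default: top ``quantile`` of the module size, at least
    ``min_hubs``). Ties break lexicographically on gene id, so the
    selection is deterministic.
    """
    genes = list(kim.index)
    if not genes:
        raise ValueError("module is empty")
    if n_hubs is None:
        n_hubs = max(min_hubs, int(np.ceil(quantile * len(genes))))
    if n_hubs > len(genes):
        warnings.warn(
            f"n_hubs={n_hubs} exceeds module size {len(genes)}; returning all",
            stacklevel=2,
        )
        n_hubs = len(genes)
    table = pd.DataFrame({"kIM": kim, "kME": kme.loc[genes]})
    # high kIM and high |kME| -> low rank numbers; average ranks on ties
    r = table["kIM"].rank(ascending=False) + table["kME"].abs().rank(ascending=False)
    table["rank_score"] = r
    table = table.loc[
        sorted(table.index, key=lambda g: (table.at[g, "rank_score"], g))
    ]
    table["rank"] = range(1, len(table) + 1)
    return table.head(n_hubs)


def build_hub_graph(
    expr, hub_genes, r_threshold: float = 0.5, adj: pd.DataFrame | None = None
) -> nx.Graph:
    """Undirected graph over hub genes; edge iff |Pearson r| >= threshold
    in the stratum's data (or adjacency >= threshold when ``adj`` given)."""
    hub_genes = sorted(hub_genes)
    g = nx.Graph()
    g.add_nodes_from(hub_genes)
    if adj is not None:
        weights = adj.loc[hub_genes, hub_genes]
    else:
        vals = as_values(expr).loc[hub_genes]
        weights = pd.DataFrame(
            np.abs(np.corrcoef(vals.to_numpy())), index=hub_genes, columns=hub_genes
        )
    for i, a in enumerate(hub_genes):
        for b in hub_genes[i + 1 :]:
            w = float(weights.loc[a, b])
            if w >= r_threshold:
                g.add_edge(a, b, weight=w)
    return g


@dataclass
class CliqueResult:
    is_complete: bool
    max_clique: tuple[str, ...]


def detect_complete_graph(graph: nx.Graph) -> CliqueResult:
    """Exact maximum clique of a small hub graph.

    ``is_complete`` is True when every node pair is connected. The maximum
    clique is found by exact enumeration (Bron-Kerbosch); among maximum
    cliques the lexicographically smallest sorted gene tuple is returned,
    so the result is deterministic.
    """
    n = graph.number_of_nodes()
    if n > 64:
        raise ValueError("exact clique search limited to <= 64 nodes")
    if n == 0:
        return CliqueResult(False, ())
    is_complete = graph.number_of_edges() == n * (n - 1) // 2
    best: tuple[int, tuple[str, ...]] | None = None
    for clique in nx.find_cliques(graph):
        key = (-len(clique), tuple(sorted(clique)))
        if best is None or key < best:
            best = key
    return CliqueResult(is_complete, best[1])
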