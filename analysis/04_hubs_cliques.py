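#!/usr/bin/env python
"""Rank hub genes of the specific modules and search for complete graphs.

Hubs combine intramodular connectivity (kIM) and module membership (kME);
the top hubs are screened for a complete subgraph under the pairwise
|Pearson r| >= 0.5 edge rule. Writes hub tables and clique edge lists.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from stratanet.hubs import (
    build_hub_graph,
    detect_complete_graph,
    intramodular_connectivity,
    module_membership,
    select_hubs,
)
from stratanet.io import read_expression_tsv
from stratanet.modules import ModulePartition, eigengene
from stratanet.network import adjacency, pairwise_correlation

BETA = 6


def main() -> None:
    warnings.simplefilter("ignore")
    mod_dir = RESULTS / "specificity"
    out = RESULTS / "hubs"
    out.mkdir(parents=True, exist_ok=True)

    calls = json.loads((mod_dir / "specificity_calls.json").read_text())
    for stratum, entries in calls.items():
        expr = read_expression_tsv(
            RESULTS / "modules" / f"expr_{stratum}.tsv",
            RESULTS / "modules" / f"cov_{stratum}.tsv",
        )
        part = ModulePartition(
            pd.read_csv(RESULTS / "modules" / f"partition_{stratum}.tsv",
                        sep="\t", index_col=0)["module"]
        )
        adj = adjacency(pairwise_correlation(expr), BETA)
        for entry in entries:
            if not entry["specific"]:
                continue
            mid = entry["module"]
            genes = part.genes_of(mid)
            kim = intramodular_connectivity(adj, part, mid)
            me = eigengene(expr.subset_genes(genes), genes, mid)
            kme = module_membership(expr.subset_genes(genes), me)
            hubs = select_hubs(kim, kme)
            hubs.to_csv(out / f"hubs_{stratum}_M{mid}.tsv", sep="\t")
            graph = build_hub_graph(expr, list(hubs.index), r_threshold=0.5)
            clique = detect_complete_graph(graph)
            edges = pd.DataFrame(
                [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)],
                columns=["gene_a", "gene_b", "abs_r"],
            )
            edges.to_csv(out / f"hubgraph_{stratum}_M{mid}.tsv", sep="\t", index=False)
            print(
                f"{stratum} module {mid}: top hubs {list(hubs.index)} | "
                f"complete graph: {clique.is_complete}, "
                f"max clique {list(clique.max_clique)}"
            )


if __name__ == "__main__":
    main()
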