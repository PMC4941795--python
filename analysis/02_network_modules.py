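#!/usr/bin/env python
"""Preprocess the simulated strata and detect co-expression modules.

Reads the TSVs written by 01_simulate.py, applies the 90% detection filter
and iterative 2-SD outlier removal, builds the powered-adjacency TOM per
stratum, cuts modules in the two disease strata, and builds the three
consensus partitions. Writes partitions and network summaries.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, RESULTS

from stratanet.containers import ExpressionMatrix, STRATA
from stratanet.io import read_expression_tsv, write_json
from stratanet.modules import consensus_modules, detect_modules
from stratanet.network import adjacency, pairwise_correlation, topological_overlap
from stratanet.preprocess import filter_transcripts, remove_outlier_samples, stratify

BETA = 6
CONSENSUS_PAIRS = {
    "AD-carrier+AD-noncarrier": ("AD-carrier", "AD-noncarrier"),
    "AD-carrier+CTRL-carrier": ("AD-carrier", "CTRL-carrier"),
    "AD-noncarrier+CTRL-noncarrier": ("AD-noncarrier", "CTRL-noncarrier"),
}


def main() -> None:
    warnings.simplefilter("ignore")
    out = RESULTS / "modules"
    out.mkdir(parents=True, exist_ok=True)

    strata = {
        s: read_expression_tsv(DATA / f"expr_{s}.tsv", DATA / f"cov_{s}.tsv")
        for s in STRATA
    }
    combined = ExpressionMatrix(
        pd.concat([e.values for e in strata.values()], axis=1),
        pd.concat([e.covariates for e in strata.values()]),
    )
    filtered = filter_transcripts(combined)
    print(f"detection filter kept {filtered.n_genes}/{combined.n_genes} genes")

    networks = {}
    outliers = {}
    for s, expr in stratify(filtered).items():
        expr, log = remove_outlier_samples(expr)
        outliers[s] = [r for it in log for r in it["removed"]]
        from stratanet.io import write_expression_tsv

        write_expression_tsv(expr, out / f"expr_{s}.tsv", out / f"cov_{s}.tsv")
        corr = pairwise_correlation(expr)
        tom = topological_overlap(adjacency(corr, BETA))
        networks[s] = {"expr": expr, "tom": tom}
        print(f"{s}: {expr.n_samples} samples after outlier removal "
              f"({len(outliers[s])} removed)")
    write_json(outliers, out / "outliers.json")

    partitions = {}
    for s in ("AD-carrier", "AD-noncarrier"):
        part = detect_modules(networks[s]["expr"], networks[s]["tom"])
        partitions[s] = part
        part.labels.rename("module").to_csv(out / f"partition_{s}.tsv", sep="\t")
        print(f"{s}: {part.n_modules()} modules, sizes {dict(part.sizes())}")

    for name, (a, b) in CONSENSUS_PAIRS.items():
        cons = consensus_modules(
            [networks[a]["tom"], networks[b]["tom"]],
            exprs=[networks[a]["expr"], networks[b]["expr"]],
        )
        cons.labels.rename("module").to_csv(out / f"consensus_{name}.tsv", sep="\t")
        print(f"consensus {name}: {cons.n_modules()} modules")


if __name__ == "__main__":
    main()
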