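# stratanet

Stratified weighted gene co-expression network analysis for calling
**disease-stratum-specific modules** — built for the APOE ε4 setting in
late-onset Alzheimer's disease, where cases and controls are split by ε4
carriage into four strata and the question is which co-expression modules
exist in exactly one of them.

It is aimed at analysts who have stratified expression matrices (genes ×
samples, with phenotype/carrier/age/sex covariates), GWAS summary
statistics, and optionally qPCR-style time-course data, and who want the
whole chain from network construction to a defensible "this module is
carrier-specific" call, reproducibly and with every threshold explicit.

## What it computes

For each stratum, a weighted network `a_ij = |cor(x_i, x_j)|^β` and its
topological overlap

```
TOM_ij = (Σ_{u∉{i,j}} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)
```

whose complement is clustered (average linkage) and cut into modules with
eigengene-based merging; consensus modules across strata via the minimum of
quantile-scaled TOMs. A module is called **specific** iff it is unmatched
against both relevant consensus partitions (Fisher exact, Bonferroni) *and*
its permutation preservation statistic `Z_summary = (Z_density +
Z_connectivity)/2` stays below 2 in both comparison strata (2–10 = modest
evidence, > 10 = strongly preserved). Calls are stress-tested by 50%/75%
subsampling (five runs each, > 80% module overlap required). Specific
modules get hub rankings (intramodular connectivity kIM + module membership
kME) and an exact complete-graph/max-clique check, a GWAS signal enrichment
test (`SPES = k/K × ES` against a SNP-label permutation null with ±20 kb
min-P gene scores, QQ/λ diagnostics), cross-disease hypergeometric overlap,
and time-course co-expression validation. A synthetic-data module plants
all of this structure with ground truth, so the whole pipeline is testable
without external data. Details: [docs/methods.md](docs/methods.md).

## Worked example

```python
from stratanet import (default_design, generate_stratified_expression,
                       PipelineConfig, run_pipeline)

cfg = PipelineConfig(seed=7, design=default_design())   # 1 carrier-only + 1 shared module
report = run_pipeline(cfg)
print(report["stages"]["modules"]["module_counts"])
print(report["stages"]["specificity"]["specific_modules"])
for call in report["stages"]["specificity"]["AD-carrier"]["calls"]:
    print(call["module"], call["specific"], call["evidence"]["z_summary"])
```

prints

```
{'AD-carrier': 2, 'AD-noncarrier': 1}
{'AD-carrier': [2], 'AD-noncarrier': []}
1 False {'AD-noncarrier': 11.528, 'CTRL-carrier': 8.692}
2 True {'AD-noncarrier': -1.34, 'CTRL-carrier': -1.555}
```

Read: both planted modules are found in the carrier stratum, the shared one
also in non-carriers. Module 2 (the one planted only in AD carriers) is
unmatched in both consensus partitions and has `Z_summary < 2` in both
comparison strata → the unique specific call; module 1 is matched and
preserved (`Z_summary` near/above the strong-preservation band) →
conserved.

The same analysis as a shell pipeline:

```bash
stratanet run-all --seed 7 --outdir results/run7      # report + summary
stratanet validate --config my_config.yaml            # schema/constraint check
```

## Analysis scripts

`analysis/` holds the numbered study drivers, each a thin narrative over
the library (`01_simulate.py` … `06_cross_disease.py`): simulate inputs,
preprocess + networks + modules + consensus, specificity calls with
replication, hub cliques, GWAS enrichment (SPES, FDR, comparative QQ/λ),
and cross-disease overlap + time-course validation. They write their
tables under `results/`; run them in order from the repository root. The
bulky intermediates (expression TSVs) are regenerated by `01`/`02` and not
kept in the repository.

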