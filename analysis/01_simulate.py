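#!/usr/bin/env python
"""Generate the synthetic study inputs and write them to results/data/.

Planted structure: a 50-gene module present only in AD APOE-e4 carriers, a
50-gene module shared by all four strata, SNP association p-values enriched
inside 40 genes, and a time course whose co-expression depends on the
treatment condition.
"""

import dataclasses
import json
import sys
import warnings

sys.path.insert(0, str(__import__("pathlib").Path(__file__).resolve().parent))
from common import DATA, SEED, study_config

from stratanet.containers import child_seed
from stratanet.io import write_assoc, write_bed, write_expression_tsv
from stratanet.synthetic import (
    generate_snp_dataset,
    generate_stratified_expression,
    generate_timecourse,
)


def main() -> None:
    warnings.simplefilter("ignore")
    cfg = study_config()
    DATA.mkdir(parents=True, exist_ok=True)

    design = dataclasses.replace(cfg.design, seed=child_seed(SEED, 0))
    strata, truth = generate_stratified_expression(design)
    for name, expr in strata.items():
        write_expression_tsv(expr, DATA / f"expr_{name}.tsv", DATA / f"cov_{name}.tsv")
        print(f"{name}: {expr.n_genes} genes x {expr.n_samples} samples")
    (DATA / "truth_expression.json").write_text(json.dumps(truth, indent=2))

    gdesign = dataclasses.replace(cfg.gwas_design, seed=child_seed(SEED, 3))
    snps, gene_map, gtruth = generate_snp_dataset(gdesign)
    write_assoc(snps, DATA / "gwas_assoc.tsv")
    write_bed(gene_map, DATA / "gwas_genes.bed")
    (DATA / "truth_gwas.json").write_text(json.dumps(gtruth, indent=2))
    print(f"GWAS: {len(snps)} SNPs, {len(gene_map)} genes, "
          f"{len(gtruth['enriched_snp_idx'])} enriched SNPs")

    tdesign = dataclasses.replace(cfg.timecourse_design, seed=child_seed(SEED, 5))
    for cond, tc in generate_timecourse(tdesign).items():
        tc.values.to_csv(DATA / f"timecourse_{cond}.tsv", sep="\t")
    print(f"time course: {len(tdesign.gene_ids)} genes x "
          f"{len(tdesign.timepoints)} timepoints x {len(tdesign.condition_coupling)} conditions")


if __name__ == "__main__":
    main()
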