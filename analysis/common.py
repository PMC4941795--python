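"""Shared configuration for the numbered analysis drivers.

One seed, one study design, one output tree: each driver reads what the
previous one wrote under results/ and adds its own tables.
"""

from pathlib import Path

from stratanet.pipeline import PipelineConfig
from stratanet.synthetic import (
    SyntheticGwasDesign,
    TimeCourseDesign,
    default_design,
    gwas_gene_ids,
)

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

ENRICHED_GENES = tuple(gwas_gene_ids(400)[:40])


def study_config() -> PipelineConfig:
    return PipelineConfig(
        seed=SEED,
        design=default_design(),
        gwas_design=SyntheticGwasDesign(
            n_snps=4000,
            n_genes=400,
            enriched_set=ENRICHED_GENES,
            signal_strength=6.0,
            frac_fail_maf=0.02,
            frac_fail_miss=0.02,
            frac_fail_hwe=0.02,
        ),
        timecourse_design=TimeCourseDesign(),
    )
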