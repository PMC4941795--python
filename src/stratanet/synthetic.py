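"""Synthetic data generators with planted, machine-readable ground truth.

Three generators emulate the statistical structure the analysis assumes:

* stratified expression matrices with co-expression modules planted in a
  chosen subset of the four phenotype x carrier strata (single-factor model,
  so the expected within-module pairwise correlation is analytic: rho^2);
* a GWAS summary-statistic table (SNP, CHR, BP, P, MAF, F_MISS, HWE_P) on a
  synthetic chromosome with genes tiled at fixed spacing and association
  p-values enriched inside a chosen gene set;
* qPCR-like time-course profiles whose pairwise co-expression is controlled
  by a per-condition coupling parameter.

Every generator is deterministic given its seed and returns truth labels
sufficient to score downstream recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import STRATA, ExpressionMatrix

# ---------------------------------------------------------------------------
# stratified expression


@dataclass
class PlantedModule:
    """One planted co-expression module.

    ``loading`` is the factor loading rho in (0, 1): within a stratum where
    the module is present, x_g = rho * e + sqrt(1 - rho^2) * eps with a
    shared per-stratum eigengene e, so E[cor(x_g, x_h)] = rho^2.

    ``loading_low``, when set, plants a hub gradient instead: per-gene
    loadings run linearly from ``loading`` (the top hub) down to
    ``loading_low``, emulating the intramodular-connectivity spread real
    modules show.
    """

    module_id: int
    gene_count: int
    strata_present: tuple[str, ...]
    loading: float
    loading_low: float | None = None

    def loadings(self) -> np.ndarray:
        if self.loading_low is None:
            return np.full(self.gene_count, self.loading)
        return np.linspace(self.loading, self.loading_low, self.gene_count)


@dataclass
class SyntheticDesign:
    """Design of a stratified expression simulation.

    Default sample sizes are the real study composition (121/55/40/148 for
    AD-carrier / AD-noncarrier / CTRL-carrier / CTRL-noncarrier) scaled by
    ``sample_scale``, preserving the imbalance the analysis must tolerate.
    """

    n_genes: int = 300
    n_samples_per_stratum: dict[str, int] | None = None
    planted_modules: list[PlantedModule] = field(default_factory=list)
    noise_sd: float = 1.0
    gene_mean_sd: float = 2.0
    sample_scale: float = 0.5
    seed: int = 0

    FULL_STUDY_SIZES = {
        "AD-carrier": 121,
        "AD-noncarrier": 55,
        "CTRL-carrier": 40,
        "CTRL-noncarrier": 148,
    }

    def __post_init__(self) -> None:
        if self.n_samples_per_stratum is None:
            self.n_samples_per_stratum = {
                s: max(4, round(n * self.sample_scale))
                for s, n in self.FULL_STUDY_SIZES.items()
            }

    def validate(self) -> None:
        unknown = set(self.n_samples_per_stratum) - set(STRATA)
        if unknown:
            raise ValueError(f"unknown strata: {sorted(unknown)}")
        for s, n in self.n_samples_per_stratum.items():
            if n < 4:
                raise ValueError(f"stratum {s!r} has {n} samples; need >= 4")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.gene_mean_sd < 0:
            raise ValueError("gene_mean_sd must be >= 0")
        total_planted = sum(m.gene_count for m in self.planted_modules)
        if total_planted > self.n_genes:
            raise ValueError(
                f"planted gene counts sum to {total_planted} > n_genes={self.n_genes}"
            )
        seen = set()
        for m in self.planted_modules:
            lo = m.loadings()
            if not ((lo > 0.0).all() and (lo < 1.0).all()):
                raise ValueError(
                    f"module {m.module_id}: loadings must lie in (0, 1)"
                )
            if m.module_id in seen or m.module_id == 0:
                raise ValueError(f"module ids must be unique and nonzero: {m.module_id}")
            seen.add(m.module_id)
            bad = set(m.strata_present) - set(STRATA)
            if bad:
                raise ValueError(f"module {m.module_id}: unknown strata {sorted(bad)}")


def default_design(seed: int = 0) -> SyntheticDesign:
    """The stock study design: one carrier-only module, one module shared by
    all four strata, the rest background noise."""
    return SyntheticDesign(
        n_genes=300,
        planted_modules=[
            PlantedModule(1, 50, ("AD-carrier",), 0.8),
            PlantedModule(2, 50, STRATA, 0.8),
        ],
        seed=seed,
    )


def generate_stratified_expression(
    design: SyntheticDesign,
) -> tuple[dict[str, ExpressionMatrix], dict]:
    """Simulate one expression matrix per stratum plus truth labels.

    Returns
    -------
    strata : dict mapping stratum name -> ExpressionMatrix
    truth : dict with ``gene_module`` (gene id -> module id, 0 = background)
        and ``module_strata`` (module id -> list of strata where planted).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    gene_ids = [f"G{i:04d}" for i in range(design.n_genes)]
    gene_module = {g: 0 for g in gene_ids}
    module_rows: dict[int, np.ndarray] = {}
    offset = 0
    for mod in design.planted_modules:
        rows = np.arange(offset, offset + mod.gene_count)
        module_rows[mod.module_id] = rows
        for r in rows:
            gene_module[gene_ids[r]] = mod.module_id
        offset += mod.gene_count

    # per-gene baseline expression level, shared across strata: dominates
    # inter-array correlation (as on real log-scale arrays) without touching
    # any gene-gene correlation
    baseline = rng.normal(0.0, design.gene_mean_sd, size=design.n_genes)

    strata_out: dict[str, ExpressionMatrix] = {}
    sample_counter = 0
    for stratum in STRATA:
        n = design.n_samples_per_stratum.get(stratum, 0)
        if n == 0:
            continue
        data = rng.standard_normal((design.n_genes, n))
        for mod in design.planted_modules:
            if stratum not in mod.strata_present:
                continue
            e = rng.standard_normal(n)
            rho = mod.loadings()[:, None]
            rows = module_rows[mod.module_id]
            data[rows] = rho * e + np.sqrt(1.0 - rho**2) * data[rows]
        data *= design.noise_sd
        data += baseline[:, None]

        sample_ids = [f"S{sample_counter + j:04d}" for j in range(n)]
        sample_counter += n
        phenotype = "case" if stratum.startswith("AD") else "control"
        carrier = "yes" if stratum.endswith("-carrier") else "no"
        covariates = pd.DataFrame(
            {
                "phenotype": phenotype,
                "carrier": carrier,
                "age": np.round(rng.normal(78.0, 7.0, size=n), 1),
                "sex": rng.choice(["M", "F"], size=n),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        values = pd.DataFrame(
            data, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
        )
        strata_out[stratum] = ExpressionMatrix(values, covariates)

    truth = {
        "gene_module": gene_module,
        "module_strata": {
            m.module_id: list(m.strata_present) for m in design.planted_modules
        },
    }
    return strata_out, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics


@dataclass
class SyntheticGwasDesign:
    """Design of a synthetic GWAS association table on one chromosome.

    Genes are tiled as [start, start + gene_length_bp - 1] blocks separated
    by ``intergenic_gap_bp``; SNP positions are drawn uniformly along the
    chromosome. SNPs falling inside a gene of ``enriched_set`` draw their
    association p from Beta(a, 1) with a = 1 / (1 + signal_strength); all
    other SNPs are Uniform(0, 1), so signal_strength = 0 reproduces the null
    generator exactly.
    """

    n_snps: int = 4000
    n_genes: int = 400
    gene_length_bp: int = 10_000
    intergenic_gap_bp: int = 30_000
    enriched_set: tuple[str, ...] = ()
    signal_strength: float = 0.0
    frac_fail_miss: float = 0.0
    frac_fail_maf: float = 0.0
    frac_fail_hwe: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps <= 0 or self.n_genes <= 0:
            raise ValueError("n_snps and n_genes must be positive")
        if self.gene_length_bp <= 0 or self.intergenic_gap_bp < 0:
            raise ValueError("gene_length_bp must be positive, gap non-negative")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        gene_ids = set(gwas_gene_ids(self.n_genes))
        unknown = set(self.enriched_set) - gene_ids
        if unknown:
            raise ValueError(f"enriched_set not a subset of genes: {sorted(unknown)[:5]}")
        for name in ("frac_fail_miss", "frac_fail_maf", "frac_fail_hwe"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")


def gwas_gene_ids(n_genes: int) -> list[str]:
    return [f"GW{i:04d}" for i in range(n_genes)]


def generate_snp_dataset(
    design: SyntheticGwasDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate (snp_table, gene_map, truth).

    ``snp_table`` columns: SNP, CHR, BP, P, MAF, F_MISS, HWE_P (the
    association-file dialect consumed by the enrichment stage).
    ``gene_map`` columns: gene, chrom, start, end (1-based inclusive).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    span = design.gene_length_bp + design.intergenic_gap_bp
    gene_ids = gwas_gene_ids(design.n_genes)
    starts = np.arange(design.n_genes, dtype=np.int64) * span + 1
    ends = starts + design.gene_length_bp - 1
    gene_map = pd.DataFrame(
        {"gene": gene_ids, "chrom": "chr1", "start": starts, "end": ends}
    )
    chrom_len = int(ends[-1] + design.intergenic_gap_bp)

    positions = np.sort(
        rng.choice(np.arange(1, chrom_len + 1), size=design.n_snps, replace=False)
    )
    # p-values: uniform null everywhere, then overwrite SNPs inside enriched genes
    p = rng.uniform(0.0, 1.0, size=design.n_snps)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    enriched_idx = set()
    if design.enriched_set and design.signal_strength > 0:
        enriched_rows = gene_map[gene_map["gene"].isin(design.enriched_set)]
        a = 1.0 / (1.0 + design.signal_strength)
        for _, g in enriched_rows.iterrows():
            inside = np.where((positions >= g["start"]) & (positions <= g["end"]))[0]
            enriched_idx.update(inside.tolist())
        idx = np.array(sorted(enriched_idx), dtype=int)
        if idx.size:
            p[idx] = np.clip(rng.beta(a, 1.0, size=idx.size), np.finfo(float).tiny, 1.0)

    # QC columns: passing draws by default, a configurable fraction failing each
    maf = rng.uniform(0.05, 0.5, size=design.n_snps)
    fmiss = rng.uniform(0.0, 0.1, size=design.n_snps)
    hwe = rng.uniform(0.0011, 1.0, size=design.n_snps)
    fail_maf = rng.random(design.n_snps) < design.frac_fail_maf
    fail_miss = rng.random(design.n_snps) < design.frac_fail_miss
    fail_hwe = rng.random(design.n_snps) < design.frac_fail_hwe
    maf[fail_maf] = rng.uniform(0.0, 0.0099, size=int(fail_maf.sum()))
    fmiss[fail_miss] = rng.uniform(0.101, 0.5, size=int(fail_miss.sum()))
    hwe[fail_hwe] = rng.uniform(1e-6, 0.0009, size=int(fail_hwe.sum()))

    snp_table = pd.DataFrame(
        {
            "SNP": [f"rs{i:06d}" for i in range(design.n_snps)],
            "CHR": 1,
            "BP": positions,
            "P": p,
            "MAF": maf,
            "F_MISS": fmiss,
            "HWE_P": hwe,
        }
    )
    truth = {
        "enriched_set": list(design.enriched_set),
        "enriched_snp_idx": sorted(enriched_idx),
        "fail_maf_idx": np.where(fail_maf)[0].tolist(),
        "fail_miss_idx": np.where(fail_miss)[0].tolist(),
        "fail_hwe_idx": np.where(fail_hwe)[0].tolist(),
    }
    return snp_table, gene_map, truth


# ---------------------------------------------------------------------------
# time-course profiles


@dataclass
class TimeCourseMatrix:
    """Replicate-mean relative expression, genes x timepoints, one condition."""

    values: pd.DataFrame  # genes x timepoints (hours)
    condition: str
    n_replicates: int

    def __post_init__(self) -> None:
        if self.values.shape[1] < 3:
            raise ValueError("time course needs >= 3 timepoints")


@dataclass
class TimeCourseDesign:
    """Condition-dependent co-expression in a short time course.

    Within a condition with coupling rho_c, every gene's mean profile is
    rho_c * z(t) + sqrt(1 - rho_c^2) * u_g(t) for a shared latent trend z,
    so rho_c near 1 yields high pairwise |r| across timepoints and rho_c = 0
    yields independent profiles. Mirrors a 24/48/72 h qPCR experiment with
    >= 3 replicates per timepoint.
    """

    gene_ids: tuple[str, ...] = tuple(f"TC{i}" for i in range(6))
    timepoints: tuple[float, ...] = (24.0, 48.0, 72.0)
    condition_coupling: dict[str, float] = field(
        default_factory=lambda: {"e4-like": 0.95, "e3-like": 0.2, "untreated": 0.2}
    )
    replicates: int = 3
    replicate_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if len(self.timepoints) < 3:
            raise ValueError("need >= 3 timepoints")
        if self.replicates < 3:
            raise ValueError("need >= 3 replicates")
        if len(self.gene_ids) < 2:
            raise ValueError("need >= 2 genes")
        for cond, rho in self.condition_coupling.items():
            if not (0.0 <= rho <= 1.0):
                raise ValueError(f"coupling for {cond!r} must be in [0, 1]")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")


def generate_timecourse(design: TimeCourseDesign) -> dict[str, TimeCourseMatrix]:
    """Simulate replicate-mean profiles for every condition."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_t = len(design.timepoints)
    out: dict[str, TimeCourseMatrix] = {}
    for cond, rho in design.condition_coupling.items():
        z = rng.standard_normal(n_t)
        profiles = np.empty((len(design.gene_ids), n_t))
        for i in range(len(design.gene_ids)):
            u = rng.standard_normal(n_t)
            profiles[i] = rho * z + np.sqrt(1.0 - rho**2) * u
        if design.replicate_sd > 0:
            noise = rng.normal(
                0.0, design.replicate_sd, size=(design.replicates, *profiles.shape)
            )
            profiles = (profiles[None, :, :] + noise).mean(axis=0)
        values = pd.DataFrame(
            profiles,
            index=pd.Index(design.gene_ids, name="gene_id"),
            columns=list(design.timepoints),
        )
        out[cond] = TimeCourseMatrix(values, cond, design.replicates)
    return out
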