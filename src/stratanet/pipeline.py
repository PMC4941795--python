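"""End-to-end orchestration from a single declarative configuration.

Stage order mirrors the analysis protocol: simulate (or load) stratified
expression -> detection filter + iterative outlier removal -> per-stratum
network (soft threshold, adjacency, TOM) -> module detection in the disease
strata -> consensus partitions -> specificity evidence (cross-tabulation,
Z_summary in both comparison strata, subsampling replication) -> hub and
clique analysis of specific modules -> GWAS signal enrichment with QQ /
lambda diagnostics -> time-course co-expression validation. Every stage
consumes a deterministic sub-seed derived from the global seed, and the
run report echoes every parameter in force.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as snio
from .containers import STRATA, child_seed
from .gwas import permutation_test, qq_lambda, snp_qc
from .hubs import (
    build_hub_graph,
    detect_complete_graph,
    intramodular_connectivity,
    module_membership,
    select_hubs,
)
from .modules import consensus_modules, detect_modules, eigengene
from .network import adjacency, pairwise_correlation, pick_soft_threshold, topological_overlap
from .overlap import compare_disease_modules, timecourse_coexpression
from .preprocess import filter_transcripts, remove_outlier_samples, stratify
from .specificity import (
    classify_specific,
    crosstab_match,
    replicate_by_subsampling,
    zsummary_preservation,
)
from .synthetic import (
    SyntheticDesign,
    SyntheticGwasDesign,
    TimeCourseDesign,
    default_design,
    generate_snp_dataset,
    generate_stratified_expression,
    generate_timecourse,
)

logger = logging.getLogger("stratanet")

STAGES = (
    "simulate",
    "preprocess",
    "network",
    "modules",
    "specificity",
    "hubs",
    "gwas",
    "overlap",
)

# comparison strata for specificity: same-phenotype/other-carrier first,
# then other-phenotype/same-carrier
COMPARISONS = {
    "AD-carrier": ("AD-noncarrier", "CTRL-carrier"),
    "AD-noncarrier": ("AD-carrier", "CTRL-noncarrier"),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Declarative run configuration; every stage parameter has a default.

    Round-trips losslessly through YAML via :meth:`to_yaml` / :meth:`from_yaml`.
    """

    seed: int = 0
    outdir: str | None = None

    design: SyntheticDesign = field(default_factory=default_design)
    gwas_design: SyntheticGwasDesign | None = None
    timecourse_design: TimeCourseDesign | None = None

    # preprocess
    min_detect_frac: float = 0.9
    outlier_sd_k: float = 2.0

    # network
    beta: int | None = 6  # None -> pick per stratum by scale-free fit
    target_r2: float = 0.8
    signed: bool = False

    # module detection
    min_module_size: int = 30
    cut_height_frac: float = 0.99
    deep_split: int = 2
    me_diss_threshold: float = 0.25
    scaling_quantile: float = 0.95

    # specificity
    crosstab_alpha: float = 0.05
    n_perm_preservation: int = 200
    replication_fractions: tuple[float, ...] = (0.5, 0.75)
    replication_runs: int = 5
    replication_overlap: float = 0.8

    # hubs
    hub_quantile: float = 0.05
    hub_min: int = 5
    clique_r_threshold: float = 0.5

    # gwas
    window_bp: int = 20_000
    gwas_alpha: float = 0.05
    n_perm_gwas: int = 1000

    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("design") is not None and not isinstance(d["design"], SyntheticDesign):
            dd = dict(d["design"])
            mods = [
                m if not isinstance(m, dict) else _planted_from_dict(m)
                for m in dd.pop("planted_modules", [])
            ]
            d["design"] = SyntheticDesign(planted_modules=mods, **dd)
        if d.get("gwas_design") is not None and not isinstance(
            d["gwas_design"], SyntheticGwasDesign
        ):
            gd = dict(d["gwas_design"])
            if "enriched_set" in gd:
                gd["enriched_set"] = tuple(gd["enriched_set"])
            d["gwas_design"] = SyntheticGwasDesign(**gd)
        if d.get("timecourse_design") is not None and not isinstance(
            d["timecourse_design"], TimeCourseDesign
        ):
            td = dict(d["timecourse_design"])
            for key in ("gene_ids", "timepoints"):
                if key in td:
                    td[key] = tuple(td[key])
            d["timecourse_design"] = TimeCourseDesign(**td)
        if "replication_fractions" in d:
            d["replication_fractions"] = tuple(d["replication_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _planted_from_dict(m: dict):
    from .synthetic import PlantedModule

    m = dict(m)
    m["strata_present"] = tuple(m["strata_present"])
    return PlantedModule(**m)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return the list of constraint violations (empty iff valid)."""
    v: list[str] = []
    if config.seed < 0:
        v.append("seed: must be non-negative")
    try:
        config.design.validate()
    except ValueError as exc:
        v.append(f"design: {exc}")
    if config.design.n_genes < config.min_module_size:
        v.append("min_module_size: exceeds design.n_genes")
    if not (0.0 < config.min_detect_frac <= 1.0):
        v.append("min_detect_frac: must be in (0, 1]")
    if config.outlier_sd_k <= 0:
        v.append("outlier_sd_k: must be positive")
    if config.beta is not None and config.beta < 1:
        v.append("beta: must be >= 1 (or null for automatic selection)")
    if not (0.0 <= config.target_r2 <= 1.0):
        v.append("target_r2: must be in [0, 1]")
    if not (0.0 < config.cut_height_frac <= 1.0):
        v.append("cut_height_frac: must be in (0, 1]")
    if config.deep_split < 0:
        v.append("deep_split: must be >= 0")
    if not (0.0 <= config.me_diss_threshold < 1.0):
        v.append("me_diss_threshold: must be in [0, 1)")
    if not (0.0 < config.scaling_quantile < 1.0):
        v.append("scaling_quantile: must be in (0, 1)")
    if not (0.0 < config.crosstab_alpha < 1.0):
        v.append("crosstab_alpha: must be in (0, 1)")
    if config.n_perm_preservation < 10:
        v.append("n_perm_preservation: must be >= 10")
    for f in config.replication_fractions:
        if not (0.0 < f <= 1.0):
            v.append(f"replication_fractions: {f} outside (0, 1]")
    if config.replication_runs < 1:
        v.append("replication_runs: must be >= 1")
    if not (0.0 <= config.replication_overlap <= 1.0):
        v.append("replication_overlap: must be in [0, 1]")
    if config.window_bp < 0:
        v.append("window_bp: must be non-negative")
    if not (0.0 < config.gwas_alpha < 1.0):
        v.append("gwas_alpha: must be in (0, 1)")
    if config.gwas_design is not None:
        try:
            config.gwas_design.validate()
        except ValueError as exc:
            v.append(f"gwas_design: {exc}")
    if config.timecourse_design is not None:
        try:
            config.timecourse_design.validate()
        except ValueError as exc:
            v.append(f"timecourse_design: {exc}")
    return v


# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> dict:
    """Execute the analysis and return the run report (a JSON-able dict).

    ``stop_after`` truncates the stage list (one of ``STAGES``); the report
    then contains the stages run so far. When ``config.outdir`` is set the
    report and key tables are written there.
    """
    violations = validate_config(config)
    if violations:
        raise PipelineError("config", "invalid", "; ".join(violations))
    if stop_after is not None and stop_after not in STAGES:
        raise PipelineError("config", "invalid", f"unknown stage {stop_after!r}")
    stop_idx = STAGES.index(stop_after) if stop_after else len(STAGES) - 1

    seed_seq = np.random.SeedSequence(config.seed)
    report: dict = {
        "parameters": config.to_dict(),
        "stages": {},
    }
    t_all = time.time()

    def running(stage: str) -> bool:
        return STAGES.index(stage) <= stop_idx

    # --- simulate ---------------------------------------------------------
    t0 = time.time()
    design = dataclasses.replace(config.design, seed=child_seed(seed_seq, 0))
    strata, truth = generate_stratified_expression(design)
    report["stages"]["simulate"] = {
        "strata_sizes": {s: e.n_samples for s, e in strata.items()},
        "n_genes": design.n_genes,
        "planted_modules": truth["module_strata"],
        "seconds": round(time.time() - t0, 3),
    }
    if not running("preprocess"):
        return _finish(report, config, t_all)

    # --- preprocess -------------------------------------------------------
    t0 = time.time()
    try:
        import pandas as pd

        combined_vals = pd.concat([strata[s].values for s in strata], axis=1)
        combined_cov = pd.concat([strata[s].covariates for s in strata], axis=0)
        from .containers import ExpressionMatrix

        combined = ExpressionMatrix(combined_vals, combined_cov)
        filtered = filter_transcripts(combined, config.min_detect_frac)
        strata_f = stratify(filtered)
        outlier_logs = {}
        for s in list(strata_f):
            if strata_f[s].n_samples < 4:
                del strata_f[s]
                continue
            strata_f[s], outlier_logs[s] = remove_outlier_samples(
                strata_f[s], config.outlier_sd_k
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("preprocess", "stage_failure", str(exc)) from exc
    report["stages"]["preprocess"] = {
        "n_genes_kept": next(iter(strata_f.values())).n_genes,
        "outliers_removed": {
            s: [r for it in log for r in it["removed"]]
            for s, log in outlier_logs.items()
        },
        "strata_sizes": {s: e.n_samples for s, e in strata_f.items()},
        "seconds": round(time.time() - t0, 3),
    }
    if not running("network"):
        return _finish(report, config, t_all)

    # --- network ----------------------------------------------------------
    t0 = time.time()
    try:
        networks: dict[str, dict] = {}
        betas: dict[str, int] = {}
        for s, expr in strata_f.items():
            corr = pairwise_correlation(expr)
            if config.beta is None:
                st = pick_soft_threshold(
                    corr, target_r2=config.target_r2, signed=config.signed
                )
                beta = st.beta
            else:
                beta = config.beta
            adj = adjacency(corr, beta, signed=config.signed)
            tom = topological_overlap(adj)
            networks[s] = {"corr": corr, "adj": adj, "tom": tom,
                           "expr": expr.subset_genes(corr.index)}
            betas[s] = beta
    except Exception as exc:
        raise PipelineError("network", "stage_failure", str(exc)) from exc
    report["stages"]["network"] = {
        "beta": betas,
        "seconds": round(time.time() - t0, 3),
    }
    if not running("modules"):
        return _finish(report, config, t_all)

    # --- modules (per disease stratum + consensus) ------------------------
    t0 = time.time()
    try:
        partitions: dict[str, object] = {}
        for s in ("AD-carrier", "AD-noncarrier"):
            if s not in networks:
                continue
            partitions[s] = detect_modules(
                networks[s]["expr"],
                networks[s]["tom"],
                min_module_size=config.min_module_size,
                cut_height_frac=config.cut_height_frac,
                deep_split=config.deep_split,
                me_diss_threshold=config.me_diss_threshold,
            )
        consensus: dict[str, object] = {}
        pairs = {
            "AD-carrier+AD-noncarrier": ("AD-carrier", "AD-noncarrier"),
            "AD-carrier+CTRL-carrier": ("AD-carrier", "CTRL-carrier"),
            "AD-noncarrier+CTRL-noncarrier": ("AD-noncarrier", "CTRL-noncarrier"),
        }
        for name, (a, b) in pairs.items():
            if a in networks and b in networks:
                consensus[name] = consensus_modules(
                    [networks[a]["tom"], networks[b]["tom"]],
                    scaling_quantile=config.scaling_quantile,
                    min_module_size=config.min_module_size,
                    cut_height_frac=config.cut_height_frac,
                    deep_split=config.deep_split,
                    exprs=[networks[a]["expr"], networks[b]["expr"]],
                    me_diss_threshold=config.me_diss_threshold,
                )
    except Exception as exc:
        raise PipelineError("modules", "stage_failure", str(exc)) from exc
    report["stages"]["modules"] = {
        "module_counts": {s: p.n_modules() for s, p in partitions.items()},
        "module_sizes": {
            s: {int(k): int(v) for k, v in p.sizes().items()}
            for s, p in partitions.items()
        },
        "consensus_module_counts": {n: p.n_modules() for n, p in consensus.items()},
        "labels": {
            s: {g: int(l) for g, l in p.labels.items()} for s, p in partitions.items()
        },
        "seconds": round(time.time() - t0, 3),
    }
    if not running("specificity"):
        return _finish(report, config, t_all)

    # --- specificity ------------------------------------------------------
    t0 = time.time()
    try:
        spec_report: dict = {}
        specific_modules: dict[str, list[int]] = {}
        stage_seed = child_seed(seed_seq, 1)
        for s, part in partitions.items():
            if part.n_modules() == 0:
                specific_modules[s] = []
                spec_report[s] = {"calls": []}
                continue
            relevant = [n for n in consensus if s in n.split("+")]
            matched_sets = {}
            for name in relevant:
                _, matched = crosstab_match(part, consensus[name], config.crosstab_alpha)
                matched_sets[name] = matched
            preservation: dict[int, dict] = {}
            for mid in part.module_ids():
                genes = part.genes_of(mid)
                if len(genes) < 10:
                    continue
                preservation[mid] = {}
                for j, other in enumerate(COMPARISONS.get(s, ())):
                    if other not in networks:
                        continue
                    rep = zsummary_preservation(
                        networks[s]["expr"],
                        networks[other]["expr"],
                        genes,
                        betas[other],
                        n_perm=config.n_perm_preservation,
                        seed=stage_seed + 1000 * mid + j,
                        module_id=mid,
                    )
                    preservation[mid][other] = rep
            calls = classify_specific(part, matched_sets, preservation)
            specific_modules[s] = [c.module_id for c in calls if c.specific]
            spec_report[s] = {
                "calls": [
                    {"module": c.module_id, "specific": c.specific,
                     "evidence": c.evidence}
                    for c in calls
                ],
            }
        # subsampling replication of every specific module
        rep_seed = child_seed(seed_seq, 2)
        for s, mids in specific_modules.items():
            reps = {}
            for mid in mids:
                rr = replicate_by_subsampling(
                    networks[s]["expr"],
                    partitions[s],
                    mid,
                    betas[s],
                    fractions=config.replication_fractions,
                    runs=config.replication_runs,
                    overlap_frac=config.replication_overlap,
                    seed=rep_seed + mid,
                    min_module_size=config.min_module_size,
                    cut_height_frac=config.cut_height_frac,
                    deep_split=config.deep_split,
                    me_diss_threshold=config.me_diss_threshold,
                )
                reps[mid] = {
                    "replicated": rr.replicated,
                    "best_overlap_per_run": rr.runs["best_overlap"].tolist(),
                }
            spec_report[s]["replication"] = reps
    except Exception as exc:
        raise PipelineError("specificity", "stage_failure", str(exc)) from exc
    spec_report["specific_modules"] = specific_modules
    spec_report["seconds"] = round(time.time() - t0, 3)
    report["stages"]["specificity"] = spec_report
    if not running("hubs"):
        return _finish(report, config, t_all)

    # --- hubs and cliques -------------------------------------------------
    t0 = time.time()
    try:
        hub_report: dict = {}
        for s, mids in specific_modules.items():
            hub_report[s] = {}
            for mid in mids:
                genes = partitions[s].genes_of(mid)
                kim = intramodular_connectivity(networks[s]["adj"], partitions[s], mid)
                me = eigengene(networks[s]["expr"].subset_genes(genes), genes, mid)
                kme = module_membership(
                    networks[s]["expr"].subset_genes(genes), me
                )
                hub_table = select_hubs(
                    kim, kme, quantile=config.hub_quantile, min_hubs=config.hub_min
                )
                graph = build_hub_graph(
                    networks[s]["expr"], list(hub_table.index),
                    r_threshold=config.clique_r_threshold,
                )
                clique = detect_complete_graph(graph)
                hub_report[s][int(mid)] = {
                    "hubs": list(hub_table.index),
                    "is_complete_graph": clique.is_complete,
                    "max_clique": list(clique.max_clique),
                }
    except Exception as exc:
        raise PipelineError("hubs", "stage_failure", str(exc)) from exc
    hub_report["seconds"] = round(time.time() - t0, 3)
    report["stages"]["hubs"] = hub_report
    if not running("gwas"):
        return _finish(report, config, t_all)

    # --- GWAS enrichment --------------------------------------------------
    t0 = time.time()
    gwas_report: dict = {}
    if config.gwas_design is not None:
        try:
            gdesign = dataclasses.replace(
                config.gwas_design, seed=child_seed(seed_seq, 3)
            )
            snps, gene_map, gtruth = generate_snp_dataset(gdesign)
            snps_qc, qc_log = snp_qc(snps)
            result = permutation_test(
                snps_qc,
                gene_map,
                gtruth["enriched_set"] or gene_map["gene"].head(50).tolist(),
                n_perm=config.n_perm_gwas,
                seed=child_seed(seed_seq, 4),
                window_bp=config.window_bp,
                alpha=config.gwas_alpha,
                gene_set_id="planted" if gtruth["enriched_set"] else "first50",
            )
            qq_all = qq_lambda(snps_qc["P"].to_numpy())
            gwas_report = {
                "qc": qc_log,
                "enrichment": {
                    "gene_set": result.gene_set_id,
                    "ES": result.es,
                    "k": result.k,
                    "K": result.K,
                    "SPES": result.spes_value,
                    "p": result.p_value,
                    "n_perm": result.n_perm,
                },
                "lambda_all_snps": qq_all.lam,
            }
        except Exception as exc:
            raise PipelineError("gwas", "stage_failure", str(exc)) from exc
    gwas_report["seconds"] = round(time.time() - t0, 3)
    report["stages"]["gwas"] = gwas_report
    if not running("overlap"):
        return _finish(report, config, t_all)

    # --- cross-disease / time course ---------------------------------------
    t0 = time.time()
    overlap_report: dict = {}
    try:
        # overlap of the specific modules of the two disease strata over the
        # shared measured-gene universe
        if all(s in partitions for s in ("AD-carrier", "AD-noncarrier")):
            universe = set(partitions["AD-carrier"].gene_ids) & set(
                partitions["AD-noncarrier"].gene_ids
            )
            sets_a = {
                f"carrier-M{m}": set(partitions["AD-carrier"].genes_of(m))
                for m in specific_modules.get("AD-carrier", [])
            }
            sets_b = {
                f"noncarrier-M{m}": set(partitions["AD-noncarrier"].genes_of(m))
                for m in specific_modules.get("AD-noncarrier", [])
            }
            if sets_a and sets_b:
                table = compare_disease_modules(sets_a, sets_b, universe)
                overlap_report["cross_stratum"] = table.drop(
                    columns="overlap_genes"
                ).to_dict("records")
        if config.timecourse_design is not None:
            tdesign = dataclasses.replace(
                config.timecourse_design, seed=child_seed(seed_seq, 5)
            )
            tcs = generate_timecourse(tdesign)
            overlap_report["timecourse_mean_abs_r"] = {
                cond: timecourse_coexpression(tc)[1] for cond, tc in tcs.items()
            }
    except Exception as exc:
        raise PipelineError("overlap", "stage_failure", str(exc)) from exc
    overlap_report["seconds"] = round(time.time() - t0, 3)
    report["stages"]["overlap"] = overlap_report
    return _finish(report, config, t_all)


def _finish(report: dict, config: PipelineConfig, t_all: float) -> dict:
    report["total_seconds"] = round(time.time() - t_all, 3)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stripped = json.loads(
            json.dumps(report, default=snio._js)
        )
        snio.write_json(stripped, outdir / "run_report.json")
        _write_summary(stripped, outdir / "run_summary.txt")
    return report


def _write_summary(report: dict, path: Path) -> None:
    lines = ["stratified co-expression run summary", "=" * 40]
    stages = report.get("stages", {})
    if "modules" in stages:
        for s, n in stages["modules"]["module_counts"].items():
            lines.append(f"{s}: {n} modules {stages['modules']['module_sizes'][s]}")
    if "specificity" in stages:
        lines.append(
            f"specific modules: {stages['specificity'].get('specific_modules')}"
        )
    if "hubs" in stages:
        for s, mods in stages["hubs"].items():
            if s == "seconds":
                continue
            for mid, info in mods.items():
                lines.append(
                    f"{s} module {mid}: hubs={info['hubs']} "
                    f"complete_graph={info['is_complete_graph']}"
                )
    if "gwas" in stages and "enrichment" in stages["gwas"]:
        e = stages["gwas"]["enrichment"]
        lines.append(
            f"GWAS enrichment [{e['gene_set']}]: SPES={e['SPES']:.3f} p={e['p']:.4g}"
        )
    if "overlap" in stages and "timecourse_mean_abs_r" in stages["overlap"]:
        for cond, r in stages["overlap"]["timecourse_mean_abs_r"].items():
            lines.append(f"time course {cond}: mean |r| = {r:.3f}")
    path.write_text("\n".join(lines) + "\n")
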