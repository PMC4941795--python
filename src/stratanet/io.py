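"""Readers and writers for every external text format the pipeline touches.

Conventions, stated once and used everywhere: genomic coordinates are
1-based inclusive internally; BED input (0-based half-open) is converted at
the boundary. Expression matrices travel as TSV with genes in rows and a
sample-id header, covariates as a sidecar TSV keyed by sample id. Missing
expression tokens are "", "NA" and "NaN". Every reader rejects malformed
input rather than coercing it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import REQUIRED_COVARIATES, ExpressionMatrix

MISSING_TOKENS = ("", "NA", "NaN")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# expression + covariates


def write_expression_tsv(expr: ExpressionMatrix, path, covariates_path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")
    expr.covariates.to_csv(covariates_path, sep="\t", index_label="sample_id")


def read_expression_tsv(path, covariates_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its covariate sidecar.

    Rejects duplicate gene ids, non-numeric body cells outside the missing
    token set, and samples without complete covariates — each with the
    offending identifier in the message.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    dup = raw.index[raw.index.duplicated()]
    if len(dup) > 0:
        raise ParseError(f"duplicate gene id {dup[0]!r} in {path}")
    body = raw.replace(list(MISSING_TOKENS), np.nan)
    try:
        values = body.astype(float)
    except ValueError as exc:
        for i, (gene, row) in enumerate(body.iterrows(), start=2):
            for cell in row:
                if pd.isna(cell):
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"line {i} (gene {gene!r}): unparseable value {cell!r}"
                    ) from exc
        raise ParseError(str(exc)) from exc

    cov = pd.read_csv(covariates_path, sep="\t", index_col=0, dtype=str)
    if not cov.index.is_unique:
        d = cov.index[cov.index.duplicated()][0]
        raise ParseError(f"duplicate sample id {d!r} in {covariates_path}")
    for col in REQUIRED_COVARIATES:
        if col not in cov.columns:
            raise ParseError(f"covariate column {col!r} missing")
    missing = set(values.columns) - set(cov.index)
    if missing:
        raise ParseError(f"covariates missing for sample {sorted(missing)[0]!r}")
    cov = cov.loc[list(values.columns)]
    if cov[list(REQUIRED_COVARIATES)].isna().any().any():
        bad = cov.index[cov[list(REQUIRED_COVARIATES)].isna().any(axis=1)][0]
        raise ParseError(f"incomplete covariates for sample {bad!r}")
    cov["age"] = cov["age"].astype(float)
    return ExpressionMatrix(values, cov)


# ---------------------------------------------------------------------------
# gene maps (BED at the boundary, 1-based inclusive inside)


def read_bed(path) -> pd.DataFrame:
    """Read a BED gene map (0-based, half-open) into the internal 1-based
    inclusive convention: (start + 1, end). Strand, if present, is carried
    along but ignored by the symmetric scoring window."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: need >= 4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates")
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = fields[5] if len(fields) >= 6 else None
            rows.append(
                {"gene": name, "chrom": chrom, "start": start + 1, "end": end,
                 "strand": strand}
            )
    table = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
    if table["gene"].duplicated().any():
        d = table.loc[table["gene"].duplicated(), "gene"].iloc[0]
        raise ParseError(f"duplicate gene id {d!r} in {path}")
    return table


def write_bed(gene_map: pd.DataFrame, path) -> None:
    """Write an internal 1-based inclusive gene map as BED (start - 1, end)."""
    with open(path, "w") as fh:
        for _, g in gene_map.iterrows():
            cols = [str(g["chrom"]), str(int(g["start"]) - 1), str(int(g["end"])),
                    str(g["gene"])]
            strand = g.get("strand")
            if strand is not None and not (isinstance(strand, float) and np.isnan(strand)):
                cols += ["0", str(strand)]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# association tables and gene sets


ASSOC_REQUIRED = ("SNP", "CHR", "BP", "P")
ASSOC_QC = ("MAF", "F_MISS", "HWE_P")


def read_assoc(path) -> pd.DataFrame:
    """Read a PLINK-association-style table (whitespace- or tab-delimited,
    header row). Requires SNP/CHR/BP/P; QC columns (MAF, F_MISS, HWE_P) are
    optional — without them the QC stage is skipped with a warning.
    p-values must lie in (0, 1]; p = 0 is rejected with guidance."""
    table = pd.read_csv(path, sep=None, engine="python")
    missing = set(ASSOC_REQUIRED) - set(table.columns)
    if missing:
        raise ParseError(f"association file missing columns: {sorted(missing)}")
    if table["SNP"].duplicated().any():
        d = table.loc[table["SNP"].duplicated(), "SNP"].iloc[0]
        raise ParseError(f"duplicate SNP id {d!r}")
    p = table["P"].astype(float)
    if (p <= 0).any():
        bad = table.loc[p <= 0, "SNP"].iloc[0]
        raise ParseError(
            f"SNP {bad!r} has p <= 0; replace exact zeros with a small floor "
            "(e.g. the machine minimum) before import"
        )
    if (p > 1).any():
        bad = table.loc[p > 1, "SNP"].iloc[0]
        raise ParseError(f"SNP {bad!r} has p > 1")
    table["P"] = p
    table["BP"] = table["BP"].astype(np.int64)
    if (table["BP"] <= 0).any():
        raise ParseError("SNP positions must be positive (1-based)")
    have_qc = set(ASSOC_QC) <= set(table.columns)
    if not have_qc:
        warnings.warn(
            "association file lacks QC columns (MAF, F_MISS, HWE_P); "
            "the QC stage will be skipped",
            stacklevel=2,
        )
    return table


def write_assoc(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: one set per line, fields = name, description, members."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT needs name, desc, members")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(f for f in fields[2:] if f)
    return sets


def write_gmt(sets: dict[str, set], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# misc report helpers


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_js))


def _js(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
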