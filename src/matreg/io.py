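"""Tab-separated readers/writers and run configuration.

All tables are TSV with a header line and ``.`` for missing values.  The
comparison-table reader also accepts the column-naming style of published
supplementary spreadsheets (e.g. ``FC mat+ vs mat-``, ``p-value``,
``selection``) and an optional decimal-comma dialect so printed tables can
be ingested verbatim.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schema import (
    COMPARISONS,
    FLAG_LEVELS,
    GENOTYPES,
    PROBE_COLUMNS,
    a_col,
    comparison_columns,
    fc_col,
    p_col,
    selected_col,
)

logger = logging.getLogger(__name__)

MISSING = "."

_GENE_ALIASES = {"gene_id", "gene", "genes", "gene number", "gene_number", "id"}


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING, float_format="%.17g")


def _read_tsv(path: str | Path, decimal_comma: bool = False) -> pd.DataFrame:
    kwargs = dict(sep="\t", na_values=[MISSING], keep_default_na=True)
    if decimal_comma:
        df = pd.read_csv(path, dtype=str, **kwargs)
    else:
        df = pd.read_csv(path, float_precision="round_trip", **kwargs)
    return df


def _numeric(df: pd.DataFrame, col: str, decimal_comma: bool = False) -> pd.Series:
    """Convert a column to float, reporting the first offending row."""
    s = df[col]
    if decimal_comma and s.dtype == object:
        s = s.str.replace(",", ".", regex=False)
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & s.notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-numeric value {s.iloc[row]!r} in column {col!r} at data row {row + 1}"
        )
    return out


def read_probe_table(path: str | Path, decimal_comma: bool = False) -> pd.DataFrame:
    """Read and validate a probe-level two-color intensity table."""
    df = _read_tsv(path, decimal_comma)
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    for col in ("sample_fg", "sample_bg", "ref_fg", "ref_bg"):
        df[col] = _numeric(df, col, decimal_comma)
        neg = df[col] < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise ValueError(f"negative intensity in column {col!r} at data row {row + 1}")
    df["flag"] = _numeric(df, "flag", decimal_comma).astype(int)
    unknown = set(df.flag.unique()) - set(FLAG_LEVELS)
    if unknown:
        raise ValueError(f"unknown flag values: {sorted(unknown)}")
    bad_geno = set(df.genotype.unique()) - set(GENOTYPES)
    if bad_geno:
        raise ValueError(f"unknown genotypes: {sorted(bad_geno)}")
    dup = df.duplicated(subset=["gene_id", "array_id", "probe"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ValueError(f"duplicate gene x array x probe key at data row {row + 1}")
    return df


def _normalize_header(name: str) -> str:
    n = name.strip().lower().replace("−", "-").replace(" ", " ")
    return re.sub(r"\s+", " ", n)


def _match_comparison(norm: str) -> str | None:
    has = lambda tok: tok in norm
    if has("fpr1") and has("fmr1"):
        return "fpr1_vs_fmr1"
    if has("mat+") and has("fpr1"):
        return "matplus_vs_fpr1"
    if has("mat-") and has("fmr1"):
        return "matminus_vs_fmr1"
    if has("mat+") and has("mat-"):
        return "matplus_vs_matminus"
    for comp in COMPARISONS:
        if comp in norm.replace(" ", "_"):
            return comp
    return None


def _match_measure(norm: str) -> str | None:
    head = norm.split(" ")[0].split("_")[0]
    if head in ("fc", "fold", "foldchange"):
        return "fc"
    if head in ("p", "p-value", "pvalue", "adj", "padj"):
        return "p"
    if head == "a":
        return "a"
    if head.startswith("sel"):
        return "selected"
    return None


def read_comparison_table(path: str | Path, decimal_comma: bool = False) -> pd.DataFrame:
    """Read a per-gene comparison table, canonical or supplement-style.

    Columns are matched by name, order-insensitively; unrecognised columns
    are preserved.  Selection flags inconsistent with the FC/p thresholds
    trigger a warning listing the genes concerned.
    """
    df = _read_tsv(path, decimal_comma)
    rename = {}
    for col in df.columns:
        norm = _normalize_header(col)
        if norm in _GENE_ALIASES:
            rename[col] = "gene_id"
            continue
        measure = _match_measure(norm)
        comp = _match_comparison(norm)
        if measure and comp:
            rename[col] = {
                "fc": fc_col(comp),
                "p": p_col(comp),
                "a": a_col(comp),
                "selected": selected_col(comp),
            }[measure]
    df = df.rename(columns=rename)
    if "gene_id" not in df.columns:
        raise ValueError("comparison table has no gene identifier column")
    for comp in COMPARISONS:
        for col in (fc_col(comp), p_col(comp), a_col(comp)):
            if col in df.columns:
                df[col] = _numeric(df, col, decimal_comma)
        scol = selected_col(comp)
        if scol in df.columns:
            df[scol] = _numeric(df, scol, decimal_comma).fillna(0).astype(bool)
    _warn_inconsistent_selection(df)
    return df


def _warn_inconsistent_selection(
    df: pd.DataFrame, fc_cut: float = 2.0, p_cut: float = 0.005
) -> None:
    for comp in COMPARISONS:
        fcc, pcc, scc = fc_col(comp), p_col(comp), selected_col(comp)
        if not {fcc, pcc, scc} <= set(df.columns):
            continue
        fc = df[fcc].to_numpy(dtype=float)
        p = df[pcc].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            expect = (np.abs(fc) >= fc_cut) & (p < p_cut)
        expect &= np.isfinite(fc) & np.isfinite(p)
        mism = df.gene_id[expect != df[scc].to_numpy(dtype=bool)]
        if len(mism):
            logger.warning(
                "selection flags inconsistent with FC/p in %s for %d genes: %s%s",
                comp,
                len(mism),
                ", ".join(map(str, mism.head(10))),
                "..." if len(mism) > 10 else "",
            )


def write_comparison_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in comparison_columns() if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    write_tsv(table[cols + extra], path)


def read_cq_table(path: str | Path, decimal_comma: bool = False) -> pd.DataFrame:
    df = _read_tsv(path, decimal_comma)
    required = {"gene_id", "sample_id", "condition", "cq", "efficiency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    df["cq"] = _numeric(df, "cq", decimal_comma)
    df["efficiency"] = _numeric(df, "efficiency", decimal_comma)
    if (df.cq <= 0).any():
        raise ValueError("Cq values must be positive")
    if (df.efficiency <= 1).any():
        raise ValueError("efficiencies must exceed 1")
    return df


def read_gene_set(path: str | Path, decimal_comma: bool = False) -> pd.DataFrame:
    """Target-set TSV: gene id plus optional FC and p columns."""
    df = _read_tsv(path, decimal_comma)
    first = df.columns[0]
    df = df.rename(columns={first: "gene_id"} if first not in _GENE_ALIASES else {})
    for col in ("fc", "p"):
        if col in df.columns:
            df[col] = _numeric(df, col, decimal_comma)
    return df


def read_ortholog_pairs(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if not {"id_sp1", "id_sp2"} <= set(df.columns):
        df = df.rename(
            columns={df.columns[0]: "id_sp1", df.columns[1]: "id_sp2"}
        )
    return df[["id_sp1", "id_sp2"]]


@dataclass
class PipelineConfig:
    """Thresholds, inputs and outputs of an end-to-end run."""

    probe_table: str | None = None
    comparison_table: str | None = None
    cq_table: str | None = None
    targets_sp1: str | None = None
    ortholog_pairs: str | None = None
    out_dir: str = "results"
    seed: int = 0
    n_genes: int = 1000
    fc_cut: float = 2.0
    p_cut: float = 0.005
    borderline_fc_low: float = 1.8
    ssr_cut: float = 3.0
    v_cut: float = 0.15
    composite_tol: float = 0.10
    overlap_fc_cut: float = 1.5
    span: float = 0.3
    genome_size: int = 10556

    def validate(self) -> None:
        for name in (
            "fc_cut",
            "p_cut",
            "borderline_fc_low",
            "ssr_cut",
            "v_cut",
            "composite_tol",
            "overlap_fc_cut",
            "span",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
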