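"""Readers and writers for the pipeline's plain-text formats.

Expression: TSV with gene IDs in the first column and sample IDs in the header.
Covariates: TSV with sample IDs in the first column. Gene sets: GMT (set name,
description, then member genes, tab-separated).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .screen import CovariateTable


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        raise ValueError("duplicate gene IDs in expression matrix")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_covariates(
    path: str | Path, interest: list[str] | None = None
) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    interest = interest or []
    roles = {
        c: ("interest" if c in interest else "non_interest") for c in df.columns
    }
    return CovariateTable(df, roles)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
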