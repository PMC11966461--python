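"""Differential-expression tiering and gene-set directionality.

Consumes gene-level DE result tables (DESeq-style: log2 fold change, raw and
adjusted p-value).  Genes with adjusted p < 0.1 are differentially expressed,
split into a strong tier (padj < 0.05) and a moderate tier (0.05 <= padj <
0.1).  Gene-set directionality counts, among all set members present in the
table regardless of significance, how many move up (log2FC > 0) versus down
(log2FC < 0); a fold change of exactly zero counts as neither.

Multiple-testing correction is consumed as provided upstream, never refit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "DETable",
    "GeneSet",
    "DegReport",
    "SetDirectionality",
    "call_degs",
    "set_directionality",
    "read_de_table",
    "write_de_table",
    "read_gmt",
]

#: column aliases accepted for DESeq-style exports
_DE_ALIASES = {
    "gene": ("gene", "gene_symbol", "symbol", "row", "id"),
    "log2fc": ("log2fc", "log2foldchange", "lfc"),
    "pvalue": ("pvalue", "p_value", "pval", "p"),
    "padj": ("padj", "p_adj", "adjusted_pvalue", "fdr", "qvalue"),
}


@dataclass
class DETable:
    """Gene-level DE records with unique symbols.

    ``records`` columns: ``gene``, ``log2fc``, ``pvalue``, ``padj`` (padj may
    be NaN; such genes are excluded from DEG calling).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "log2fc", "pvalue", "padj"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")
        if self.records["gene"].duplicated().any():
            dup = self.records.loc[self.records["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicated gene symbol {dup!r}")
        p = self.records["pvalue"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("pvalue outside [0,1]")
        q = self.records["padj"].dropna()
        if ((q < 0) | (q > 1)).any():
            raise ValueError("padj outside [0,1]")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class DegReport:
    degs: set[str]
    n_up: int
    n_down: int
    n_zero: int
    tiers: dict[str, str]  # gene -> "strong" | "moderate" | "none"
    alpha: float
    strong_alpha: float

    @property
    def n_deg(self) -> int:
        return len(self.degs)


def call_degs(table: DETable, alpha: float = 0.1, strong_alpha: float = 0.05) -> DegReport:
    """Call DEGs at ``padj < alpha`` and tier them by ``strong_alpha``.

    Up/down counts are over DEGs with strictly positive/negative log2FC; a
    DEG at exactly zero is tallied separately as ``n_zero``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if strong_alpha > alpha:
        raise ValueError("strong_alpha must not exceed alpha")
    df = table.records
    sig = df["padj"].notna() & (df["padj"] < alpha)
    strong = df["padj"].notna() & (df["padj"] < strong_alpha)
    tiers = {
        str(g): ("strong" if st else "moderate" if s else "none")
        for g, s, st in zip(df["gene"], sig, strong)
    }
    deg_rows = df[sig]
    return DegReport(
        degs=set(deg_rows["gene"].astype(str)),
        n_up=int((deg_rows["log2fc"] > 0).sum()),
        n_down=int((deg_rows["log2fc"] < 0).sum()),
        n_zero=int((deg_rows["log2fc"] == 0).sum()),
        tiers=tiers,
        alpha=alpha,
        strong_alpha=strong_alpha,
    )


@dataclass
class SetDirectionality:
    set_name: str
    n_in_table: int
    n_up: int
    n_down: int
    n_zero: int
    frac_up: float | None
    frac_down: float | None


def set_directionality(table: DETable, gene_set: GeneSet) -> SetDirectionality:
    """Direction of fold changes among a signature's genes present in the
    table, with no significance filter.  Fractions are missing (None) when
    no member of the set is present."""
    df = table.records[table.records["gene"].isin(gene_set.genes)]
    n = len(df)
    n_up = int((df["log2fc"] > 0).sum())
    n_down = int((df["log2fc"] < 0).sum())
    return SetDirectionality(
        set_name=gene_set.name,
        n_in_table=n,
        n_up=n_up,
        n_down=n_down,
        n_zero=n - n_up - n_down,
        frac_up=n_up / n if n else None,
        frac_down=n_down / n if n else None,
    )


def _resolve_column(columns: Sequence[str], key: str) -> str:
    lowered = {c.lower(): c for c in columns}
    for alias in _DE_ALIASES[key]:
        if alias in lowered:
            return lowered[alias]
    raise ValueError(f"no column for {key!r} among {list(columns)}")


def read_de_table(path: str | Path, schema: Mapping[str, str] | None = None) -> DETable:
    """Read a DE result TSV; DESeq column names (log2FoldChange, padj) are
    recognized automatically, or pass ``schema`` to remap explicitly."""
    df = pd.read_csv(path, sep="\t")
    if schema:
        rename = {v: k for k, v in schema.items()}
    else:
        rename = {_resolve_column(df.columns, k): k for k in _DE_ALIASES}
    df = df.rename(columns=rename)
    df["gene"] = df["gene"].astype(str)
    for col in ("log2fc", "pvalue", "padj"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return DETable(records=df[["gene", "log2fc", "pvalue", "padj"]])


def write_de_table(table: DETable, path: str | Path) -> None:
    out = table.records.rename(columns={
        "gene": "gene", "log2fc": "log2FoldChange", "pvalue": "pvalue", "padj": "padj"
    })
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSet(name=parts[0], genes=frozenset(g for g in parts[2:] if g)))
    return sets
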