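"""Developmental co-expression of partner genes with the bait.

Each partner's expression profile across developmental stages and brain
structures is compared with the bait's by Pearson correlation; partners whose
correlation reaches a moderate-to-high positive cutoff are classed as
co-expressed.  Genes absent from the matrix, profiles with fewer than three
samples, and zero-variance profiles yield a *missing* correlation — never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "correlate_with_bait",
    "classify_correlation",
    "read_expression_matrix",
    "write_expression_matrix",
]

#: default cutoff for calling a positive correlation "moderate-to-high"
DEFAULT_CORR_THRESHOLD = 0.58


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with developmental sample metadata.

    ``values`` is genes x samples; ``samples`` (optional) is indexed like the
    columns of ``values`` and carries ``stage`` and ``structure`` labels.
    """

    values: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated gene symbol {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.samples is not None and list(self.samples.index) != list(self.values.columns):
            raise ValueError("sample metadata must match value columns")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def correlate_with_bait(
    matrix: ExpressionMatrix,
    bait: str,
    partners: Iterable[str],
) -> dict[str, float | None]:
    """Pearson correlation of each partner's profile with the bait's.

    Returns ``None`` (missing) for partners absent from the matrix, for
    profiles with fewer than 3 finite samples, and for zero-variance profiles.
    """
    if bait not in matrix.values.index:
        raise KeyError(f"bait {bait!r} not in expression matrix")
    bait_profile = matrix.values.loc[bait].to_numpy(dtype=float)
    out: dict[str, float | None] = {}
    for gene in partners:
        if gene not in matrix.values.index:
            out[gene] = None
            continue
        profile = matrix.values.loc[gene].to_numpy(dtype=float)
        if profile.size < 3:
            warnings.warn(f"{gene}: fewer than 3 samples; correlation missing")
            out[gene] = None
            continue
        if np.std(profile) == 0 or np.std(bait_profile) == 0:
            warnings.warn(f"{gene}: zero-variance profile; correlation missing")
            out[gene] = None
            continue
        rho = float(np.corrcoef(bait_profile, profile)[0, 1])
        out[gene] = float(np.clip(rho, -1.0, 1.0))
    return out


def classify_correlation(
    rho: float | None,
    threshold: float = DEFAULT_CORR_THRESHOLD,
) -> str:
    """Bin a correlation: ``coexpressed`` (rho >= threshold, inclusive),
    ``not-coexpressed``, or ``unknown`` when the value is missing."""
    if rho is None:
        return "unknown"
    return "coexpressed" if rho >= threshold else "not-coexpressed"


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV; optional ``#stage`` / ``#structure`` header
    rows (below the column header) become sample metadata."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_rows = [r for r in df.index if str(r).startswith("#")]
    samples = None
    if meta_rows:
        meta = df.loc[meta_rows].T
        meta.columns = [str(c).lstrip("#") for c in meta.columns]
        samples = meta
        df = df.drop(index=meta_rows)
    return ExpressionMatrix(values=df.astype(float), samples=samples)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    if matrix.samples is not None:
        header = matrix.samples.T.copy()
        header.index = [f"#{c}" for c in header.index]
        df = pd.concat([header, df])
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
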