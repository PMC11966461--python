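"""Readers, writers and in-memory models for the pipeline's tabular data.

The central container is :class:`SpectralCountTable`, a per-protein matrix of
integer peptide-spectrum-match (PSM) counts across immunoprecipitation
conditions and replicate injections, carrying the protein length in amino
acids that NSAF normalization requires.  Annotation rows for the bait's
partner table (known-partner status, disease class, pLI, developmental
co-expression, phosphosites) are modelled by :class:`PartnerAnnotation`; the
published partner table for the DYRK1A bait ships with the package as a
plain-TSV fixture and is exposed through :func:`load_table1_fixture`.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "SpectralCountTable",
    "PartnerAnnotation",
    "read_spectral_counts",
    "write_spectral_counts",
    "load_table1_fixture",
    "read_partner_annotations",
    "write_partner_annotations",
]

_REP_PATTERN = re.compile(r"^(?P<cond>.+)_rep(?P<rep>\d+)$")


@dataclass
class SpectralCountTable:
    """Integer PSM counts per protein across (condition, replicate) cells.

    Parameters
    ----------
    counts
        DataFrame indexed by protein accession with a two-level column
        MultiIndex ``(condition, replicate)``; every cell is an integer >= 0.
    meta
        DataFrame indexed by accession with columns ``symbol`` (non-empty
        string) and ``length_aa`` (positive integer).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex):
            raise ValueError("counts must have (condition, replicate) columns")
        if list(self.counts.index) != list(self.meta.index):
            raise ValueError("counts and meta must share the same accession index")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicated protein accessions")
        conds = self.conditions
        if len(conds) != len(set(conds)):
            raise ValueError("condition labels must be unique")
        vals = self.counts.to_numpy()
        if vals.size:
            if not (vals == vals.astype(int)).all():
                raise ValueError("PSM counts must be integers")
            if (vals < 0).any():
                bad = self.counts.index[(vals < 0).any(axis=1)][0]
                raise ValueError(f"negative PSM count in row {bad!r}")
        if (self.meta["length_aa"] <= 0).any():
            bad = self.meta.index[self.meta["length_aa"] <= 0][0]
            raise ValueError(f"non-positive protein length for {bad!r}")
        if (self.meta["symbol"].astype(str).str.len() == 0).any():
            raise ValueError("empty gene symbol")
        # canonical form: sorted columns, named indices, integer dtype
        self.counts = self.counts.astype(int).sort_index(axis=1)
        self.counts.index.name = "accession"
        self.counts.columns.names = ["condition", "replicate"]
        self.meta = self.meta[["symbol", "length_aa"]].copy()
        self.meta.index.name = "accession"
        self.meta["length_aa"] = self.meta["length_aa"].astype(int)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for cond in self.counts.columns.get_level_values(0):
            if cond not in seen:
                seen.append(cond)
        return seen

    @property
    def accessions(self) -> list[str]:
        return list(self.counts.index)

    def replicates(self, condition: str) -> list[int]:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return sorted(r for c, r in self.counts.columns if c == condition)

    def condition_sums(self) -> pd.DataFrame:
        """Per-protein PSM sum over the replicates of each condition."""
        return self.counts.T.groupby(level=0).sum().T[self.conditions]

    def replicate_counts(self, accession: str, condition: str) -> list[int]:
        row = self.counts.loc[accession, condition]
        return [int(row[r]) for r in self.replicates(condition)]

    def symbol(self, accession: str) -> str:
        return str(self.meta.loc[accession, "symbol"])

    def length(self, accession: str) -> int:
        return int(self.meta.loc[accession, "length_aa"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralCountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.meta.equals(other.meta)


def _flat_columns(table: SpectralCountTable) -> list[str]:
    return [f"{c}_rep{r}" for c, r in table.counts.columns]


def write_spectral_counts(table: SpectralCountTable, path: str | Path) -> None:
    """Serialize a count table as TSV with ``<condition>_rep<k>`` columns."""
    out = table.meta.copy()
    flat = table.counts.copy()
    flat.columns = _flat_columns(table)
    out = pd.concat([out, flat], axis=1)
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


def read_spectral_counts(
    path: str | Path,
    schema: Mapping[str, object] | None = None,
) -> SpectralCountTable:
    """Read a protein-level PSM count export into a :class:`SpectralCountTable`.

    ``schema`` may remap the identifier columns and assign count columns to
    (condition, replicate) slots::

        {"accession": "Accession", "symbol": "Gene", "length": "# AAs",
         "counts": {"Abundance F1": ("Cter", 1), ...}}

    With no ``counts`` entry, columns named ``<condition>_rep<k>`` are
    auto-detected.  Counts must be non-negative integers.
    """
    schema = dict(schema or {})
    acc_col = str(schema.get("accession", "accession"))
    sym_col = str(schema.get("symbol", "symbol"))
    len_col = str(schema.get("length", "length_aa"))
    df = pd.read_csv(path, sep="\t", dtype={acc_col: str})
    for col, what in ((acc_col, "accession"), (sym_col, "symbol"), (len_col, "length")):
        if col not in df.columns:
            raise ValueError(f"missing {what} column {col!r} in {path}")
    count_map: dict[str, tuple[str, int]] = {}
    if "counts" in schema:
        count_map = {str(k): (str(v[0]), int(v[1]))
                     for k, v in dict(schema["counts"]).items()}  # type: ignore[arg-type]
    else:
        for col in df.columns:
            m = _REP_PATTERN.match(col)
            if m and col not in (acc_col, sym_col, len_col):
                count_map[col] = (m.group("cond"), int(m.group("rep")))
    if not count_map:
        raise ValueError(f"no count columns found in {path}")
    df = df.set_index(acc_col)
    for col in count_map:
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            row = df.index[series.isna()][0]
            raise ValueError(f"non-numeric count in column {col!r}, row {row!r}")
        if (series % 1 != 0).any():
            row = df.index[series % 1 != 0][0]
            raise ValueError(f"non-integer count in column {col!r}, row {row!r}")
        if (series < 0).any():
            row = df.index[series < 0][0]
            raise ValueError(f"negative count in column {col!r}, row {row!r}")
        df[col] = series.astype(int)
    counts = df[list(count_map)].copy()
    counts.columns = pd.MultiIndex.from_tuples(
        [count_map[c] for c in counts.columns], names=["condition", "replicate"]
    )
    counts = counts.sort_index(axis=1)
    meta = df[[sym_col, len_col]].rename(columns={sym_col: "symbol", len_col: "length_aa"})
    meta["length_aa"] = pd.to_numeric(meta["length_aa"]).astype(int)
    return SpectralCountTable(counts=counts, meta=meta)


@dataclass
class PartnerAnnotation:
    """One row of the bait's annotated partner table.

    ``psm_cter``/``psm_nter`` are per-antibody PSM sums (replicate-level
    counts are not part of the published table).  Missing pLI or correlation
    values are ``None``, never 0 — a partner with no expression data must not
    be treated as weakly co-expressed.
    """

    symbol: str
    psm_cter: int = 0
    psm_nter: int = 0
    phospho_sites: list[str] = field(default_factory=list)
    known_partner: bool = False
    known_sources: list[str] = field(default_factory=list)
    disease_class: str = "none"  # one of {"none", "NDD", "other"}
    disease_note: str = ""
    pli: float | None = None
    bait_correlation: float | None = None
    aliases: list[str] = field(default_factory=list)
    is_bait: bool = False

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("empty symbol")
        if self.disease_class not in ("none", "NDD", "other"):
            raise ValueError(f"unknown disease class {self.disease_class!r}")
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"pLI out of [0,1] for {self.symbol}: {self.pli}")
        if self.bait_correlation is not None and not -1.0 <= self.bait_correlation <= 1.0:
            raise ValueError(f"correlation out of [-1,1] for {self.symbol}")

    @property
    def names(self) -> set[str]:
        """Primary symbol plus aliases, for gene-set membership tests."""
        return {self.symbol, *self.aliases}


def _split(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    text = str(cell).strip()
    return [t for t in text.split(";") if t] if text else []


def _opt_float(cell: object) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text in ("", "-", "NA"):
        return None
    return float(text)


def read_partner_annotations(path: str | Path) -> list[PartnerAnnotation]:
    """Read an annotation TSV (the dialect written by the fixture and CLI)."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
    rows: list[PartnerAnnotation] = []
    for _, r in df.iterrows():
        disease = str(r.get("disease_class", "none")).strip() or "none"
        rows.append(
            PartnerAnnotation(
                symbol=str(r["symbol"]),
                psm_cter=int(r.get("psm_cter", 0)),
                psm_nter=int(r.get("psm_nter", 0)),
                phospho_sites=_split(r.get("phospho")),
                known_partner=str(r.get("known_partner", "")).strip().lower() == "yes",
                known_sources=_split(r.get("known_sources")),
                disease_class=disease,
                disease_note=str(r["disease_note"]).strip()
                if "disease_note" in r and pd.notna(r["disease_note"]) else "",
                pli=_opt_float(r.get("pli")),
                bait_correlation=_opt_float(r.get("correlation")),
                aliases=_split(r.get("aliases")),
                is_bait=bool(int(r.get("is_bait", 0))),
            )
        )
    return rows


def write_partner_annotations(rows: Sequence[PartnerAnnotation], path: str | Path) -> None:
    records = []
    for a in rows:
        records.append({
            "symbol": a.symbol,
            "aliases": ";".join(a.aliases),
            "psm_cter": a.psm_cter,
            "psm_nter": a.psm_nter,
            "phospho": ";".join(a.phospho_sites),
            "known_partner": "yes" if a.known_partner else "no",
            "known_sources": ";".join(a.known_sources),
            "disease_class": a.disease_class,
            "disease_note": a.disease_note,
            "pli": "" if a.pli is None else a.pli,
            "correlation": "" if a.bait_correlation is None else a.bait_correlation,
            "is_bait": int(a.is_bait),
        })
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def load_table1_fixture() -> list[PartnerAnnotation]:
    """The packaged DYRK1A partner table: bait row plus 35 partners.

    Per-antibody PSM values are condition-level sums; replicate-level counts
    are not published, so operations needing per-replicate data refuse this
    input and callers use :func:`neurointeract.interactor_calling.count_summary`.
    """
    ref = importlib.resources.files("neurointeract").joinpath("data/table1_interactors.tsv")
    with importlib.resources.as_file(ref) as path:
        rows = read_partner_annotations(path)
    # the bait row's known-partner cell is not applicable, not "no"
    for row in rows:
        if row.is_bait:
            row.known_partner = False
    return rows
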