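"""Phenotype-term overlap and NDD-candidate flagging.

The bait syndrome maps to a set of clinical-sign terms (HPO-style
identifiers).  For each disease caused by mutation of a partner gene we count
what fraction of the bait syndrome's terms it shares (exact identifier
intersection, no ontology-graph propagation), and overall what fraction is
covered by the union of partner-linked diseases.

A partner is flagged as an NDD candidate when it has no known disease
involvement, is highly intolerant to loss-of-function (pLI above threshold),
and its developmental expression correlates strongly with the bait's.
Missing pLI or correlation disqualifies — candidacy requires positive
evidence on all three axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .tables_io import PartnerAnnotation

__all__ = [
    "TermSet",
    "CandidateFlag",
    "phenotype_overlap",
    "flag_candidates",
    "read_term_links",
    "write_term_links",
]

DEFAULT_PLI_THRESHOLD = 0.9
DEFAULT_CORR_THRESHOLD = 0.58


@dataclass(frozen=True)
class TermSet:
    """A disease (or syndrome) and its set of phenotype-term identifiers."""

    id: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))


def phenotype_overlap(
    bait_terms: TermSet,
    disease_terms: Mapping[str, TermSet],
) -> tuple[float, dict[str, float]]:
    """Fraction of the bait syndrome's clinical signs covered by partner
    diseases, overall and per disease.

    Returns ``(covered_fraction, per_disease_fraction)`` where
    ``covered_fraction = |bait ∩ union(diseases)| / |bait|``.
    """
    if not bait_terms.terms:
        raise ValueError("bait syndrome term set is empty")
    n = len(bait_terms.terms)
    union: set[str] = set()
    per_disease: dict[str, float] = {}
    for disease, ts in disease_terms.items():
        shared = bait_terms.terms & ts.terms
        union |= shared
        per_disease[disease] = len(shared) / n
    return len(union) / n, per_disease


@dataclass
class CandidateFlag:
    symbol: str
    is_candidate: bool
    reasons: list[str] = field(default_factory=list)


def flag_candidates(
    annotations: Sequence[PartnerAnnotation],
    pli_threshold: float = DEFAULT_PLI_THRESHOLD,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> list[CandidateFlag]:
    """Flag partners that are plausible novel NDD genes.

    A partner qualifies iff it has no recorded disease involvement, pLI is
    present and strictly above ``pli_threshold``, and the bait co-expression
    correlation is present and at least ``corr_threshold``.  The bait row is
    skipped.
    """
    flags: list[CandidateFlag] = []
    for a in annotations:
        if a.is_bait:
            continue
        reasons: list[str] = []
        if a.disease_class == "none":
            reasons.append("no_known_disease")
        if a.pli is not None and a.pli > pli_threshold:
            reasons.append("pli_high")
        if a.bait_correlation is not None and a.bait_correlation >= corr_threshold:
            reasons.append("coexpressed")
        flags.append(CandidateFlag(
            symbol=a.symbol,
            is_candidate=len(reasons) == 3,
            reasons=reasons,
        ))
    return flags


def read_term_links(path: str | Path) -> dict[str, TermSet]:
    """Read a two-column TSV (disease_id, term_id) into term sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (disease_id, term_id)")
    disease_col, term_col = df.columns[:2]
    out: dict[str, TermSet] = {}
    for disease, grp in df.groupby(disease_col, sort=False):
        out[str(disease)] = TermSet(id=str(disease), terms=frozenset(grp[term_col]))
    return out


def write_term_links(term_sets: Mapping[str, TermSet], path: str | Path) -> None:
    records = [
        {"disease_id": disease, "term_id": term}
        for disease, ts in term_sets.items()
        for term in sorted(ts.terms)
    ]
    pd.DataFrame.from_records(records, columns=["disease_id", "term_id"]).to_csv(
        path, sep="\t", index=False
    )
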