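"""NSAF computation and the three-criterion candidate-interactor filter.

A protein is called a candidate interactor for a given bait antibody when it
simultaneously (1) stays below a PSM bound in every mock-purification control
condition, (2) is reproducibly detected in the bait pull-down (replicate sum
at or above a minimum with every replicate positive), and (3) is enriched over
the controls by a normalized spectral abundance factor (NSAF) ratio of at
least 1.5.  NSAF for protein *i* in a scope (one run, or one condition with
replicates summed) is ``(SpC_i / L_i) / sum_j (SpC_j / L_j)`` with ``SpC``
the spectral count and ``L`` the protein length in amino acids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tables_io import PartnerAnnotation, SpectralCountTable

__all__ = [
    "compute_nsaf",
    "criterion1_control_clean",
    "criterion2_test_supported",
    "criterion3_nsaf_enriched",
    "call_interactors",
    "count_summary",
    "AntibodyCall",
    "InteractorCall",
    "SummaryCounts",
]


def compute_nsaf(table: SpectralCountTable, scope: str = "condition") -> pd.DataFrame:
    """Normalized spectral abundance factors per protein.

    ``scope='condition'`` sums replicates before normalizing and returns one
    column per condition; ``scope='run'`` normalizes each (condition,
    replicate) injection separately.  Columns whose counts are all zero come
    back all-zero with a warning rather than dividing by zero.
    """
    if scope == "condition":
        counts = table.condition_sums()
    elif scope == "run":
        counts = table.counts
    else:
        raise ValueError(f"unknown scope {scope!r}")
    lengths = table.meta["length_aa"]
    saf = counts.div(lengths, axis=0)
    totals = saf.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        warnings.warn(f"all-zero counts in scope(s) {list(zero_cols)}; NSAF set to 0")
        totals = totals.replace(0, 1.0)
    return saf.div(totals, axis=1)


def criterion1_control_clean(
    control_sums: Mapping[str, int],
    bound: int = 5,
    mode: str = "per_condition",
) -> bool:
    """Control-cleanliness criterion.

    ``per_condition`` (default): the replicate sum of *every* control
    condition is strictly below ``bound`` — a control sum equal to the bound
    fails.  ``grand_sum``: the total over all control conditions is below the
    bound (a weaker alternative reading, kept selectable).
    """
    if not control_sums:
        raise ValueError("no control conditions given")
    if mode == "per_condition":
        return all(s < bound for s in control_sums.values())
    if mode == "grand_sum":
        return sum(control_sums.values()) < bound
    raise ValueError(f"unknown criterion-1 mode {mode!r}")


def criterion2_test_supported(replicate_counts: Sequence[int], min_sum: int = 5) -> bool:
    """Reproducible detection: replicate sum >= ``min_sum`` and every replicate > 0."""
    counts = list(replicate_counts)
    if not counts:
        raise ValueError("need at least one replicate")
    return sum(counts) >= min_sum and all(c > 0 for c in counts)


def criterion3_nsaf_enriched(
    test_nsaf: float,
    control_nsafs: Sequence[float],
    ratio_threshold: float = 1.5,
    control_ref: str = "max",
) -> tuple[bool, float]:
    """NSAF enrichment of the bait pull-down over the controls.

    The control reference is the maximum control NSAF by default (most
    conservative; ``mean`` and ``sum`` are selectable).  When the reference is
    zero the ratio is ``+inf`` if the test NSAF is positive (pass) and 0.0 if
    the test NSAF is also zero (no evidence, fail).
    """
    if test_nsaf < 0 or any(c < 0 for c in control_nsafs):
        raise ValueError("NSAF values must be non-negative")
    refs = list(control_nsafs)
    if not refs:
        raise ValueError("no control NSAF values given")
    if control_ref == "max":
        ref = max(refs)
    elif control_ref == "mean":
        ref = sum(refs) / len(refs)
    elif control_ref == "sum":
        ref = sum(refs)
    else:
        raise ValueError(f"unknown control reference {control_ref!r}")
    if ref == 0.0:
        ratio = math.inf if test_nsaf > 0 else 0.0
    else:
        ratio = test_nsaf / ref
    return ratio >= ratio_threshold, ratio


@dataclass
class AntibodyCall:
    """Outcome of the three criteria for one protein under one bait antibody."""

    criterion1_pass: bool
    criterion2_pass: bool
    criterion3_pass: bool
    nsaf_ratio: float

    @property
    def called(self) -> bool:
        return self.criterion1_pass and self.criterion2_pass and self.criterion3_pass


@dataclass
class InteractorCall:
    accession: str
    symbol: str
    per_antibody: dict[str, AntibodyCall]
    is_bait: bool = False

    @property
    def called(self) -> bool:
        return any(c.called for c in self.per_antibody.values())

    @property
    def support_class(self) -> str:
        hits = [ab for ab, c in self.per_antibody.items() if c.called]
        if len(hits) == len(self.per_antibody) and len(hits) > 1:
            return "both"
        if len(hits) == 1:
            return f"{hits[0]}-only"
        if not hits:
            return "none"
        return "+".join(hits)


def call_interactors(
    table: SpectralCountTable,
    bait_conditions: Sequence[str],
    control_conditions: Sequence[str],
    bait_symbol: str | None = None,
    control_psm_bound: int = 5,
    test_psm_min: int = 5,
    nsaf_ratio_threshold: float = 1.5,
    criterion1_mode: str = "per_condition",
    control_ref: str = "max",
) -> list[InteractorCall]:
    """Apply the three-criterion filter per protein and per bait antibody.

    The bait protein itself (matched by ``bait_symbol``) is returned with
    ``is_bait=True`` and must never be counted among the partners.
    """
    if not isinstance(table, SpectralCountTable):
        raise TypeError(
            "call_interactors needs replicate-level counts (SpectralCountTable); "
            "annotation rows with per-antibody sums go through count_summary()"
        )
    for cond in list(bait_conditions) + list(control_conditions):
        if cond not in table.conditions:
            raise KeyError(f"condition {cond!r} not in table (has {table.conditions})")
    nsaf = compute_nsaf(table, scope="condition")
    sums = table.condition_sums()
    calls: list[InteractorCall] = []
    for acc in table.accessions:
        control_sums = {c: int(sums.loc[acc, c]) for c in control_conditions}
        c1 = criterion1_control_clean(control_sums, bound=control_psm_bound,
                                      mode=criterion1_mode)
        per_ab: dict[str, AntibodyCall] = {}
        for bait_cond in bait_conditions:
            reps = table.replicate_counts(acc, bait_cond)
            c2 = criterion2_test_supported(reps, min_sum=test_psm_min)
            c3, ratio = criterion3_nsaf_enriched(
                float(nsaf.loc[acc, bait_cond]),
                [float(nsaf.loc[acc, c]) for c in control_conditions],
                ratio_threshold=nsaf_ratio_threshold,
                control_ref=control_ref,
            )
            per_ab[bait_cond] = AntibodyCall(c1, c2, c3, ratio)
        calls.append(InteractorCall(
            accession=acc,
            symbol=table.symbol(acc),
            per_antibody=per_ab,
            is_bait=bait_symbol is not None and table.symbol(acc) == bait_symbol,
        ))
    return calls


def calls_to_frame(calls: Iterable[InteractorCall]) -> pd.DataFrame:
    """Flatten interactor calls into a tidy per-protein table."""
    records = []
    for call in calls:
        rec: dict[str, object] = {
            "accession": call.accession,
            "symbol": call.symbol,
            "is_bait": call.is_bait,
            "called": call.called,
            "support_class": call.support_class,
        }
        for ab, c in call.per_antibody.items():
            rec[f"{ab}_criterion1"] = c.criterion1_pass
            rec[f"{ab}_criterion2"] = c.criterion2_pass
            rec[f"{ab}_criterion3"] = c.criterion3_pass
            rec[f"{ab}_nsaf_ratio"] = c.nsaf_ratio
            rec[f"{ab}_called"] = c.called
        records.append(rec)
    return pd.DataFrame.from_records(records)


@dataclass
class SummaryCounts:
    """Partner-table headline counts (bait always excluded)."""

    n_partners: int
    n_both_antibodies: int
    n_known: int
    n_novel: int
    n_disease: int
    n_ndd: int
    n_coexpressed: int
    n_phospho_partners: int
    n_in_set: int = 0
    n_in_set_novel: int = 0
    gene_set_name: str = ""

    def as_dict(self) -> dict[str, object]:
        return dict(self.__dict__)


def count_summary(
    annotations: Sequence[PartnerAnnotation],
    corr_threshold: float = 0.58,
    dual_min_psm: int = 5,
    gene_set: set[str] | None = None,
    gene_set_name: str = "",
) -> SummaryCounts:
    """Headline counts over an annotated partner table.

    Dual-antibody support is decided from per-antibody PSM sums (both >=
    ``dual_min_psm``) because the published table carries condition-level sums
    only; this proxy is specific to annotation-level input.  A partner with a
    missing correlation is never counted as co-expressed.  Gene-set membership
    honours aliases (e.g. CDC16/ANAPC6).
    """
    partners = [a for a in annotations if not a.is_bait]
    both = [a for a in partners
            if a.psm_cter >= dual_min_psm and a.psm_nter >= dual_min_psm]
    known = [a for a in partners if a.known_partner]
    disease = [a for a in partners if a.disease_class != "none"]
    ndd = [a for a in partners if a.disease_class == "NDD"]
    coexpr = [a for a in partners
              if a.bait_correlation is not None and a.bait_correlation >= corr_threshold]
    phospho = [a for a in partners if a.phospho_sites]
    in_set: list[PartnerAnnotation] = []
    if gene_set:
        in_set = [a for a in partners if a.names & gene_set]
    return SummaryCounts(
        n_partners=len(partners),
        n_both_antibodies=len(both),
        n_known=len(known),
        n_novel=len(partners) - len(known),
        n_disease=len(disease),
        n_ndd=len(ndd),
        n_coexpressed=len(coexpr),
        n_phospho_partners=len(phospho),
        n_in_set=len(in_set),
        n_in_set_novel=sum(1 for a in in_set if not a.known_partner),
        gene_set_name=gene_set_name,
    )
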