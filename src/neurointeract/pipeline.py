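"""End-to-end orchestration: configuration, stage logging, consolidated report.

A run takes whatever inputs the configuration points at — a spectral-count
table for interactor calling, an annotated partner table for headline counts
and candidate flagging, an expression matrix for co-expression, phenotype
term links for overlap scoring, DE tables and gene sets for directionality —
executes the applicable stages, and emits one JSON-serializable report that
embeds the exact configuration used, so a run is reproducible from its own
report.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import coexpression, deg_summary, interactor_calling, phenotype_prioritization
from . import tables_io

logger = logging.getLogger("neurointeract")

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Thresholds, condition labels and input paths for one pipeline run."""

    bait_symbol: str = "DYRK1A"
    bait_conditions: list[str] = field(default_factory=lambda: ["Cter", "Nter"])
    control_conditions: list[str] = field(default_factory=lambda: ["Beads", "MAR", "RAM"])
    control_psm_bound: int = 5
    test_psm_min: int = 5
    nsaf_ratio: float = 1.5
    criterion1_mode: str = "per_condition"
    nsaf_control_ref: str = "max"
    corr_threshold: float = 0.58
    pli_threshold: float = 0.9
    deg_alpha: float = 0.1
    deg_strong_alpha: float = 0.05
    dual_min_psm: int = 5
    gene_set_name: str = ""
    gene_set: list[str] = field(default_factory=list)
    counts_path: str = ""
    counts_schema: dict[str, Any] = field(default_factory=dict)
    annotations_path: str = ""   # "fixture" loads the packaged partner table
    expression_path: str = ""
    terms_path: str = ""
    de_path: str = ""
    gmt_path: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("control_psm_bound", "test_psm_min", "nsaf_ratio",
                     "corr_threshold", "pli_threshold", "deg_alpha",
                     "deg_strong_alpha", "dual_min_psm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _stage(name: str, n_in: int | None = None, n_out: int | None = None) -> None:
    detail = ""
    if n_in is not None or n_out is not None:
        detail = f" (in={n_in}, out={n_out})"
    logger.info("stage %s%s", name, detail)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage whose inputs are configured; return the report dict."""
    report: dict[str, Any] = {"config": config.to_dict(), "stages": []}

    annotations: list[tables_io.PartnerAnnotation] = []
    if config.annotations_path == "fixture":
        annotations = tables_io.load_table1_fixture()
    elif config.annotations_path:
        annotations = tables_io.read_partner_annotations(config.annotations_path)

    if config.counts_path:
        table = tables_io.read_spectral_counts(
            config.counts_path, schema=config.counts_schema or None
        )
        calls = interactor_calling.call_interactors(
            table,
            bait_conditions=config.bait_conditions,
            control_conditions=config.control_conditions,
            bait_symbol=config.bait_symbol,
            control_psm_bound=config.control_psm_bound,
            test_psm_min=config.test_psm_min,
            nsaf_ratio_threshold=config.nsaf_ratio,
            criterion1_mode=config.criterion1_mode,
            control_ref=config.nsaf_control_ref,
        )
        called = [c for c in calls if c.called and not c.is_bait]
        _stage("interactor_calling", len(calls), len(called))
        report["stages"].append("interactor_calling")
        report["interactor_calls"] = {
            "n_proteins": len(calls),
            "n_called_partners": len(called),
            "called": sorted(c.symbol for c in called),
            "support_classes": {c.symbol: c.support_class for c in called},
        }

    if annotations:
        gene_set = set(config.gene_set) or None
        summary = interactor_calling.count_summary(
            annotations,
            corr_threshold=config.corr_threshold,
            dual_min_psm=config.dual_min_psm,
            gene_set=gene_set,
            gene_set_name=config.gene_set_name,
        )
        _stage("count_summary", len(annotations), summary.n_partners)
        report["stages"].append("count_summary")
        report["summary_counts"] = summary.as_dict()

        flags = phenotype_prioritization.flag_candidates(
            annotations,
            pli_threshold=config.pli_threshold,
            corr_threshold=config.corr_threshold,
        )
        candidates = sorted(f.symbol for f in flags if f.is_candidate)
        _stage("flag_candidates", len(flags), len(candidates))
        report["stages"].append("flag_candidates")
        report["candidates"] = candidates

    if config.expression_path and annotations:
        matrix = coexpression.read_expression_matrix(config.expression_path)
        partners = [a.symbol for a in annotations if not a.is_bait]
        corr = coexpression.correlate_with_bait(matrix, config.bait_symbol, partners)
        classes = {g: coexpression.classify_correlation(r, config.corr_threshold)
                   for g, r in corr.items()}
        _stage("coexpression", len(partners),
               sum(1 for c in classes.values() if c == "coexpressed"))
        report["stages"].append("coexpression")
        report["coexpression"] = {
            "correlations": {g: (None if r is None else round(r, 6))
                             for g, r in corr.items()},
            "classes": classes,
        }

    if config.terms_path:
        term_sets = phenotype_prioritization.read_term_links(config.terms_path)
        bait_id = config.bait_symbol + "_SYNDROME"
        bait_candidates = [k for k in term_sets
                           if k == bait_id or k.endswith("_SYNDROME") or k == "BAIT_SYNDROME"]
        if not bait_candidates:
            raise ValueError("terms file lacks a bait syndrome term set")
        bait_terms = term_sets.pop(bait_candidates[0])
        covered, per_disease = phenotype_prioritization.phenotype_overlap(
            bait_terms, term_sets
        )
        _stage("phenotype_overlap", len(bait_terms.terms), None)
        report["stages"].append("phenotype_overlap")
        report["phenotype_overlap"] = {
            "covered_fraction": covered,
            "per_disease_fraction": per_disease,
        }

    if config.de_path:
        de = deg_summary.read_de_table(config.de_path)
        deg = deg_summary.call_degs(de, alpha=config.deg_alpha,
                                    strong_alpha=config.deg_strong_alpha)
        _stage("call_degs", len(de), deg.n_deg)
        report["stages"].append("call_degs")
        report["deg"] = {
            "n_deg": deg.n_deg, "n_up": deg.n_up,
            "n_down": deg.n_down, "n_zero": deg.n_zero,
        }
        if config.gmt_path:
            directions = []
            for gs in deg_summary.read_gmt(config.gmt_path):
                d = deg_summary.set_directionality(de, gs)
                directions.append({
                    "set": d.set_name, "n_in_table": d.n_in_table,
                    "n_up": d.n_up, "n_down": d.n_down, "n_zero": d.n_zero,
                    "frac_up": d.frac_up, "frac_down": d.frac_down,
                })
            _stage("set_directionality", len(directions), None)
            report["stages"].append("set_directionality")
            report["set_directionality"] = directions

    if not report["stages"]:
        raise ValueError("configuration selects no stage (no inputs given)")
    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    def _default(obj: Any) -> Any:
        if isinstance(obj, float) and math.isinf(obj):
            return "inf"
        raise TypeError(f"not serializable: {obj!r}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
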