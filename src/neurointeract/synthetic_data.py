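"""Synthetic inputs with ground truth for every pipeline stage.

Each generator emulates the *shape* of one real input — an AP-MS spectral
count export with bait and mock-control conditions, a developmental
expression matrix, a DESeq-style differential-expression table, a
disease-to-phenotype-term annotation — and returns the planted truth
alongside, so recovery can be measured.  Spectral counts follow an
overdispersed negative-binomial model; no claim is made that its defaults
match any particular instrument.  All generators are deterministic given
their seed and touch no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpression import ExpressionMatrix
from .deg_summary import DETable, GeneSet
from .phenotype_prioritization import TermSet
from .tables_io import SpectralCountTable

__all__ = [
    "SimTruth",
    "simulate_apms",
    "simulate_expression",
    "simulate_de_table",
    "simulate_ontology",
]

_STAGES = ["8pcw", "12pcw", "16pcw", "21pcw", "37pcw", "4mos", "1yr", "8yr"]
_STRUCTURES = ["DFC", "HIP", "V1C", "CBC"]


@dataclass
class SimTruth:
    """Ground-truth labels emitted by the generators."""

    seed: int
    true_interactors: set[str] = field(default_factory=set)
    planted_corr: dict[str, float] = field(default_factory=dict)
    planted_up_sets: dict[str, float] = field(default_factory=dict)
    planted_down_sets: dict[str, float] = field(default_factory=dict)


def _protein_rate(rng: np.random.Generator, mean: float, dispersion: float) -> float:
    """Protein-specific abundance rate: Gamma with shape ``dispersion`` and
    the given mean.  Poisson counts drawn from such a rate are marginally
    negative-binomial with variance ``mean + mean^2/dispersion``."""
    if mean <= 0:
        return 0.0
    return float(rng.gamma(dispersion, mean / dispersion))


def simulate_apms(
    n_background: int = 200,
    n_true: int = 5,
    bait_mean: float = 30.0,
    background_mean: float = 0.5,
    replicates: int = 3,
    bait_conditions: Sequence[str] = ("Cter", "Nter"),
    control_conditions: Sequence[str] = ("Beads", "MAR", "RAM"),
    control_leak_mean: float = 0.05,
    bait_protein_mean: float = 90.0,
    dispersion: float = 5.0,
    length_range: tuple[int, int] = (100, 2000),
    seed: int = 0,
) -> tuple[SpectralCountTable, SimTruth]:
    """Simulate an immunoprecipitation spectral-count experiment.

    All count means are per-condition sums over the replicate injections, the
    scale on which published per-antibody PSM numbers are reported; each
    replicate draws Poisson counts at ``mean / replicates``.  The universe
    holds one bait protein (``bait_protein_mean`` in the bait pull-downs),
    ``n_true`` planted interactors (``bait_mean`` in the bait conditions,
    near-zero leakage into controls) and ``n_background`` sticky background
    proteins with the same mean (``background_mean``) in every condition.
    Background stickiness is protein-intrinsic: each background protein draws
    one gamma-distributed rate applied to every condition (marginally
    negative-binomial with the given dispersion), the way bead-binding
    contaminants reproduce across pull-downs.  Protein lengths are uniform
    over ``length_range`` amino acids.
    """
    if n_background < 0 or n_true < 0 or replicates < 1:
        raise ValueError("invalid experiment sizes")
    if bait_mean <= 0 or background_mean <= 0:
        raise ValueError("count means must be positive")
    rng = np.random.default_rng(seed)
    symbols = (["DYRK1A"]
               + [f"TRUE{i + 1:03d}" for i in range(n_true)]
               + [f"BG{i + 1:04d}" for i in range(n_background)])
    accessions = [f"SIM{i:05d}" for i in range(len(symbols))]
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=len(symbols))
    conditions = list(bait_conditions) + list(control_conditions)
    cols = pd.MultiIndex.from_tuples(
        [(c, r + 1) for c in conditions for r in range(replicates)],
        names=["condition", "replicate"],
    )
    counts = np.zeros((len(symbols), len(cols)), dtype=int)
    for i, sym in enumerate(symbols):
        if sym == "DYRK1A":
            bait_rate = bait_protein_mean
            ctrl_rate = control_leak_mean
        elif sym.startswith("TRUE"):
            bait_rate = bait_mean
            ctrl_rate = control_leak_mean
        else:
            rate = _protein_rate(rng, background_mean, dispersion)
            bait_rate = ctrl_rate = rate
        for j, (cond, _rep) in enumerate(cols):
            rate = (bait_rate if cond in bait_conditions else ctrl_rate) / replicates
            counts[i, j] = rng.poisson(rate) if rate > 0 else 0
    table = SpectralCountTable(
        counts=pd.DataFrame(counts, index=accessions, columns=cols),
        meta=pd.DataFrame(
            {"symbol": symbols, "length_aa": lengths.astype(int)}, index=accessions
        ),
    )
    truth = SimTruth(
        seed=seed,
        true_interactors={s for s in symbols if s.startswith("TRUE")},
    )
    return table, truth


def simulate_expression(
    n_genes: int = 100,
    n_samples: int = 40,
    bait: str = "DYRK1A",
    planted_corr: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate a developmental expression matrix with planted correlations.

    Each planted gene's profile is ``rho * z_bait + sqrt(1 - rho^2) *
    noise_sd * eps`` with ``z_bait`` the standardized bait profile and ``eps``
    independent standard normal; at ``noise_sd=1`` the realized Pearson
    correlation converges to the planted ``rho`` as samples grow.  Remaining
    genes are independent noise.  Samples carry cycling developmental-stage
    and brain-structure labels.
    """
    planted = dict(planted_corr or {})
    for gene, rho in planted.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"planted correlation out of [-1,1] for {gene}")
    rng = np.random.default_rng(seed)
    z_bait = rng.standard_normal(n_samples)
    z_bait = (z_bait - z_bait.mean()) / z_bait.std()
    profiles: dict[str, np.ndarray] = {bait: z_bait}
    for gene, rho in planted.items():
        eps = rng.standard_normal(n_samples)
        profiles[gene] = rho * z_bait + np.sqrt(1.0 - rho**2) * noise_sd * eps
    n_filler = max(0, n_genes - len(profiles))
    for i in range(n_filler):
        profiles[f"G{i + 1:04d}"] = rng.standard_normal(n_samples)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "stage": [_STAGES[i % len(_STAGES)] for i in range(n_samples)],
            "structure": [_STRUCTURES[(i // len(_STAGES)) % len(_STRUCTURES)]
                          for i in range(n_samples)],
        },
        index=sample_ids,
    )
    values = pd.DataFrame(profiles, index=sample_ids).T
    return ExpressionMatrix(values=values, samples=samples)


def simulate_de_table(
    n_genes: int = 1000,
    sets: Sequence[tuple[GeneSet, float, float]] = (),
    sig_fraction: float = 0.05,
    background_lfc_sd: float = 0.3,
    seed: int = 0,
) -> tuple[DETable, SimTruth]:
    """Simulate a DESeq-style result table with planted set directionality.

    ``sets`` lists ``(gene_set, p_up, effect_size)`` triples: each member
    gene present in the table gets a log2 fold change whose sign is positive
    with probability ``p_up`` and magnitude around ``effect_size``.
    Background genes get centred fold changes, and adjusted p-values are
    drawn so that about ``sig_fraction`` of genes fall below 0.1.
    """
    for _, p_up, _ in sets:
        if not 0.0 <= p_up <= 1.0:
            raise ValueError("p_up must be in [0,1]")
    rng = np.random.default_rng(seed)
    set_genes: dict[str, tuple[float, float]] = {}
    for gene_set, p_up, effect in sets:
        for g in sorted(gene_set.genes):
            set_genes.setdefault(g, (p_up, effect))
    background = [f"G{i + 1:05d}" for i in range(max(0, n_genes - len(set_genes)))]
    genes = list(set_genes) + background
    lfc = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g in set_genes:
            p_up, effect = set_genes[g]
            sign = 1.0 if rng.random() < p_up else -1.0
            lfc[i] = sign * abs(rng.normal(effect, effect / 4 if effect else 0.1))
        else:
            lfc[i] = rng.normal(0.0, background_lfc_sd)
    sig = rng.random(len(genes)) < sig_fraction
    padj = np.where(sig, rng.uniform(0.0, 0.1, len(genes)),
                    rng.uniform(0.1, 1.0, len(genes)))
    pvalue = padj * rng.uniform(0.0, 1.0, len(genes))
    table = DETable(records=pd.DataFrame({
        "gene": genes, "log2fc": lfc, "pvalue": pvalue, "padj": padj,
    }))
    truth = SimTruth(
        seed=seed,
        planted_up_sets={gs.name: p_up for gs, p_up, _ in sets if p_up >= 0.5},
        planted_down_sets={gs.name: p_up for gs, p_up, _ in sets if p_up < 0.5},
    )
    return table, truth


def simulate_ontology(
    n_terms_bait: int = 73,
    n_diseases: int = 3,
    overlap_fracs: Sequence[float] = (0.3, 0.2, 0.1),
    n_private_terms: int = 5,
    seed: int = 0,
) -> tuple[TermSet, dict[str, TermSet]]:
    """Simulate a bait syndrome term set and partner-disease term sets.

    Disease *k* shares exactly ``round(overlap_fracs[k] * n_terms_bait)``
    terms with the bait set; shared blocks are carved from disjoint stretches
    of the bait set while terms remain, so modest overlap fractions sum
    exactly in the union.  Each disease also carries private terms.
    """
    if len(overlap_fracs) != n_diseases:
        raise ValueError("need one overlap fraction per disease")
    for f in overlap_fracs:
        if not 0.0 <= f <= 1.0:
            raise ValueError("overlap fractions must be in [0,1]")
    rng = np.random.default_rng(seed)
    bait_terms = [f"HP:{i + 1:07d}" for i in range(n_terms_bait)]
    bait = TermSet(id="BAIT_SYNDROME", terms=frozenset(bait_terms))
    diseases: dict[str, TermSet] = {}
    cursor = 0
    private_counter = 0
    for k, frac in enumerate(overlap_fracs):
        n_shared = round(frac * n_terms_bait)
        if cursor + n_shared <= n_terms_bait:
            shared = bait_terms[cursor:cursor + n_shared]
            cursor += n_shared
        else:  # bait set exhausted: reuse a random subset
            shared = list(rng.choice(bait_terms, size=n_shared, replace=False))
        private = [f"HP:9{private_counter + i:06d}" for i in range(n_private_terms)]
        private_counter += n_private_terms
        diseases[f"DISEASE_{k + 1}"] = TermSet(
            id=f"DISEASE_{k + 1}", terms=frozenset(shared + private)
        )
    return bait, diseases
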