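# Methods

## Interactor calling

The filter operates on protein-level PSM counts from an immunoprecipitation
experiment with two bait antibodies (C-terminal, N-terminal; conditions
`Cter`, `Nter`) and three mock controls (`Beads`, `MAR`, `RAM`), three
replicate injections each.  A protein is called for an antibody iff:

1. **Control cleanliness** — the replicate PSM sum of *every* control
   condition is strictly below 5.  The bound is per control condition, not a
   grand sum over controls; a grand-sum variant is selectable
   (`criterion1_mode="grand_sum"`) but per-condition is the default and the
   stricter reading.  A control sum of exactly 5 fails.
2. **Reproducible detection** — the bait condition's replicate sum is ≥ 5
   (inclusive) with every replicate strictly positive, so a single replicate
   spike cannot qualify a protein.
3. **NSAF enrichment** — the bait-condition NSAF divided by the control
   reference is ≥ 1.5 (inclusive).

NSAF is computed on condition-level sums by default (per-injection scope is
available): `NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j)` within the scope, with
`L_i` the protein length in amino acids.  Within any scope that has a nonzero
count, NSAF sums to 1 (asserted to 1e−9); an all-zero scope yields all-zero
NSAF and a warning.

Open choices resolved here (each configurable):

- **Control reference for the ratio** — the *maximum* NSAF over control
  conditions, the most conservative aggregation (`mean` and `sum`
  selectable).
- **Zero-control handling** — when every control NSAF is 0 the ratio is +∞
  and criterion 3 passes iff the test NSAF is positive; a protein absent from
  bait and controls alike has ratio 0 and fails (absence is not evidence).
- **Bait handling** — the bait protein is reported (`is_bait=True`) but never
  counted among partners.

The filter is monotone: raising a bait count never un-calls a called protein,
raising a control count never adds a call.  With the control bound relaxed to
∞ and the ratio threshold to ~0, the call set reduces exactly to the
criterion-2 passers.

## Partner-table summaries

The packaged partner table carries per-antibody PSM *sums* only (replicate
splits are not published), so `call_interactors` refuses annotation input and
summary counting uses `count_summary`, where dual-antibody support is defined
as both per-antibody sums ≥ 5.  This annotation-level proxy reproduces the
published dual-antibody count and is used nowhere else.  Missing pLI and
correlation values are explicit missing (`None`), never 0: a partner without
expression data is classed `unknown`, not `not-coexpressed`, and cannot be
flagged as a candidate.  Gene-set membership honours aliases (CDC16/ANAPC6,
CDC27/ANAPC3, CDC23/ANAPC8), so complex membership counts are robust to which
symbol a set uses.

## Co-expression and candidate flagging

Partner profiles are correlated with the bait's across whatever samples the
expression matrix provides (Pearson; at least 3 samples and nonzero variance
required, otherwise missing-with-warning).  The "moderate-to-high"
co-expression cutoff defaults to **0.58 inclusive**.  The published analysis
does not state its cutoff; 0.58 is the value at which the packaged partner
correlations reproduce the published co-expressed count (11 of 35), and it is
configurable.  The co-expressed fraction is reported over all partners,
including the one with a missing correlation.

A partner is an NDD candidate iff all three hold: no recorded disease
involvement, pLI strictly above 0.9, correlation at least 0.58.  Missing
values disqualify (conservative).  On the packaged table this flags DCAF7,
GSPT1 and PRRC2B — the rule is a screen, not a ranked shortlist, and the
first two are the canonical examples.

Phenotype overlap is exact term-identifier intersection: coverage =
|bait ∩ ∪diseases| / |bait|, per-disease likewise.  No ontology-graph
propagation to ancestor terms is attempted; overlap through semantically
related but distinct terms is therefore undercounted relative to analyses
run against a live ontology.

## DEG tiering and set directionality

DEGs are `padj < 0.1` (strict), tiered strong (`< 0.05`) / moderate
(`0.05 ≤ padj < 0.1`).  Adjusted p-values are consumed as produced upstream;
no correction is recomputed, and rows with missing padj are excluded from
calling.  A log2FC of exactly 0 counts as neither up nor down (`n_zero`).
Set directionality uses **all** set members present in the table with no
significance filter — the published signature fractions are over whole
signatures, not over significant genes.

## Synthetic generators

All generators take an explicit integer seed (`numpy.random.default_rng`;
no global state) and are byte-deterministic per seed.

**AP-MS counts.**  Count means are per-condition sums over the replicate
injections — the scale on which per-antibody PSM numbers are reported; the
default bait-protein mean of 90 sits at the published bait PSM scale (97/80
per antibody) and the planted-interactor mean of 30 in the middle of the
partner range (5–56).  Replicates draw Poisson counts at mean/3.  Background
proteins model sticky bead contaminants: each draws one gamma-distributed
stickiness rate (shape 5, mean 0.5 per condition) applied to *every*
condition, so its counts are marginally negative-binomial (variance
m + m²/5) and reproducible across pull-downs, the way real contaminants are.
The dispersion default was fixed from a pilot of the Monte-Carlo recovery
experiment: heavier tails (shape 2) produce border-line contaminants that sit
exactly at the 5-PSM boundary and are indistinguishable from weak true
interactors — a real failure mode of the filter, but not the
strong-enrichment regime the recovery experiment is designed to probe.
Planted interactors draw Poisson counts at the bait mean in bait conditions
and at a 0.05 leak mean in controls.  In the default regime (200 background,
5 planted), perfect recovery (all planted called, zero false positives)
occurs in roughly 94–98 of 100 seeds; residual failures are single background
proteins fluctuating to exactly 5 PSMs in one bait condition.  The
"strong-background-suppression" null regime (no planted interactors,
background mean 0.2) yields empty call sets.

**Expression.**  The bait profile is standardized white noise over samples;
a planted gene's profile is `rho·z_bait + sqrt(1−rho²)·noise_sd·eps`.  At the
default `noise_sd=1` the realized correlation converges to the planted `rho`
(±0.05 at 500 samples); other values attenuate it.  Samples carry cycling
developmental-stage and brain-structure labels for shape compatibility only —
no developmental trend is modelled, so the generator validates the
correlation machinery, not any biology of co-expression.

**DE tables.**  Set members get fold changes with sign positive at the
planted probability and magnitude around the effect size; background genes
are centred.  Adjusted p-values are drawn as a mixture with a configured
significant fraction below 0.1; raw p-values are drawn below their padj for
plausibility and are not used by any consumer.

**Ontologies.**  Disease term sets intersect the bait set in exactly
`round(frac · n_bait_terms)` identifiers, carved from disjoint stretches
while terms remain (so modest fractions add exactly in the union), plus
private per-disease terms.

What passing the synthetic suite does **not** show: recovery under
compositional NSAF coupling at realistic proteome depth (thousands of
proteins), correlated antibody cross-reactivity, batch structure in
expression data, or p-value distributions of a real DE fit.  The generators
probe the decision logic, not instrument physics.

## Numbers not reproducible from packaged data

The published knockdown DEG counts (91 = 85 down + 6 up), the bait's own
knockdown log2FC (−0.87, padj 1.1e−5), the E2F-signature 91%-of-200 and
TGFβ 42/54 fractions, and the 80%-of-73 phenotype-term coverage all require
the deposited RNA-seq data or a live ontology snapshot.  The pipeline
implements the rules that produce such numbers and demonstrates them on
synthetic inputs of the same structure (e.g. a planted 0.91 up-probability
for a 200-gene signature is recovered within binomial error), but does not
claim the published values.

## Problem sizes and runtime

Defaults are sized so the full test suite runs in well under a minute and
the reproduction script in seconds: 100 seeds × 206 proteins for the
recovery experiment, 500 samples for correlation convergence, 1000-gene DE
tables.  All thresholds (control bound 5, test minimum 5, NSAF ratio 1.5,
correlation 0.58, pLI 0.9, DEG alphas 0.1/0.05) live in `PipelineConfig` and
are serialized into every report for provenance.
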