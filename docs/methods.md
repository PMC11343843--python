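# Methods

## Scope and model

signaflow derives a mechanistic, signed, directed network from differential
multi-omics data in three steps: protein-activity inference, sign-coherent
subnetwork optimization, and phenotype-activity inference. The underlying
assumptions are those of the activity-flow formalism: every causal prior
interaction is binary, directed and signed (+1 activation, −1 inhibition);
a protein's activity change is a ternary state (−1, 0, +1); and a state is
mechanistically *explained* when some selected incoming edge carries it from
an upstream nonzero state with the matching sign product.

## Prior-knowledge network assembly

Three tabular dialects are parsed into `CausalEdge` records:

* **Curated causal tables** — effect labels beginning "up-regulates",
  "down-regulates" or "form complex" map to +1/−1/+1; rows involving
  "protein family" entities are dropped (families cannot be resolved to one
  gene), as are rows with unrecognized effect labels (logged count).
* **Regulatory-phosphosite tables** — a kinase–site table inner-joined with
  a site regulatory-role table on (substrate gene, residue); role text is
  mapped to {+1, −1, 0} ("induced"/"stabilization" → +1,
  "inhibited"/"degradation" → −1, anything else 0) and only edges with a
  defined effect (±1) are kept. The role also classifies the site as
  affecting *activity*, *abundance* or *both*, which PhosphoScore uses.
* **Kinome-atlas percentile matrices** — kinase→site relations with
  percentile strictly above the *regulon threshold* (default 88) become
  regulon entries, weighted by a linear map of the percentile from
  [threshold, 100] onto [0.5, 0.9] (the mapping is declared linear; the
  weight band endpoints are clamped against floating-point spill).
  Relations strictly above the *PKN threshold* (default 99) inherit a sign
  from the regulatory-role table and enter the PKN. Threshold semantics are
  strictly-greater throughout.

Six presets apply cumulative filters (none → direct-only → no atlas →
proteins-only, with two mouse analogues carried by an organism flag —
gene symbols are treated case-sensitively with no cross-organism casing
conversion), so each stricter preset's edge set is a subset of the looser
one. Duplicate (source, target, residue) records with opposite signs are
resolved in favor of the manually-curated (non-atlas) source; a tie among
curated sources drops both records with a log entry — the sources give no
basis for preferring either sign. PKN preprocessing removes edges whose
protein endpoints were not quantified in the experiment; complexes,
metabolites, fusions and phenotype nodes are exempt because they are never
directly quantified.

## Step 1 — protein activities

**Footprint enrichment.** Signature statistics are rank-transformed
(average ranks, so exact antisymmetry under sign flips) to standard-normal
quantiles q = Φ⁻¹(rank/(N+1)), and each regulon scores
NES = Σ wᵢmᵢqᵢ/√(Σ wᵢ²) with a two-sided normal p-value. This is the
analytic rank-based formulation of footprint analysis, reduced to a single
two-sided statistic (the two-tailed/one-tailed combination of the original
enrichment method is deliberately not reproduced). Regulons with fewer than
`min_targets` (default 5) quantified targets are skipped.

**Hypergeometric weighting** (optional, default on): with N signature
analytes, K significant, n regulon targets present and k of them
significant, p = P[X ≥ k]; the weighted score is NES·(1−p). The functional
form of the damping is a package choice; it vanishes when the regulon's
significant targets are no more than chance and is near-neutral when they
are strongly over-represented.

**Proteomics correction** (optional, default on): a regulator whose
enrichment is non-significant (p ≥ 0.05) but whose protein is significantly
modulated in proteomics is added with activity = sign(proteomics statistic)
and method `proteomics_rescue`. On discordant significant signs the
enrichment record wins and a flag is set.

**Phospho normalization** (optional, default on): corrected site statistic
= phospho fold-change − parent-protein fold-change; sites without a
quantified parent pass through unchanged (flagged). z-scores use the mean
and sample standard deviation (ddof = 1) of the corrected distribution;
significant iff |z| > 1.96, strictly. A zero-variance corrected
distribution raises with guidance rather than emitting undefined scores.

**PhosphoScore**: per protein, the mean over significant regulatory sites
of (site statistic × regulatory sign); with `activity_only` (default on)
abundance-class sites are excluded. Only significant sites are used
(configurable) — sub-threshold sites say nothing reliable about direction.

**Combination**: union of footprint and PhosphoScore tables; on overlap the
footprint record wins and agreement is flagged. The *inferred sign* of a
regulator is the sign of its enrichment score; significance filtering
decides inclusion in downstream tables, and a filtered regulator counts as
an abstention, not a sign error, in recovery statistics.

## Step 2 — network construction and optimization

**Naive network.** Layer sets come from the activity table's molecular
functions: sources → KIN/PP → OTHER → TF for the three-layer layout; the
two-layer layout merges OTHER and TF into the final layer; the one-layer
layout bridges sources to all inferred proteins at once. For each boundary,
the union of *all* shortest paths of length ≤ `max_len` (default 4 per
boundary) from every upstream node to every downstream node is included —
taking every shortest path removes tie-break arbitrariness. Self-loops are
dropped before search. `connect_all` (default on) then adds every PKN edge
between nodes already in the network.

**ILP.** The objective minimizes Σ wₘ·|measuredₘ − stateₘ| + β·|E| over
ternary states and binary edge selections; the mismatch term is 0/1/2 for
matched/absent/opposite states. Defaults: β = 0.2, measured-node weights
w = |activity score| normalized to [0, 1]. Constraints: an edge may be
selected only if its source state is nonzero; a selected edge forces
state(v) = sign·state(u) (so coherence holds edge-by-edge, not merely
existentially); every nonzero non-source state needs a selected incoming
edge; acyclicity via integer ordering variables (selected u→v implies
order(v) ≥ order(u)+1). States are encoded as two binaries (up, down) with
up+down ≤ 1. The MILP is solved with the HiGHS backend of
`scipy.optimize.milp`; infeasibility or timeout raises a `SolverError`
carrying the solver status. The vanilla flavor fixes source signs (a node
both fixed and measured follows the source — the perturbation is ground
truth); the inverse flavor adds an artificial perturbation node joined to
every candidate receptor by one activating and one inhibiting edge, its
state unconstrained.

**Multi-shot.** Layer boundaries are split into `shots` contiguous groups
solved upstream-first. Each downstream shot fixes the upstream layers'
nodes as sources: the solved state where one was assigned, else the node's
measured sign. The fallback is what makes multi-shot more expansive than a
single global ILP — an inferred mid-layer protein whose upstream connection
was pruned still drives its own downstream layer — matching the observation
that three-shot models are larger than one-shot ones. At the union, state
conflicts resolve in favor of the more upstream shot (logged) and edges
rendered incoherent by a conflict are dropped.

**Phospho validation.** A post-translational edge is *quantified* when its
(target gene, residue) appears in the phosphoproteomics table and
*significant* when that site is significant; SignRatio = significant-backed
edges / all edges.

## Step 3 — phenotypes

The proximity scorer runs BFS on the parity expansion of the
phenotype-augmented graph (state = (node, sign product)), giving, per
(protein, phenotype, sign class), the shortest signed path length within
`max_len` (default 4). With preprocessing (default on), paths traversing
unquantified proteins are discarded (phenotypes and the query proteins are
exempt). The null distribution draws up to R (default 100) degree-matched
random sources without replacement — candidates with out-degree closest to
the query's, tolerance widened until ≥ 10 candidates — and uses their path
lengths to the same phenotype and sign class; z = (obs − stat(null))/sd
with stat ∈ {mean, median} (default mean), significant at z ≤ −1.96. At
least 3 null lengths with nonzero spread are required for a z to be
defined. This degree-matched random-source null is an explicit, documented
approximation of the original proximity method, whose internals are not
restated here.

PhenoScore: eligible regulators are model nodes with a significant path;
with `use_optimizer_states` (default on) every nonzero optimizer state
counts, else only Step-1-inferred proteins. `remove_cascades` (default on)
drops regulators reachable in the model from another eligible regulator of
the same phenotype, keeping independent regulators only (iterating in
sorted order for determinism). Activity = Σ wᵢ·pathsignᵢ·activityᵢ / Σ wᵢ
with wᵢ = number of significant paths (default) or 1; it lies in [−1, +1]
when activities are signs and flips exactly under global sign flips. Each
regulator→phenotype edge is drawn with the regulator's dominant path sign
(the sign class with the more significant z; tie → activating).

## Benchmarking and randomization

Gold-standard scoring: TP = inferred matching expected sign, FP = inferred
diverging, FN = in-gold inferable but not inferred; TN follows the
convention "opposite activity than expected and not inferred" — kept
literally for compatibility although it is internally inconsistent as a
definition; no downstream formula uses it. Not-inferable entities are
excluded from all counts. RMSE compares signed predictions clipped to ±1
against expected signs over inferred ∩ gold.

Combined scores (exactly as ranked):
score₂ = (precision·0.5 + recall·0.5 + SignRatio·0.5 + CC·0.5) −
(NormTime·0.2 + PowerLawFit); score₃ = (precision + recall) − (normRMSE +
normTime·0.5). PowerLawFit is the Kolmogorov–Smirnov distance between the
empirical degree distribution and a maximum-likelihood discrete power law
(α fitted by bounded 1-D likelihood maximization, xmin = 1) — the estimator
is a package choice, as only the metric's name is prescribed.

Rewiring applies double-edge swaps separately within the positive- and
negative-edge strata until at least the requested fraction of each
stratum's edges has moved, refusing any swap that would recreate an
existing (source, target) pair in either stratum (which would collapse as
a duplicate or sign conflict); every node's signed in/out degrees are
preserved exactly. Analyte shuffling permutes the statistic among
⌈fraction·n⌉ rows; regulon shuffling permutes target assignments across
regulators, preserving regulon sizes, modes and weights. All randomization
is driven by seeded generators.

## Synthetic data

The fixture generator emulates the statistical structure the pipeline
assumes: a planted regulator with activity a ∈ {−1, +1} shifts each target
by mode·a plus Gaussian noise (σ default 0.5, matching the recovery
conditions of 50 regulators × 10 targets), with significance at
|stat| > 1.96σ — the pipeline's own z-convention. The end-to-end toy world
builds a receptor → kinases → other proteins → TFs cascade whose edge signs
are chosen coherent with randomly drawn node states, so a recoverable
optimum exists; regulatory phosphosites are simulated at ~6× the protein
fold-change over a 150-row null background so they survive
phospho-over-proteomics normalization, and about half of the cascade's
phosphosites are strongly modulated so edge validation has both outcomes.
Role fractions in the generic toy PKN are apportioned by largest remainder
(floor each share, distribute leftovers by fractional remainder, earlier
roles first on ties).

What the synthetic data does *not* emulate: mass-spec intensity noise
structure, missing-value mechanisms, correlated regulons, shared targets
between regulators, off-pathway crosstalk, or realistic proteome scale.
Passing tests therefore demonstrate the correctness of the algorithms under
their own model assumptions, not performance on real biological data.

## Numerical choices and degenerate inputs

* Enrichment antisymmetry is exact (average ranks + symmetric quantiles),
  tested at 1e-12.
* The atlas weight map clamps to [0.5, 0.9] against floating-point spill.
* Hypergeometric p-values use the survival function at k−1; saturated
  tables (k = n = K = N) give p = 1 and a zero weighted score.
* Zero-variance corrected phospho distributions raise; zero-variance
  proximity nulls yield no z (pair omitted).
* A single-node graph reports diameter 0 and clustering 0; empty graphs
  are rejected by the topology scorer.
* Problem sizes: acceptance-style checks run 100 ILP instances of ≤ 6
  nodes / ≤ 8 edges against exhaustive enumeration, 300 rewired networks,
  and a toy world of ~18 proteins and ~230 phosphosites; these sizes keep
  every exhaustive oracle exact while exercising all code paths.

## Known limitations

* The ILP mismatch weights, β, and the multi-shot seeding rule are package
  choices where the source methods leave them open; they are exposed in the
  configuration.
* The proximity null is degree-matched on out-degree only; very small
  graphs widen the matching tolerance and the null becomes partly
  degree-agnostic.
* The inverse flavor leaves the artificial perturbation node's sign fully
  free; with few measured nodes this can make solutions non-unique (the
  solver's optimum is still globally optimal in objective value).
* Mouse support is an organism flag on PKN presets; no ortholog mapping is
  performed.
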