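# Methods

## Model and assumptions

`regutarget` treats metabolism and transcriptional regulation as two
separately parameterised modules joined by scores, not as one integrated
model. The metabolic side is a standard constraint-based model: steady
state Σ_n S_mn·v_n = 0 with flux bounds α_n ≤ v_n ≤ β_n (mmol·gDW⁻¹·h⁻¹)
and a growth requirement v_biomass ≥ f·v_biomass^max. The regulatory side
is a signed digraph with empirically estimated edge strengths. The
combination assumes (i) that the expression contrast between producer and
non-producer conditions reflects regulation relevant to the product
phenotype, (ii) that mRNA changes proxy enzyme-activity changes, and
(iii) that a regulator's effects compose linearly across its regulon and
down the hierarchy. None of these hold exactly in a cell; the method is a
ranking heuristic, not a yield predictor.

## Reaction slopes (nRAP)

The feasible range [v_min, v_max] of each gene-associated reaction is
computed by FVA **with the growth constraint already active**, so that
every subsequent sweep point v_r = v_min + k·(v_max − v_min), k ∈
{0, 0.1, …, 1}, is feasible by construction. At each of the 11 points the
product flux is maximised; nRAP_r is the ordinary-least-squares slope of
max v_target against k. OLS is used because the response is piecewise
linear in k and occasionally kinked: a two-point slope would be hostage to
the endpoints, while OLS agrees with it exactly on perfectly linear
responses. The fractional coordinate k (not absolute flux) keeps slopes
comparable between reactions of very different magnitude. Only
gene-associated reactions are swept; exchange and spontaneous reactions
cannot be targeted through a regulator.

Numerics: solver feasibility/optimality tolerances are left at the GLPK
defaults; FVA extremes are clipped into the reaction's bounds; a sweep
point that fails numerically is retried with its fixed bounds relaxed by
1e-6 (scaled) and the reaction is flagged `infeasible` and excluded from
gene scoring if it still fails. Slopes with |nRAP| < 1e-6 are snapped to 0
so that downstream sign semantics do not chase solver noise. A `loopless`
flag post-corrects each FVA optimum with the cycle-free method, so reported
extremes are attainable without thermodynamically infeasible internal
cycles; it is off by default because the correction is unnecessary for
loop-free models and costs one extra solve per optimum.

Reversible reactions are swept over their signed range as-is; no direction
splitting. Raising the growth fraction only tightens the polytope, so
ranges shrink monotonically (property-tested), and multiplying all bounds
by c > 0 scales every slope by c (the LP is homogeneous; also tested).

## Alternate routes

The sweep only scores reactions the optimum actually uses: an equivalent
parallel pathway scores 0 because fixing its flux never changes the
optimum. An optional extension (off by default, `alternate_rounds`) probes
for such routes: candidates — reactions with positive nRAP, strongest
first, excluding the target and biomass reactions — are knocked out **one
at a time**, and reactions still scored 0 are re-ranged and re-swept under
that single knockout; newly nonzero slopes are recorded with provenance
`alternate-route`, never overwriting a primary score. Knockouts are not
accumulated: an unproductive knockout (one that severs every route, e.g.
the shared uptake step) would otherwise mask alternates that the next
candidate reveals. This is an explicit heuristic; different knockout
policies can surface different alternates.

## Gene scores (nGAP) and subunit factors

GPR rules are parsed into n-ary boolean trees ("and" binds tighter than
"or"; associative chains flattened; keywords case-insensitive; any other
token is a gene id). Factors follow the subunit logic: the root carries 1,
OR (isozymes) passes the factor unchanged, AND with c children (a complex
of c parts) multiplies it by c; a gene reachable only inside a quarter of
a complex gets factor 4 and hence a quarter of the reaction's slope,
nGAP_jr = nRAP_r / GPRf_j. A gene occurring in several leaves keeps the
**minimum** of its leaf factors — its strongest single stoichiometric
contribution; a harmonic-sum combination would be defensible but
overweights genes that appear both alone and in complexes. Reactions
without GPR contribute no gene scores.

## Regulatory strengths (nRS) and the sign filter

nRS_ij = (ΔGene_j/ΔTR_i)·(TR_i,n-prod/Gene_j,n-prod): the ratio of the
gene's relative change to the regulator's relative change. The
normalisation stops lowly expressed TRs from accruing inflated strengths.
Replicate columns are averaged per condition before the ratio. Edges with
an effectively unchanged regulator (|ΔTR| < 1e-8·TR_n-prod), a nonpositive
baseline, or missing expression are excluded outright rather than clamped —
a pseudocount in a ratio of ratios invents regulation. Note the quantity is
invariant to rescaling an id's intensities in both conditions by one
factor (unit changes cancel), but **not** to rescaling a single condition;
inputs must be cross-condition normalised upstream.

The sign filter removes edges whose empirical nRS contradicts the curated
effect. It applies **per edge** by default: striking a whole regulator for
one inconsistent edge would discard valid regulon members. A
`per_tr_filter` flag restores the stricter whole-regulator behaviour. Dual
(`+-`) edges pass either way, since either sign is curated as plausible.

## TRE and the randomisation screen

TRE_i sums nRS_ij·nGAP_jr over the regulon. Because TRE is linear in the
vector of reaction slopes, the chance screen is a single matrix product:
each of n_draws (default 1000) draws samples every scored reaction's slope
uniformly from one global [min, max] of the observed slopes (each reaction
has a single observed value, so per-reaction ranges would be degenerate),
and q_i is the fraction of draws whose random TRE_i lands within
±window·|TRE_i| (window 0.10) of the actual value; significant ⇔ q_i <
alpha (0.05). TRs with |TRE| < 1e-9 are never significant — a ±10% window
around ~0 has measure ~0 and would otherwise auto-pass. Draws are consumed
as one uniform block in sorted-reaction-id order from a seeded generator,
so q values are bit-reproducible. The ±10% window is inherently arbitrary;
single-edge regulators whose observed slope sits at the range extreme have
q exactly at window/2 = 0.05 and will flap across the threshold — a known
boundary artefact of this screen, harmless to the extremes of the ranking.

## Hierarchy and gTRE

Self-loops and all edges internal to strongly connected components of size
> 1 are excluded before layering — only the edges, not the member TRs,
whose regulons stay in play. The rationale is structural: iterating the
propagation across a negative feedback loop cancels and across a positive
one diverges geometrically, so the recursion is only meaningful on the
acyclic remainder (finiteness is property-tested on random cyclic graphs).
Levels are assigned by longest path from the roots, the one layering under
which every retained edge points strictly downward so the bottom-up
recursion gTRE(i) = TRE(i) + Σ nRS_ic·gTRE(c) is well defined for every
edge. Regulators that fail the significance screen contribute 0 of their
own TRE but **remain conduits** for their children's gTRE; removing them
as nodes (available via `strict_significance`) would sever real regulatory
paths on the evidence of a noisy local score.

Ranking sorts by gTRE descending (positive → overexpress, negative →
downregulate, 0 → neutral), ties broken by |TRE| then id, so reruns are
deterministic.

## The toy instance

The generator plants a minimal instance with every behaviour the pipeline
must handle: product-favouring and competing reactions (slopes ±5 under
10 units of uptake and the 50% growth rule), a two-subunit complex, an
activator of the product path, an activator of the drain, a repressor, a
3-level cascade, a feedback loop and a self-loop. Expression values are
integers in [10, 1000] so every nRS is exact rational arithmetic checkable
by hand; seeds jitter magnitudes by a per-id integer factor, which leaves
every nRS — and hence the planted ranking — exactly invariant. What passing
recovery tests shows is therefore *correctness of the machinery*, not
robustness to realistic transcriptome noise, regulon overlap at scale, or
genome-scale degeneracy of FVA ranges; the toy has none of those features.

## Evaluation metrics

`classification_metrics` derives TPR, PPV, FNR, FDR, F1 and FP/FN from raw
TP/FP/FN counts (true negatives are undefined when validation rests on
published evidence), computing from unrounded intermediates and rounding
half-up at the end. For counts (TP=17, FP=2, FN=10) the precision is
17/19 = 0.895, consistent with the FDR row (0.105 = 1 − 0.895) and the F1
of 0.739; a published rendering of this table prints PPV 0.893, which is
internally inconsistent with its own FDR and F1, so this implementation
reports the computed 0.895 and documents the discrepancy here rather than
matching it.

## Problem sizes and defaults

Defaults: growth fraction 0.5, k step 0.1 (11 sweep points), 1000 draws,
window 0.10, alpha 0.05, alternate rounds 0, per-edge sign filter, conduit
semantics for non-significant TRs. The shipped tests run the full pipeline
on the 9-reaction / 7-regulator toy (12 FVA LPs + 66 sweep LPs per run,
~0.1 s), which is sufficient to pin every formula and invariant; the same
code paths run unchanged on genome-scale SBML models, where FVA dominates
the cost and the `loopless` flag becomes advisable.

## Known limitations

- No prediction of the *magnitude* of yield change — scores rank, they do
  not quantify.
- The expression contrast must match the desired phenotype; partial or
  mismatched datasets degrade targets silently.
- Hierarchy levels depend on the completeness of curated TR→TR edges;
  missing edges flatten the hierarchy toward plain TRE ranking.
- The alternate-route procedure is a knockout heuristic, not an exhaustive
  elementary-mode analysis.
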