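# Methods

This note documents the models and procedures implemented in `adam`, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Scope and assumptions

The pipeline treats metabolism as being at quasi-steady state at each
transcriptome sampling time: enzyme-level dynamics (seconds) are assumed
fast relative to transcriptional change (minutes), so each time point is
analysed as an independent steady-state problem, and temporal coupling
enters only through the data. Transcript levels are used as *indicators*
of reaction activity, not as flux values — post-transcriptional regulation
means expression does not quantitatively determine flux, which is why the
integration happens through an optimisation objective rather than through
hard on/off constraints.

Inputs are (1) a stoichiometric model with bounds, reversibility, a biomass
objective, exchange reactions and GPR rules (SBML L3/fbc via cobrapy, or a
three-file TSV dialect: reactions, metabolites, stoichiometry triplets);
(2) a long-format expression table (gene, condition, time_min, value) and a
differential table (gene, condition, time_min, p_value, direction). The
growth medium is a separate two-column config restricting exchange bounds;
exchanges follow the signed convention (negative flux = uptake), and
exchanges not listed in the medium have uptake closed while secretion stays
open.

## Gene and reaction weighting

Weight per gene/time/condition: `w = I*z + (xi - theta)/theta`.

* **z-score.** `z = Phi^-1(1 - p/2)`, the two-sided magnitude of the
  differential-expression p-value, capped at 8 to avoid quantile underflow
  (configurable). Two-sided is used because the indicator `I` already
  carries the direction; `z` is a direction-agnostic significance size.
* **Indicator.** `I = +1/-1` only when the table reports direction up/down
  *and* `p <= alpha` (default alpha = 0.05, configurable); otherwise 0.
  Missing differential rows mean `I = 0`, `z = 0`.
* **Threshold theta.** Per gene, pooled over all conditions and time points
  jointly. A 2-component univariate Gaussian mixture (EM, 5 restarts,
  fixed seed) is compared against a 1-component fit by BIC. If bimodality
  wins, theta is the point between the two component means where posterior
  responsibilities are equal (closed-form quadratic; midpoint fallback when
  the quadratic has no root between the means). Otherwise — and for
  degenerate input (< 4 values, zero variance, coincident means) — theta is
  the gene's median. The BIC criterion and the equal-responsibility
  boundary are this package's operationalisation of "bimodality analysis";
  both are recorded per gene in the weight table (`bimodal` flag).
* **Non-positive expression scales.** `theta > 0` is required by the
  normalised term. If a gene's pooled values contain non-positive numbers
  (log-ratio data), all of that gene's values are shifted so the minimum
  equals eps = 1e-3 before fitting, and xi is evaluated on the same shifted
  scale; the shift is stored in the table.

Mapping to reactions: GPR trees are evaluated with AND → min (a complex is
limited by its scarcest subunit) and OR → sum (isoenzyme capacities add).
Genes annotated in the model but absent from the data are imputed with the
median weight over measured genes; reactions with no GPR receive the median
weight over GPR-weighted reactions at the same time/condition. Provenance
(`gpr` / `gene-median` / `reaction-median`) is recorded per reaction so
coverage is auditable.

## Dispensability partition

Single-reaction deletions (both bounds set to zero; indices stable) with an
FBA re-solve classify a reaction as *dispensable* when the perturbed
biomass optimum stays ≥ threshold · f_max, default threshold 0.99 with
{0.99, 0.95, 0.90} exposed for robustness runs. Only the optimal values are
compared, so FBA degeneracy is irrelevant here. A tolerance of 1e-6 guards
the comparison against LP round-off. Lowering the threshold can only grow
the dispensable set (tested). Only dispensable reactions get Boolean
variables in the extraction MILP — indispensable reactions are always in
the network; this both reduces the integer dimension and encodes that the
backbone of biomass production is never up for removal.

## Bilevel extraction and its single-level form

Per time point/condition, on the irreversible split model (every reversible
reaction becomes forward/backward columns with negated stoichiometry; the
flux cone is preserved):

* outer: minimise the number of included dispensable reactions Σ y_j;
* inner: maximise Σ w_j v_j subject to S v = 0, biomass ≥ f_min,
  0 ≤ v_j ≤ u_j y_j on dispensable columns, 0 ≤ v_j ≤ u_j otherwise.

f_min defaults to 0.10 · f_max (growth under stress is observed at roughly
10–30% of the unstressed rate; the robustness grid {0.01, 0.10, 0.20} is a
config option). Because the floor is an inner constraint, outer feasibility
of an assignment y equals inner-LP feasibility; the expression data select
among count-ties through a **lexicographic second phase**: after the
minimal count k* is found, a second solve fixes Σ y = k* and maximises the
inner objective. Remaining degeneracy (distinct networks of equal count
*and* equal inner objective) is possible and is logged when detected.

The single-level form replaces the inner LP by strong duality. With duals
λ (steady state, free), μ ≥ 0 (biomass floor) and η ≥ 0 (upper bounds), the
MILP imposes inner primal feasibility, dual feasibility
`S^T λ − c μ + η ≥ w`, and the equality
`w·v = −f_min μ + Σ_N u_j η_j + Σ_D u_j (η_j y_j)`. The products η_j y_j are
linearised with auxiliaries g_j and big-M envelopes. Numerical choices:

* **Dual box / big-M.** Dual variables are boxed at
  `M = 1e4 · max(1, max|w|)` (logged, configurable). There is no a-priori
  finite bound on LP duals in general, so the box is validated empirically:
  the test suite and the acceptance script compare the MILP against an
  exhaustive oracle that enumerates every Boolean assignment and solves the
  inner LP directly — any truncation of the true duals would surface as a
  count or objective mismatch. A deliberately tiny box is also tested to
  confirm the failure mode is visible.
* **Bounds.** All upper bounds must be finite (big-M needs them); infinite
  bounds are an error unless a cap is supplied.
* **Split pairs share one Boolean** — a reaction is "in the network"
  regardless of direction, since the outer objective counts reactions.
  Simultaneous forward/backward flux (a futile two-cycle inflating the
  inner objective) is not excluded by constraint but detected post hoc and
  logged; it did not occur on any test fixture.
* **Verification.** Every returned solution is re-checked by direct
  substitution (steady state ≤ 1e-6, bounds, floor) and against a fresh
  inner-LP solve at the chosen y; violations raise instead of returning.
* Solvers: HiGHS via `scipy.optimize.linprog`/`milp`, MIP gap 0.

Results are reported on original reaction ids (net flux = forward −
backward).

## EFM enumeration

Elementary flux modes of the (minimal) networks are enumerated with the
canonical nullspace/double-description scheme on the irreversible form:
starting from the unit rays, each metabolite's balance is imposed in turn
(cheapest-first ordering), keeping in-hyperplane rays and combining
positive/negative pairs that pass the support-adjacency test; a final
support-minimality sweep guards against numerically retained rays.
Representatives are normalised to max coefficient 1; spurious two-cycles of
split pairs are dropped; supports are folded to original ids and
de-duplicated. Exchange and biomass pseudo-reactions are retained inside
the computation — they are part of the minimal networks, and open exchanges
are what make non-trivial modes possible. A configurable ray budget turns
combinatorial blow-up into an explicit error, never silent truncation.

EFM identity for all cross-network comparisons is the **support set over
original reaction ids**: coefficients are scale-ambiguous, supports are
not. The independent oracle enumerates all column subsets (increasing
cardinality, pruned by found supports and by a per-metabolite
sign-balance necessary condition) and accepts a subset iff an LP finds a
strictly positive balanced flux on exactly that subset.

## Profiles, transitions, clustering

* `X(i, j)` = fraction of EFMs at time j containing reaction i; rows are
  the union of network members, so a reaction absent from a time point's
  network has X = 0 there. The double-counting identity
  Σ_i X(i,j)·|EFMs_j| = Σ_modes |support| is asserted exactly.
* Flat = X > 0 at every time point; fluctuating = X = 0 at ≥ 1 time point.
* Transitions: Jaccard between consecutive (and optionally all pairs of)
  time points, separately for EFM-support sets and for the dispensable
  reactions retained in the minimal networks. Jaccard of two empty sets is
  1 by convention (logged where it fires).
* Correlation: Kendall τ_b (tie-corrected — appearance profiles are tie-
  rich). Zero-variance profiles give missing (NaN) correlations, never 0.
* Clustering: top-n reactions per time point (default n = 50, cutoff ties
  broken lexicographically, logged), union over time points; average-
  linkage hierarchical clustering on the 1 − τ distance (NaN τ → distance
  1), cut at k = 9 by default; k-means on raw profiles is a config
  alternative. k is capped at the number of selected reactions on small
  models. Deterministic at fixed seed.
* Robustness: re-extraction over the threshold × floor grid and under
  uniform noise of amplitude 1% of the total weight range applied to (up
  to) 100 randomly selected reactions; overlaps are reported as percentages
  of the smaller set.

## Synthetic benchmark

The generator produces the data *shape* the method consumes, not a
simulation of transcription or kinetics: a carbon uptake feeding a linear
core, a branch point with parallel two-reaction paths that reconverge
(configurable yields, so paths need not be equivalent), optional one-step
shortcut, dispensable secretion decorations, and one optionally reversible
reaction to exercise the split bookkeeping. The default schedule moves
activity from path 0 to path 1 at t = 30 min over seven time points
(0–90 min). Gene expression is drawn from N(8, sd) when the gene's reaction
is scheduled active and N(2, sd) otherwise (sd = 0.25 by default, so a
switched gene's pooled values are strongly bimodal); differential rows
compare each time point's state to the first time point, with p = 1e-4 and
the correct direction on changed states, p = 0.9/none otherwise. P-values
are generated directly because the pipeline's contract starts at the
differential table. Everything is a deterministic function of the scenario
seed (byte-identical bundles, tested).

Fixture sizes are deliberately oracle-compatible: ≤ 10 Booleans for the
exhaustive bilevel enumeration and ≤ 12 split columns for subset-LP EFM
enumeration. Problem sizes used by the default test-suite and acceptance
runs: 20 fixtures per oracle family, 50 mixture/unimodal samples of
n = 400, a 9-point parameter grid and 10 noise replicates for robustness.

**What passing shows — and does not.** Perfect flat/fluctuating recovery
and exact oracle agreement on these fixtures certify the *algorithms*:
formulation, dualisation, big-M validity, enumeration completeness,
bookkeeping across the reversible split. They do not certify behaviour on
genome-scale reconstructions, where weight imputation fractions are higher,
count-ties are pervasive (making the lexicographic tie-break load-bearing),
MILP solve times and EFM counts grow sharply, and expression bimodality is
far noisier than a two-Gaussian mixture. The robustness suite on the toy
model yields 100% overlaps because the optimum is unique and well
separated there; on real models overlap below 100% is the expected
outcome, and the suite exists to quantify it.

## Known limitations

* No compartment semantics beyond id suffixes; no gap-filling or curation.
* No genome-scale EFM enumeration (explicit ray budget instead) and no
  performance guarantees for MILPs with many hundreds of Booleans.
* The bimodality criterion (BIC + equal-responsibility boundary) is one
  reasonable operationalisation; alternatives (dip tests, kernel density
  antimodes) are not implemented.
* Alternate optima of the extraction MILP beyond the lexicographic
  tie-break are reported, not resolved.
* Differential-expression testing itself is upstream; the package consumes
  p-values and directions as given.
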