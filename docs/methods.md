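# Methods

## Model

Given a binary alteration matrix `A(g, p)` over genes g and samples p, a
continuous phenotype `w(p)` (z-scored; larger = more sensitive), and an
undirected gene network `G = (V, E)`, the method seeks a two-sided gene
module — an *increased-sensitivity* set S⁺ and a *decreased-sensitivity*
set S⁻ — maximizing

    W(S⁺, S⁻) = W₊(S⁺; w) + W₊(S⁻; −w),

where for a single side with weights v,

    W₊(S; v) = Σ_{p ∈ P(S)} v(p) − Σ_{p ∈ P(S)} pt(p) · (c(p,S) − 1),

`P(S)` is the set of samples altered in ≥ 1 gene of S and
`c(p,S) = |{g ∈ S : A(g,p) = 1}|`. The coverage term rewards modules whose
alterations concentrate in high-weight (sensitive) samples; because w is
centered, a random gene set has zero expected reward. The overlap term
charges each extra alteration in an already-covered sample, preferring
mutually exclusive alteration patterns — the hallmark of alterations that
are alternative routes to the same phenotype. The decreased side is scored
against −w: its alterations should concentrate in resistant samples.

Connectivity makes the module a functional unit: under the **combined**
model S⁺ ∪ S⁻ must induce one connected subgraph of G; under the
**separate** model each nonempty side must be connected on its own
(capturing, e.g., a resistance module in drug metabolism unrelated to the
sensitivity pathway).

### Penalty schemes

`pt(p)` is configurable:

- `abs_weight` (default): `pt(p) = λ·|v(p)|` with λ = 1. The penalty is
  commensurate with the reward and invariant under rescaling of the
  phenotype, so λ is a pure exclusivity-vs-coverage trade-off.
- `constant`: `pt(p) = λ`, for sensitivity analysis.
- `none`: plain weighted set cover.

A sample covered by both sides contributes to both sides' sums and is not
cross-penalized; the per-module `cross_side_overlap` diagnostic reports how
often this happens so users can judge whether the two sides are claiming
the same samples.

## ILP encoding

Per side, binary selection variables `x[g, s]` and coverage indicators
`y[p, s]` with `y ≤ Σ_{g: A(g,p)=1} x[g,s]` and `y ≥ x[g,s]` for each such
gene; the objective is linear because
`W₊ = Σ_p (v(p) + pt(p))·y[p] − pt(p)·c(p)` with `c(p)` linear in x. A gene
may sit on at most one side and `Σ x ≤ k` bounds the module size.

Connectivity is enforced by single-commodity flow per required component:
a root indicator `r[g] ≤ u[g]` (u the component's selection indicator),
`Σ r = t` with nonemptiness bit `t ≥ u[g]`, arc flows on both orientations
of each network edge with capacity `(k−1)·u[head]`, and node balance
`inflow − outflow ≥ u[g] − k·r[g]`. Every selected non-root gene must
absorb one flow unit that can only pass through selected genes, which is
feasible iff the selected set induces a connected subgraph containing the
root. The empty module (t = 0) is always feasible with W = 0, so reported
optima are ≥ 0 unless an exact size is forced.

The backend is HiGHS through `scipy.optimize.milp` (branch-and-cut, proven
optimality to a relative gap, default 1e-6; default time limit 600 s, well
below the day-scale cap practical for screening-scale runs). Solutions are
re-scored by the pure-Python objective and their connectivity re-checked by
graph traversal after every solve; a disagreement raises rather than
returning a silently wrong module. `SolverConfig.sides` restricts the
search to one direction, used in simulation studies where the planted
direction is known. An enumeration oracle (`brute_force_best`, guarded to
≤ 15 genes) provides an independent optimum for verification; solver and
oracle agree on 100% of randomized test instances across both connectivity
models and penalty on/off.

Tie-breaking among co-optimal modules is solver-dependent; tests compare
objective values, not gene identity, except against the deterministic
oracle (enumeration order: lexicographic gene subsets, increased side
before decreased).

## Candidate generation, significance, selection

One ILP per grid point (k = 1..k_max) × connectivity model × penalty
option; each point's exact optimum is a candidate. Significance is
assessed by permuting the phenotype values across samples (alterations and
network fixed), re-solving the same grid point, and computing the add-one
estimator p = (1 + #{null ≥ observed}) / (1 + n_perm), which is never zero.
The constraint system is reused across permutations (only the objective
vector changes). Default n_perm = 100 — each permutation is a full MIP
solve, so this is a desk-scale default; per-grid-point sub-seeds are
derived from the master seed with `numpy.random.SeedSequence`, making runs
bit-reproducible.

Final modules are the **maximal** significant candidates (p < α, default
0.05): a module whose side-labeled gene set is a strict subset of another
significant module's is redundant and dropped. Side labels are respected in
the containment check by default (a gene associated with increased
sensitivity is not "contained" in a module where it flags resistance); a
`respect_sides=False` toggle gives the looser set-level reading. Candidates
that hit the solver time limit are excluded from finals by default. No
multiple-testing correction is applied across the candidate grid (the grid
points are nested re-optimizations, not independent hypotheses); BH FDR
adjustment is provided for the independent-profile ANOVA validation, where
many modules are tested.

## Simulation model

`simulate_instance` generates: a gene network (Barabási–Albert with m = 2
by default — scale-free like protein-interaction networks; Erdős–Rényi and
user-supplied networks optional); a planted connected module grown by
random walk from a uniform seed node; alterations; and a phenotype.
A `coverage_target` fraction of samples (default 0.3) receives planted
alterations — round-robin across planted genes in `exclusive` mode, so
each covered sample carries exactly one planted alteration, or
independently in `overlapping` mode — and all remaining gene–sample pairs
are Bernoulli(`background_rate`, default 0.05). The phenotype is
N(±effect_size·noise_sd, noise_sd²) for covered samples (sign by the
covering side) and N(0, noise_sd²) otherwise, then z-scored. Defaults
(150 genes, 100 samples, effect 2 sd) give a strong but not trivial
signal: each planted gene covers ~10 samples whose weights average ~1 sd
above the mean.

What the simulator does *not* emulate: real per-gene mutation-rate
heterogeneity (hypermutators, length effects), co-amplification of
neighboring genes, interactome topology beyond the degree distribution,
and measurement error structure of real screens. Passing recovery tests
therefore demonstrate correctness of the optimization and calibration of
the significance machinery under the stated generative model, not
performance on real screening data.

Recovery is scored by F1 over gene sets (direction-agnostic by default;
a direction-aware variant compares side labels too), with
precision = recall = 0 for an empty result. In the strong-signal regime
the solver recovers planted modules of sizes 3–5 exactly (F1 = 1) in
≥ 90% of seeded replicates when searching at the planted size, and mean F1
degrades by < 0.1 when searching two genes larger — connectivity and the
centered weights make spurious extensions rarely profitable. Simulation
studies search the planted direction only (`sides=("increased",)`),
matching the one-direction planting; with both directions enabled the
z-centering artifact — uncovered samples are genuinely below average — lets
background genes pad the resistance side.

## Evaluation procedures

- **Target distance**: each module gene's distance is its minimum
  unweighted shortest-path length to any of the drug's targets
  (multi-source BFS); means per side and overall; unreachable genes are
  excluded from means and counted. Distances are hop counts on the
  thresholded network — edge confidence scores are used only for
  thresholding at load time. Per-drug means are reported (pooling across
  drugs is left to the caller, since both conventions are defensible).
- **Three-group ANOVA**: samples are grouped as altered in decreased-side
  genes only / increased only / unaltered; samples altered on both sides do
  not fit the design and are excluded by default (`both_sides_group=True`
  tests them as a fourth group). One-way fixed-effects ANOVA
  (`scipy.stats.f_oneway`, verified against the explicit sum-of-squares
  decomposition); groups below the minimum size (default 2) are dropped,
  and fewer than two usable groups yields a NaN sentinel.
- **BH adjustment**: statsmodels' step-up implementation behind a thin
  validator, verified against hand-worked lists.
- **Drug pairs**: two drugs are suggested as combination candidates when
  ≥ `min_shared` genes (default 1) appear in both drugs' merged final
  modules with opposite side labels — alterations that sensitize to one
  drug while conferring resistance to the other. An optional Jaccard
  threshold tightens the "similar modules" requirement.

## Numerical and degenerate-input choices

- Phenotype z-scoring uses the population denominator; zero variance or
  < 2 samples is a hard error. `negate=True` handles IC50-style inputs.
- Missing phenotype values are dropped (logged), never imputed; missing or
  non-binary alteration entries are load errors.
- Gene filters default to min_freq = 0.01 (configurable) and drop genes
  absent from the network, since connectivity is undefined for them.
- Objective/oracle comparisons use 1e-6 absolute tolerance, matching the
  solver's optimality gap; re-scoring after solve uses 1e-5 relative.
- Null-objective comparisons in the permutation test use a 1e-9 tolerance
  so solver jitter does not turn ties into anti-conservative p-values.

## Problem sizes

Tests and the reproduction script run at sizes a workstation solves in
minutes: oracle comparisons on 10-gene/15-sample instances (the
enumeration oracle is exponential), recovery on 150-gene/100-sample
instances (~0.1–5 s per MIP solve), calibration on 10-gene/25-sample null
instances (200 replicates × 101 solves). Screening-scale inputs (tens of
thousands of genes before filtering, hundreds of samples) are supported by
the same code path but need the frequency/network filters and a generous
time limit.

## Known limitations

- Systematically co-occurring alterations (e.g. co-amplified neighbors):
  set-cover objectives keep only one representative.
- Associations found are not necessarily causal.
- No heuristic fallback: instances too large for exact solving within the
  time limit return the incumbent flagged `feasible_time_limited`.
- The permutation test permutes the phenotype only; confounders correlated
  with both alterations and response (e.g. tissue of origin) are not
  controlled.
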