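# Methods

## Overview

`decrem` addresses a structural weakness of constraint-based metabolic
modeling: flux balance analysis (FBA) treats every reaction of a
genome-scale model (GSM) as an independent degree of freedom, although
reactions embedded in tightly interlocked cycles (TCA-like loops, coupled
reversible pairs) are co-activated and co-regulated in vivo.  The package
(1) detects these topologically coupled substructures, (2) replaces each
with a small set of merged *linear basis reactions* (LBRs) built from a
sparsest basis of the substructure's null space, producing a decoupled
stoichiometric matrix on which the usual FBA-family problems are solved,
and (3) fits a biomass-metabolite-driven, log-linear model of global
transcriptional regulation whose predicted key-reaction fluxes can be
imposed on the solve as kinetic box constraints.

## Topological coupling and clustering

The network is represented as a directed bipartite graph with a node per
metabolite and per reaction; arcs run substrate -> reaction -> product and
are mirrored for reversible reactions.  The coupling strength `a_ij` between
reactions i and j is the exhaustive count of simple directed cycles through
both reaction nodes.  Two conventions matter:

* **Length cap.**  Unbounded simple-cycle counting is #P-hard, so cycles
  are enumerated up to a cap of `max_cycle_len = 12` reaction nodes
  (24 bipartite nodes), configurable.  Counts are entrywise nondecreasing
  in the cap, so coupled-set membership can only grow with it.
* **Direction filtering.**  Reversibility is resolved into two direction
  nodes per reaction during enumeration; cycles that traverse the same
  reaction in both directions are discarded (they are artifacts of writing
  a reversible reaction as two arcs, not coordinated flux routes).  Fully
  reversible cycles count once per orientation.

Coupled reactions (`D_i = sum_j a_ij > 0`) are partitioned by minimizing
the generalized weighted cut

    WCut(C) = sum_k Cut(C_k, complement) / D_k,

where `Cut` sums `a_ij` across the cluster boundary and `D_k` is the
cluster's total cycle degree.  The minimizer is searched by a spectral
relaxation: eigen-embedding of the symmetric-normalized similarity matrix,
seeded k-means (default seed 17), greedy single-move refinement, and a
minimum cluster size of 2; the connected components of the coupling matrix
are scored as an additional candidate partition, which makes recovery of
genuinely disjoint cycle blocks exact (their WCut is 0).  K is selected
within a user-supplied range by the smallest WCut.

## Sparse linear basis extraction

For each cluster, the stoichiometric submatrix is augmented with an
artificial exchange column for every metabolite also touched by reactions
outside the cluster, so the submodel can carry steady state on its own.
The null space of the augmented matrix (dimension `r_k = l_k - rank`,
rank tolerance `1e-9 * sigma_max`) is re-expressed in a minimal-support
basis by at most `2 r_k` linear programs.  Each LP minimizes the L1 norm of
a steady-state vector under the original flux bounds, subject to a linear
independence constraint `|w . P . v| > zeta` (`zeta = 1e-3`, w uniform
random on [0,1], seed logged), where P projects onto the part of the null
space orthogonal to the columns already found; the two signs of the
disjunction are solved separately and the branch with the smaller element
support wins (ties to the positive branch).

Two deliberate numerical choices:

* **Sparsity is counted over element reactions only.**  The artificial
  exchange coordinates carry zero cost in the L1 objective.  A basis vector
  is "sparse" when it uses few real reactions; penalizing the helper
  exchanges biases the search toward internal loops and can discard
  through-path basis vectors, which demonstrably shrinks the feasible
  space of the decoupled model (a fed cycle with an uptake bound loses its
  optimum entirely).  With element-only cost the decoupled model preserves
  the toy solution spaces exactly.
* **Support and scaling.**  Each column is rescaled so its largest element
  coefficient is 1; entries below `1e-7` of that peak are treated as zero.

LBR bounds intersect the element reactions' own bounds mapped through the
basis coefficients: a coefficient `a` maps element bounds `[lo, hi]` to
`[lo/a, hi/a]`, swapped when `a < 0`; an empty intersection is an assembly
error naming the LBR.  An LBR is reversible iff its interval straddles 0.
Clusters with `r_k = 0` pass their reactions through unchanged.  Objective
weights are pushed through the basis so `c . v` is invariant under the
change of variables.

## Solves

All problems are LPs solved with HiGHS dual simplex (feasibility tolerance
`1e-9`).  Parsimonious variants pin the objective at its optimum (within
`1e-9` relative slack) and minimize total absolute flux through the
standard `t >= |v|` split.  FVA solves two LPs per column at a fraction of
the optimum.  Kinetic constraints are boxes `v_KF +/- delta` imposed in
element space; for a reaction merged into an LBR the box becomes a linear
row over its cluster's LBR columns via the basis coefficients (imposing the
box in basis space instead would constrain coordinates that have no
physical identity).  `delta` defaults to 5% of `|v_KF|`.  A reaction is
"activated" when `|v| > 1e-6`.

## Global regulation and linearized kinetics

Gene expression is modeled log-linearly in metabolite concentrations:
`log E_g ~ alpha_g * sum_j theta_j log M_bj + sum_i beta_gi log M_gi + b`,
where the first sum runs over biomass-constituent (BG) metabolites — whose
product form the growth rate, `R = lambda * prod_j (1 + M_bj/K_mj)^theta_j`,
using `log(1 + M/K) ~ log(M/K)` — and the second over local precursor (PG)
regulators.  Candidate regulators are split into the two groups by
average-linkage hierarchical clustering (correlation distance) of their
gene-correlation profiles; the group labeled BG is the one whose
concentrations correlate more with growth (or a user override when growth
is unmeasured).

The BG-to-expression link is fitted by PLSR (NIPALS via scikit-learn,
centering without variance scaling); the component count is chosen by
leave-one-out predictive R-squared unless fixed.  A gene is called globally
regulated when its observed-vs-fitted correlation exceeds 0.84 **and** its
correlation with the first X-score exceeds 0.38.  Selection is monotone in
both thresholds.  Significance is an empirical p-value: PLSR is refitted on
random same-size subsets of the candidate pool (default 10,000 draws) and
scored by the mean per-gene fitted correlation over the identified
regulated genes; p is the fraction of draws scoring at least the selected
set.  Restricting the score to the identified genes matters: over all genes
a mixed random subset can fit locally regulated genes that the BG set
deliberately ignores.

Reaction kinetics follow the reversible Michaelis-Menten law under the
Haldane relationship `k_eq = exp(-dG'0 / RT)` (RT = 2.4788 kJ/mol at
298.15 K).  Using the observation that substrate concentrations sit at or
above their K_m in central metabolism, the log rate is linearized as

    log v ~ alpha sum_j theta_j log M_bj + log(1 - ([P]/[S])/k_eq)
            + ([P]/[S])/k_eq + sum_u k_A^u/[A_u] + const,

and fitted by OLS of log-flux on the concentration-derived design columns
(BG log-concentrations, saturation term, mass-action ratio, reciprocal
activator concentrations, intercept).  Inhibitor reciprocal terms are
accepted but off by default, matching the retained linearization terms.
Strains at or past equilibrium (saturation argument <= 0) or with
nonpositive flux are excluded and reported.  Natural log throughout; zero
concentrations are floored at half the smallest positive value of the same
metabolite.  The train/test split is 80/20, stratified along the
growth-rate ordering, seed logged; when the training set is thinner than
twice the column count a tiny ridge penalty (1e-6) replaces plain OLS with
a warning.  Predictions are exponentiated back to flux units and flagged
when a design value falls beyond 10x its training range.

The rate-law denominator `1 + [S]/k_m^s + [P]/k_m^p` is not an explicit
design column; it is absorbed only insofar as the substrate is itself a BG
metabolite whose log-concentration appears in the design.  This is the
main approximation error: on data simulated from the full rate law with
`[S] >= K_m` it costs a few hundredths of correlation (held-out r ~ 0.98-1.0
at 5% multiplicative noise, n = 60).

## Synthetic data

`make_network` plants closed irreversible cycles (lengths >= 3) beside
uptake -> chain -> secretion routes, optionally bridged from cycle
metabolites into the chains (bridges never close new cycles, so the planted
clusters are exactly the coupled set).  Default toy bounds are [0, 10] for
irreversible and [-10, 10] for reversible reactions; models are feasible by
construction.

`make_omics` simulates a default 24-strain panel (mirroring a single-gene
knockout panel) with 45 candidate regulators (23 BG + 22 PG) and 85 genes
of which 32 are globally regulated.  BG log-concentrations share a
per-strain growth-state factor (coefficient 0.5) plus idiosyncratic noise
(sd 0.3) — knockout panels vary chiefly in global growth state, and biomass
precursor pools co-vary with it — while PG concentrations are independent
(sd 0.5).  Growth follows the multiplicative biomass law with theta drawn
from U(0.02, 0.08) and lambda scaled so the median growth is 0.7;
regulated genes follow the log-linear law with alpha from U(0.5, 1.5);
the remaining genes are driven by two random PG regulators each.  Fluxes
come from the full reversible rate law with `[S]/K_m` in [2, 8],
`k_eq` 5-20x the median mass-action ratio, and activators well above their
affinity, with 5% multiplicative log-normal noise by default.

What the generator does **not** emulate: measurement-platform artifacts
(normalization drift, missingness structure), correlated noise across
genes, genuine enzyme saturation regimes below K_m, and realistic
genome-scale topology.  Passing tests therefore demonstrate correctness of
the algorithms under the stated generative assumptions, not performance on
any particular organism's data.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic
instances: toy graphs up to 12 reaction nodes for exact cycle-count
checks, planted networks of 2-4 cycles for clustering/decoupling, 20
random chain models for the FBA-reduction limit, and 24-60-strain panels
for the regulation stages — sizes at which every stage has an independent
brute-force or generative oracle.  All randomness flows through explicit
integer seeds; reruns with the same seed are bit-identical for the
deterministic stages.

## Known limitations

* Published genome-scale coupled-reaction and LBR counts depend on the
  original clustering parameters and cycle-length policy, which are not
  fully specified; counts from this implementation on the same models are
  expected to approximate, not bit-match, them.
* The LBR bound construction constrains basis coordinates, which is
  conservative when basis supports overlap: some steady-state flux
  patterns of the original model may be unreachable in the decoupled one
  (the element-only sparsity cost minimizes but does not eliminate this).
* Exhaustive cycle enumeration above the length cap is intractable; very
  long coupled loops are invisible to the similarity metric.
* The kinetic design assumes single-compartment concentrations and treats
  multi-substrate reactions through concentration products.
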