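# Methods

This note documents the model, its assumptions, the tunable parameters,
the numerical choices, and what the synthetic validation does and does
not demonstrate.

## Reaction model

Species are proteins, RNAs or drugs.  A species carries a list of
domains with copy counts; each domain copy is an independent binding
*site* that can hold at most one bond.  A species-level cap
`max_partners` (default 10) additionally limits the number of
simultaneous bonds per molecule regardless of free sites; this is a
coarse stand-in for steric hindrance, which is not modelled explicitly.

Binding rules are derived from a PPI network filtered by domain
compatibility:

* for each PPI edge (a, b), one rule is emitted per ordered domain pair
  (d_a on a, d_b on b) whose unordered pair appears in the DDI table;
* if no compatible pair exists and the two proteins share at least one
  GO term, a fresh single-copy *fictitious* domain pair, private to that
  edge, is attached to both proteins and one fictitious rule is emitted
  (any supplied term id counts — the inputs are user-curated term sets,
  so the test is not restricted to one ontology branch);
* otherwise the edge is dropped and counted in the build report.

All rules share a uniform default k_on = 1 and k_off = 0.1 per time
unit; measured per-interaction rates are not generally available, so the
predictions rest on topology, abundance and locality rather than on
kinetic detail.  A per-rule k_on can be supplied through the weight
column of the DDI table.  Abundances are integers (copies per simulated
cell); inputs expressed in molecules/million are divided by a cell
volume factor (default 1000) before rounding.  An optional abundance
transformation (square root, or a multiplicative factor) reduces copy
numbers for tractability while preserving rank structure; any species
that started with at least one copy keeps at least one copy.

## Spatial simulation

Space is a grid of well-mixed subvolumes (SVs), 64×64 by default, each
holding at most `sv_capacity` molecules (default 150).  Subvolumes carry
compartment labels (single compartment by default; custom maps are text
grids of single-character labels), and a molecule is only ever placed in
or moved to an SV whose label belongs to its species' compartment set.

Each cycle of length `dt` (default 1 time unit) has two phases:

1. **Reaction.**  An exact Gillespie SSA (direct method) runs in every
   SV for `dt` time units.  Channels are complexation — one channel per
   binding rule and eligible molecule pair with a free matching site
   each and both below `max_partners`, propensity k_on — and
   decomplexation, one channel per existing bond with propensity k_off.
   Eligible pairs are co-located in the SV, or sit in 4-neighbour SVs
   belonging to two *different* compartments (so complexes can span a
   compartment interface, e.g. cytosolic and ER-anchored proteins).
   Channel ownership (pairs owned by the lower-indexed SV, bonds by the
   SV of the lower-uid endpoint) ensures no channel is counted twice.
   Propensities are recomputed after every event; subvolume populations
   are small, so the direct method with recomputation is cheaper than
   maintaining incremental structures.
2. **Diffusion.**  Each unbound molecule hops to a uniformly chosen
   4-neighbour SV with probability min(1, D·dt) — the expected flux
   between neighbouring SVs is then D·Δn, the discrete Fickian flux.
   A bound complex without cross-compartment bonds moves as a rigid unit
   at the slowest member's rate (so movement never tears complexes
   apart); a complex holding a cross-compartment bond stays anchored
   until the bond breaks.  Moves that would leave the grid, enter a
   forbidden compartment, or overfill the target SV are rejected, which
   conserves per-species molecule counts exactly.  Component move order
   is randomized each cycle to avoid directional bias from sequential
   updates.

There is no protein synthesis or degradation: the simulation predicts
the steady-state complexome of fixed copy numbers, not expression
dynamics.

Samples are taken at evenly spaced cycles in the second half of the run
(`burn_in_fraction` = 0.5): connected components of the bond graph with
at least two members become simulated complexes (SCs).  Replicate runs
use RNG streams derived deterministically from (seed, run index); a
pooled SC list is exactly reproducible from the seed.

## Refinement

* **Split.**  Markov Clustering runs on each SC's molecule-level bond
  graph (edge weight = number of bonds between the two molecules, plus
  unit self-loops): column-normalize, then alternate expansion (matrix
  power 2) and inflation (elementwise power, default 2.0) with pruning
  below 1e-5 until stable.  Clusters are read off attractor rows;
  singleton clusters are discarded, and an SC that stays in one cluster
  (or a non-converged MCL, which is only a theoretical concern) is
  returned unchanged.  This separates strongly connected subcomplexes
  linked by a few spurious bonds.
* **Merge.**  Distinct member sets are agglomerated greedily: the pair
  with the largest overlap score merges (union) while that maximum
  exceeds the similarity threshold ω_m = 0.5.  Greedy max-first
  agglomeration enforces the stopping rule — all final pairwise overlaps
  ≤ ω_m — directly; ties are broken by the lexicographically smallest
  member tuples, so the result is deterministic.  Overlap is computed on
  protein *sets*, not stoichiometric multisets, matching the set
  notation of the evaluation metrics.
* **Quantify.**  Every post-split SC is assigned to the refined complex
  it overlaps most (ties: larger RC, then smallest id; an SC overlapping
  nothing founds its own RC).  RC membership is frozen at merge time —
  assignment never grows it — so qualitative identity and quantification
  stay separable.  Abundance = number of assigned SCs; the sum of RC
  abundances always equals the number of post-split SCs.  Two RCs that
  both match one reference complex are kept apart as *alternative
  forms*; their abundances split the prediction between the forms.

## Evaluation

Overlap(p, r) = |p∩r|²/(|p|·|r|).  A reference complex is recalled when
some prediction exceeds the match threshold ω = 0.25 *strictly*.  Sn
weights each reference complex's best per-complex sensitivity by its
size; PPV weights each prediction's best column fraction by its column
sum, with predictions sharing no protein with any reference complex
contributing nothing (forced by the column-sum denominator); accuracy is
the geometric mean.  MMR is the total weight of a maximum-weight
bipartite matching between predictions and references divided by the
number of reference complexes, solved exactly as an assignment problem —
never greedily, which can be arbitrarily worse.  The composite score is
the sum recall + MMR + accuracy (consistent with published composite
values above 1); a fully degenerate contingency table defines
Sn = PPV = accuracy = 0 rather than raising, so the composite stays
composable.  A location-consistency filter removes complexes whose
members share no compartment; members without annotation are treated as
ubiquitous.

## Condition comparison and specificity

Refined complexes from two or more conditions are clustered by single
linkage on overlap > 0.5 (reusing the merge threshold).  Each cluster
gets a per-condition abundance vector (absent = 0) and its coefficient
of variation, population standard deviation over mean.  Because a
Poisson count of mean n fluctuates with relative error ≈ 1/√n, the cv of
clusters counted from a handful of SCs is dominated by sampling noise
(a mean of ~10 SCs already mimics a 2-fold change); clusters with mean
abundance below `min_mean_abundance` (default 25 SCs) are therefore
flagged `low_abundance` and ranked after the substantial clusters, in
the spirit of independent filtering in differential-abundance analysis.
All clusters remain in the output table with their cv.

Specificity of protein i for complex c is S_i^c = A_i^c / A_i, where
A_i^c counts copies of i over the SCs assigned to c (per-snapshot
averaged) and A_i is the species' simulated copy number — simulated
rather than raw input abundance, so the ratio stays self-consistent when
abundance scaling is active.  Bait ranking orders complex members by
specificity, then abundance, then (ascending) PPI degree.

## Synthetic scenarios

The generator plants `n_complexes` disjoint complexes (sizes uniform in
`size_range`, default 3–6) as PPI cliques.  Each within-complex edge is
realized by a dedicated single-copy domain pair in the DDI table, or —
for a configurable fraction of edges — by the complex's unique shared GO
term only, exercising the fictitious-domain rule.  Because every edge
uses its own single-copy domain pair, a molecule can hold at most one
bond per planted partner: fully assembled complexes have no free sites
and are inert, making the planted member sets the absorbing states of
the binding dynamics at low k_off.  Noise edges between complexes carry
neither DDI support nor shared terms and are dropped during model
generation.  Abundances cycle through `abundance_levels` (default
20/40/80 copies per member).  Two-condition pairs derive a perturbed
copy of a scenario (abundance scaling of one complex, or an added drug
species with fictitious bindings to named partners), recording the truth
for assertions.

The planted-recovery conditions use k_on = 10, k_off = 0.01, a 16×16
grid at capacity 150, dt = 1, and 3 replicate runs of 60 cycles with 2
samples each in the post-burn-in half — copy numbers and grid small
enough for the absorbing regime to be approached within the run while
the problem remains a genuine spatial many-body simulation (~2000
molecules).  What passing these tests shows: the engine reproduces exact
stochastic kinetics and unbiased diffusion, the refinement implements
its stated contracts, and the full pipeline recovers planted structure
and abundance ordering.  What they do not show: performance on real
proteomes, whose PPI networks have hubs, overlapping complexes,
abundance distributions spanning four orders of magnitude, and noisy
annotations — none of which the default generator emulates (an
`overlap_proteins` option adds shared subunits for stress testing, with
no accuracy claim attached).

## Numerical and degenerate-input choices

* SSA uses NumPy's PCG64 generator; exponential waiting times via
  `rng.exponential()`; one master seed, per-run streams spawned from
  (seed, run).
* MCL convergence: max 100 iterations, tolerance 1e-8 on the matrix
  change; prune threshold 1e-5.
* Empty SC lists refine to empty RC lists; an all-zero contingency
  table raises in `sensitivity_ppv_accuracy` but is mapped to zeros
  inside `composite_score`; empty reference sets always raise.
* Self-pairs in interaction tables are dropped with a warning;
  unordered duplicates are deduplicated; complexes with fewer than two
  members are dropped from reference catalogs.
* Capacity checks count molecules, not complexes.

## Known limitations

Steric inhibition is approximated only by the `max_partners` cap;
post-translational modifications and expression dynamics are out of
scope; kinetic parameters are uniform defaults unless supplied per
rule; the diffusion step is a plain cycle alternation (no event-driven
next-subvolume optimization), which bounds the practical problem size
in pure Python to ~10⁴ molecules per run.
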