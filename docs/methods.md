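# Methods

This note documents the models, algorithmic choices, default parameters and
known limitations of `nanoprune`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external sources.

## Dose–response reductions

**Logarithmic endpoint.** For each (material, day, endpoint) series the
response is fitted over the non-zero concentrations as
*y* = −*b* ln *c* + *b*₀ by (optionally weighted) least squares. Controls
(*c* = 0) are excluded — ln 0 is undefined and the controls describe the
unexposed baseline rather than the concentration trend. *b* has units of
response per ln(mg/kg) and summarises the steepness of the whole curve;
*b*₀ is the extrapolated response at *c* = 1 mg/kg. Weights 1/sd² are
applied only when every point carries a positive replicate sd, so
single-replicate studies get the plain normal-equations solution (the fit
is computed with centred normal equations, which are better conditioned
than the raw 2×2 solve). A flat series returns *b* = 0 with R² reported
as 0. The fit requires ≥ 3 distinct non-zero concentrations.

**Sigmoid models and ECx.** Two two-parameter models are provided, with the
control response *y*₀ fixed from the data:

* `logistic2`: *y*(*c*) = *y*₀ / (1 + exp(*s*·(ln *c* − ln EC50))) —
  EC50 is an explicit parameter;
* `threshold_sigmoid2`: flat at *y*₀ up to a no-effect threshold *t*, then
  2·*y*₀ / (1 + (*c*/*t*)^*s*) (continuous at *t*).

ECx comes analytically from the fitted parameters; for `logistic2`,
ECx = EC50·(x/(100−x))^(1/s), so ECx increases with x (EC10 < EC50) and
ecx(50) = EC50 identically. Fitting uses `scipy.optimize.least_squares`
with a deterministic multistart (8 log-spaced EC50 starts × 2 slope
starts); the threshold *t* is profiled over a 64-point log grid with ties
broken toward smaller *t*. A series whose response does not change with
concentration raises a no-effect error instead of reporting a spurious
EC50; a response that *increases* with concentration warns but returns the
fit. Confidence intervals are not computed by default; the CLI's bootstrap
option was considered and deferred (see Limitations).

## Descriptor clustering

Similarity between descriptors is |Spearman ρ| (mid-rank ties), so the
partition is invariant under any strictly monotone transform of any column,
and anticorrelated descriptors — equally redundant for regression — cluster
together. Distance 1 − |ρ|, average linkage. The tree is cut where the
inconsistency coefficient (depth 2) exceeds 0.8, **or** where a merge
reaches distance 0.8 (|ρ| ≤ 0.2). The second condition is essential: the
inconsistency statistic is scale-free, so a set of mutually independent
columns merging at uniformly high distances looks "consistent" and would
otherwise collapse into one cluster; the distance ceiling encodes the
judgment that columns correlated below |ρ| = 0.2 are not redundant. The
two criteria are combined as a subtree-maximum monocrit so the flat cut is
well defined. Constant columns are excluded (warned) and become
singletons. Cluster validity is reported as the cophenetic correlation
between tree and original distances; representatives are nominated by a
user priority list (defaulting to parameters commonly studied in the
toxicity literature: SSA, d_BET, diameter, zeta potential, hydrodynamic
size, force vector), falling back to the member with highest mean |ρ| to
its cluster mates, then lexicographic order.

## Symbolic regression

A tree-based genetic-programming engine searches for compact expressions.
Operator vocabularies: `rational_polynomial` = {+, −, ×, ÷} and
`rational_plus_translog` adding {log, sqrt, exp}. All operators are
guarded — division by |den| < 1e−9 returns 1, log/sqrt act on absolute
values, exp is clipped at ±50 — so any expression evaluates finitely on
finite inputs; residual overflow in products is penalised (score 0), not
propagated.

Model accuracy is always computed after **linear output scaling**
(pred = a + b·f(x), a and b from OLS): the search only has to discover the
functional shape. Three fitness metrics, all mapped to higher-is-better
scores in [0, 1]: R² of the scaled prediction; 1 − MAE/MAE of the
constant-mean baseline; and a hybrid index defined as the arithmetic mean
of the two (the combination rule was an open choice; the arithmetic mean
keeps both components on the same [0, 1] scale). Two vocabularies × three
metrics give the six canonical configurations used for pruning, each with
a distinct derived sub-seed.

Evolution: generational, tournament size 5 with a parsimony tie-break,
subtree crossover (p = 0.65), subtree mutation (0.15), point mutation
(0.10), constant jitter (0.05), single-individual elitism, ramped
half-and-half initialisation seeded with every bare variable, tree size
capped at 25 nodes. Complexity is the plain node count. A per-complexity
archive records the best expression ever seen at each size; the final
Pareto front is the non-dominated set of the archive, with constants of
front members polished by local least squares. Runs stop early when a
score of 1 − 1e−6 is reached or after 40 stagnant generations. The
default budget (population 500, 200 generations) recovers planted
low-complexity relations on tens of rows in seconds; it is configuration,
not contract.

Variable importance for pruning is **accuracy-weighted front occurrence**:
front-model accuracies (clipped at 0) are normalised to sum 1 and each
variable scores the total weight of the models containing it.

## Iterative pruning

Each round runs the six canonical configurations on the surviving
candidates against the per-material *b* values (day 49 by default),
averages the occurrence-weighted importances, and retains the top 40%
(ceiling, floored at 3 variables; importance ties at the cutoff keep all
tied candidates and trim from the lexicographically last). Candidate
columns are sorted internally so results are invariant to caller column
order. Termination: the literal stopping inequality mean/sd(survivor
importance) < 0.2, or the 3-variable floor. A point worth recording: the
mean/sd of k non-negative numbers is bounded below by 1/√k, so the ratio
rule can only fire for > 25 survivors — for typical representative counts
(≤ 20) termination is always by the floor, within 3 rounds from 20
candidates. Pruning uses a reduced GP budget (population 200, 40
generations, stall cutoff 15): six regressions × several rounds on
small-row tables converge well below the desk default.

## Sensitivity and directionality

The raw response (not *b*) is refitted per exposure day on the final
descriptor set — pruning survivors plus concentration, hydrodynamic size
and zeta potential. The merged front (low-accuracy tail below R² = 0.5
dropped) is then scanned: each descriptor is swept over a 21-point grid
from its observed minimum to maximum, once per (front model, data row),
other descriptors held at the row's values. A case is *positive* if the
rank correlation of model output with the grid exceeds +0.5, *negative*
below −0.5, else *none*; the three percentages sum to 100 and the ±0.5
cutoff is the package's operationalisation of "monotone in practice"
(results are stable within 2 percentage points between 21- and 41-point
grids, asserted in tests). Sensitivity is the mean swept output range over
the model's output sd, rescaled per day so the most influential descriptor
scores 1. Day 21 and day 49 run through identical code on different
response columns.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the geometry of a doped metal-oxide library study:
8 materials (CuO plus Fe-doped CuO, doping spread over 0–10%) × 5 soil
concentrations (100–3200 mg/kg), 68 descriptor columns of which 65 are
concentration-independent and organised into 15 clusters, and 3
(concentration, hydrodynamic size, zeta potential) vary with dose.
Reproduction counts follow *y* = −*b* ln *c* + *b*₀ with Gaussian noise
(default sd = 5% of the material's control scale *b*₀), rounded and
floored at 0; the planted *b* is globally rescaled so every noiseless
response stays positive over the tested range (keeping the count floor
from kinking the planted law). Controls are drawn to satisfy the OECD
validity criteria (mortality < 20%, > 50 juveniles per replicate,
CV < 50%, all strict).

Cluster structure is planted **in rank space**: each cluster has a latent
permutation of the materials, chosen greedily to minimise pairwise rank
correlation between clusters, and each member column applies a fixed
number of disjoint adjacent rank-value transpositions plus a random
strictly monotone (possibly decreasing) value map. Because every member
carries the same number of disjoint transpositions at distinct positions,
all within-cluster pairwise Spearman correlations are **equal**, which
keeps within-cluster dendrogram heights uniform — the regime in which
inconsistency-based cutting is reliable. `within_cluster_abs_rho` is a
floor: the planted correlation never drops below it.

Two geometric facts shape the defaults and the benchmarks:

* With *m* materials there are only *m* − 1 independent rank dimensions,
  so 15 mutually |ρ| ≤ 0.2 latents over 8 materials do not exist (a
  coherence bound); the material-structured generator gets between-cluster
  |ρ| down to ≈ 0.45, which still separates cleanly from the planted
  within-cluster level (≥ 0.95 at 8 materials). The 40-exchangeable-row
  block generator (`generate_block_matrix`) honours the ≤ 0.2 ceiling and
  is the benchmark object for clustering and pruning recovery.
* With counts-level noise, the uncertainty of the fitted *b* scales with
  *b*₀ while the admissible range of *b* is itself bounded by
  *b*₀/ln *c*max — so the signal-to-noise of the *b* endpoint is capped
  (≈ 2.5 per sd of planted spread at 5% count noise) regardless of scale.
  Descriptor-recovery benchmarks therefore add noise to *b* directly
  (`planted_b_table`, 5% of the planted spread); the counts path remains
  for end-to-end runs, with the understanding that small libraries sit
  near the identifiability limit.

What the generator does **not** emulate: soil chemistry, dissolution or
particokinetics, dose-dependent replicate variance, correlations between
the concentration-dependent parameters and the planted toxicity mechanism,
or reference materials (ionic controls enter dose–response fitting but not
the descriptor matrix). Passing recovery tests therefore demonstrates that
the pipeline's inferences are correct when its structural assumptions
hold, not that real studies contain recoverable signal.

## Numerical choices and degenerate inputs

Ties in rank correlations use mid-ranks. Constant descriptor columns:
correlation 0 (warned) in the correlation matrix, excluded from
clustering, error in normalisation. Constant regression targets collapse
to the constant model (R² reported 0 with a warning in the final fit).
Degenerate sweep ranges report 100% "no response" and zero sensitivity.
The Kneedle core/shell split normalises both axes to [0, 1] and takes the
point of maximum deviation from the chord; numerically straight profiles
(max deviation < 1e−6) raise "no curvature". Coordination numbers count
counter-ion (metal↔oxygen) neighbours only, within 1.2 × the sum of the
pair's ionic radii — in a rock-salt arrangement at spacing r_M + r_O an
interior atom scores 6, the like-ion shell at √2 spacing being excluded
by construction.

## Limitations

* ECx confidence intervals are not implemented; a bootstrap over
  replicates is the natural extension.
* The GP engine is deliberately compact: no multi-objective NSGA-style
  selection, no co-evolved constants beyond local refinement, single
  thread. It is adequate for the ≤ 68-descriptor, ≤ 40-row regime the
  pipeline targets.
* The pruning ratio rule is kept literal (see above) and in practice the
  3-variable floor terminates; both the ratio and the per-round
  importances are recorded in the trace so the decision is auditable.
* Sensitivity percentages depend mildly on the ±0.5 monotonicity cutoff;
  the reported stability bound (±2 points under grid refinement) does not
  cover cutoff variation.
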