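# Methods

This note records the model, the algorithms, the tunable parameters with
their defaults and rationale, the numerical choices, and what the
synthetic-data studies do and do not demonstrate.

## Model and assumptions

Data are n iid observations of (Y, X) from the linear Gaussian structural
equation model Y = Uᵀ Y + Wᵀ X + ε with ε ~ N(0, Diag(σ₁²,…,σ_p²)),
independent of X. The support of U is a DAG; edges from primary to
intervention variables are excluded by construction. X may be dependent
(the default simulated covariance is AR(0.5)) and may be discrete in
principle; only second moments of X enter the estimators.

Identification rests on interventions. An intervention variable is an
*instrument* if it targets exactly one primary variable; interventions
with several targets (invalid instruments) or none (inactive) are allowed
and need not be labelled in advance — targets are unknown throughout.
The reconstruction theory needs three conditions, which the simulator can
satisfy or deliberately break:

* non-degenerate second moments of X;
* no exact cancellation of interventional effects through unmediated
  parents (with the simulator's 0/1 weights, path contributions are
  positive sums and cancellation cannot occur);
* every primary variable carries at least one instrument
  (`classify_interventions` reports this flag; Setup B violates it).

## Reduced form and the ℓ0/DC solver

V = W (I − U)⁻¹ collects the regression coefficients of Y on X alone.
Each column is estimated under a hard sparsity bound κ_j by a
difference-of-convex iteration on the truncated-L1 surrogate
min(|z|/τ, 1): each step solves a weighted Lasso in which coordinates of
the previous iterate above τ are unpenalized, starting from zero (so the
first step is a plain Lasso), until the sup-norm change is below `tol`.
The converged iterate is projected onto the ℓ0 ball (keep the κ largest
magnitudes, ties to the lower index) and the support is refit by OLS; the
refit RSS is what selection criteria and the likelihood machinery use.
The coordinate descent runs on the Gram system in a numba kernel; the
Gram matrix is shared across columns, sparsity levels and γ values.

Parameters (per column j):

* **τ_j** (threshold separating signal from noise): default
  `sd(Y_j) · sqrt((log q + log n)/n)`, the rate at which true reduced-form
  coefficients must separate from noise for support recovery;
  `tau_scale` rescales it.
* **γ grid** (internal DC penalty): 10 log-spaced values descending from
  γ_max = ‖Xᵀy‖∞/(n τ) (the smallest value whose first Lasso step is all
  zero) to 0.01 γ_max, solved with warm starts. For each γ the
  projected/refit candidate is scored and the best γ wins; ties go to the
  larger (sparser) γ.
* **κ_j** (sparsity bound): user-set, or chosen by walking κ = 1, 2, …
  upward and stopping once the selection score has not improved for 3
  consecutive values.
* **Selection score**: `n log(RSS/n) + df · (log n + 2 log q)` — an
  extended-BIC penalty. Plain BIC (penalty log n per coefficient) is
  available (`extended_bic=False`) but systematically overselects here:
  with q candidate interventions the best spurious coordinate improves
  the fit by roughly 2 log q, which exceeds log n at the benchmark sizes
  (q = 40–100, n = 500), and each spurious entry of V̂ corrupts leaf
  identification downstream. The extended penalty is the standard remedy
  for support recovery when the candidate count is comparable to n.
* **tol** = 1e-8; **max DC iterations** = 1 + ⌈log q / log 4⌉. The
  returned iteration count is the number of solves that moved the iterate
  at the selected γ; the final convergence-confirming solve is not
  counted. The finite-termination bound 1 + ⌈log κ° / log 4⌉ holds for γ
  in a proper interior range, so the bound is checked on a DC run at the
  geometric mid-grid γ from a zero start; the γ selected by the extended
  BIC can sit at the large edge of its tie range and spend one extra
  release round without affecting the solution.

No automatic standardization is performed — the method is insensitive to
variable scaling, which matters because directed effects should not
depend on units; an opt-in flag standardizes and back-transforms.

## Peeling

A node is a leaf exactly when some row of V has its sole nonzero at that
column; such rows are the leaf's instruments. The algorithm repeatedly
collects all current leaves (processed in ascending index for
determinism — leaf identification is order-free), adds an edge from leaf
k to a previously peeled column j whenever **every** instrument row of k
is nonzero at j, removes the leaves, and recurses. The ancestral edge set
is the transitive closure of the collected edges (edges from unmediated
parents suffice to determine all ancestral relations); the candidate
intervention set attaches X_l to Y_j whenever V̂ loads X_l on Y_j or any
estimated ancestor of Y_j. The output is acyclic by construction (edges
always point from later-peeled to earlier-peeled variables) and closed by
the final closure, so it is a valid ancestral relation graph for any
input matrix. "Nonzero" means exactly nonzero after projection and refit;
no extra magnitude threshold is applied.

If no single-nonzero row exists, some variable lacks an instrument
(observational data, W = 0, always ends here) and `NoLeafFoundError` is
raised. A greedy fallback — take the row whose second-largest magnitude
is smallest and treat its smaller entries as zero — is opt-in and always
logged, because silently proceeding would mask an instrumentation
failure, which demonstrably degrades both learning and power.

V̂ is computed once from the full sample; sub-graphs reuse its restricted
columns (the leaf characterization holds for the full-sample V restricted
to the active set).

Given the ARG, coefficients (U, W) are re-estimated per node by the same
DC machinery: Y_j on its estimated ancestors (hard bound κ′_j on the
ancestor coefficients only) and its candidate interventions
(unpenalized). κ′_j defaults to a per-node plain-BIC choice over
{1,…,5} — plain BIC is appropriate here because the candidate pool is the
small estimated ancestor set, not all q interventions. Entries outside
the ARG are exactly zero.

## Likelihood-ratio inference with data perturbation

Hypotheses are edge sets ℋ among primary variables; the edge test's null
is that all hypothesized coefficients vanish, the pathway test's null is
that at least one does. Against the estimated ancestral edges, an edge
(k, j) is *nondegenerate* if adding it creates no cycle; the hypothesis
is *regular* if all nondegenerate edges can be added jointly. Degenerate
hypotheses get p-value exactly 1. Irregular edge hypotheses are
decomposed into single edges, tested separately, and combined by
Holm–Bonferroni (the adjusted minimum is the decision p-value); irregular
pathway hypotheses get p-value 1, since the hypothesized path cannot
coexist with the learned ancestral relations.

For a regular hypothesis, the testing graph adds the nondegenerate edges
to the ARG. Each node's regressors are its testing-graph parents among Y
plus its candidate interventions; σ̂_j² is the residual mean square of
that regression (RSS divided by n minus the regressor count). The
statistic sums, over nodes with hypothesized parents, the RSS drop from
adding those parents divided by 2 σ̂_j². Two algebraically identical
routes are implemented — the RSS-difference form from refits and the
projection form from nested QR decompositions — and their agreement to
1e-8 relative is asserted in the tests. Projections use pivoted QR with
rank truncation, never explicit n×n matrices; exact collinearity is
handled by projecting onto the column space, with a logged warning.
A perfect fit (σ̂ = 0) or a saturated node raises an error rather than
dividing by zero.

The DP null approximation draws e* with rows N(0, Σ̂), sets Y* = Y + e*,
re-runs the reduced-form fit (same κ, τ and γ grid, warm-started from the
unperturbed per-γ iterates; re-tuning is deliberately not repeated, since
the perturbation is meant to probe the selection, not the tuning) and the
peeling, and recomputes the statistic with e* in place of the response.
The hypothesized-parent sets are held fixed at the unperturbed estimate;
only the regressor sets move. A replicate is *valid* for the edge test
when its re-learned ARG contains the reference ARG (both edge sets), and
for the pathway test when the re-learned testing graph contains the
reference testing graph — the two conditions differ deliberately,
mirroring the respective p-value definitions. The p-value is the fraction
of valid replicates whose perturbation statistic reaches the observed
one; zero valid replicates is reported as an error, never as 0 or 1.
Replicate m's noise stream is keyed by (seed, m), so results do not
depend on the total replicate count, and Σ̂ is held at the unperturbed
estimate across replicates.

**M** defaults to 1000 (Monte-Carlo standard error ≈ 0.007 at the 0.05
level); the desk-scale studies use M = 200. Asymptotic reference
p-values (χ² with |D| degrees of freedom, or the normal approximation
when |D| > 50) and an oracle variant that accepts the true graph are
provided for comparison; both are computed from the same statistic.

## Synthetic data

The generator reproduces the standard benchmark designs: random DAGs
(upper off-diagonal entries Bernoulli(1/p), weight 1, with an optional
weight scale for weak-signal alternatives), hub graphs (nodes 1 and 2
with dense out-neighborhoods), intervention layouts A (instrument per
node + invalid + inactive), B (only the last node instrumented) and C
(identity atop zeros), error variances equally spaced from 0.5 to 1
(0.5 when p = 1, a documented convention), and X ~ N(0, AR(0.5)). Y is
solved exactly along a topological order (triangular back-substitution,
no matrix inversion). A single seed drives independent substreams for X,
ε and the DP perturbations, so runs are bit-reproducible and adding
consumers never shifts earlier draws.

What passing tests on these data do **not** show: robustness to
non-Gaussian errors, hidden confounding, cyclic feedback, or weak/dense
instruments — none of which the generator emulates, and the first two of
which the model excludes by assumption. Real genotype matrices are also
discrete and linkage-structured; only their covariance enters here.

## Study scales and known limitations

The packaged studies run on one CPU in minutes: 500 noiseless peeling
instances (p ≤ 8), 200 solver-vs-best-subset instances (q = 8), 2000
null-calibration replicates (chain graph, n = 200), 200 type-I
replicates with M = 200 (p = 10, q = 40, n = 500), 40 power replicates
per signal with M = 100, 100 BIC-selection replicates (p = 30, q = 100),
and a recovery sweep over n ∈ {250, 500, 1000, 2000} with the
reduced-form step at the oracle per-column sparsity (the regime of the
consistency theory; the coefficient step still selects κ′ by BIC). These
sizes were chosen as the package's own desk-scale defaults; larger
replicate counts only tighten the Monte-Carlo error.

The per-node modal BIC choice of κ′ under the p = 30 random-graph design
concentrates at 1, not 2: most nodes of a Bernoulli(1/p) random graph
have in-degree 0 or 1, and a per-node criterion tracks the in-degree of
the node it tunes. A selection summary concentrated at 2 would require a
criterion tied to a graph-level quantity (e.g. the maximum in-degree);
the per-node definition implemented here is reported as measured.

Other known limitations: the DP validity filter can starve (few valid
replicates) when the learner is unstable at small n or without full
instrumentation; irregular edge hypotheses use Holm–Bonferroni rather
than an exact joint null; and p-values are valid only insofar as the
local graph structures around the hypothesized edges are recoverable —
at small n this is an asymptotic promise, empirically checked by the
type-I study, not a finite-sample guarantee.
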