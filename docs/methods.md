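# Methods

This note documents the models and procedures implemented in `graphmcs`,
the choices made where the design was open, and what the synthetic
generator does and does not establish.

## Graphs and costs

All computation operates on simple undirected graphs with labels on nodes
and edges (symbolic tokens or numeric vectors). Node identifiers are
normalized to dense 0-based integers in file order; this ordering is the
tie-break order everywhere (centrality ranking, assignment solving, KNN),
which makes every stage deterministic across runs and platforms.

Edit operations are priced by a `CostModel`: insertion/deletion of a node
or edge costs τ_node / τ_edge (default 1.0 each — only relative magnitudes
matter for KNN ranking), and substitution of labels costs 0 on identical
labels, 2τ on mismatched symbolic labels (so a substitution never trivially
exceeds delete-plus-insert), and the Euclidean distance for numeric
vectors. A single weight α ∈ (0, 1) multiplies node-operation costs by α
and edge-operation costs by (1 − α); it is the main data-dependent
hyperparameter, selected by cross-validation (below).

## Centrality and reduction

**PageRank** is the unnormalized fixed point x = αAD⁻¹x + β·1 with damping
α = 0.85, additive constant β = 1 and D_ii = max(degree, 1) (undirected
degree stands in for the out-degree of the general formulation). It is
solved by fixed-point iteration from the all-ones vector; α < 1 makes the
map a contraction, and iteration stops when the infinity-norm residual of
the returned vector is ≤ 1e−9 (cap 10 000 iterations). An isolated node
scores exactly 1.

**Betweenness** is implemented as a binary membership count: node v scores
the number of unordered pairs {s, t} (endpoints excluded, t reachable from
s) with d(s,v) + d(v,t) = d(s,t) over unweighted hop distances — i.e. v
lies on at least one shortest s–t path. This is deliberately *not* the
fractional Brandes centrality (which divides by the number of shortest
paths); the Brandes variant is available via `variant="brandes"` but is not
the default. Counting ordered instead of unordered pairs would double every
score and change no ranking, so the choice is inconsequential for
reduction.

**Reduction** keeps the ⌊λ|V|⌋ highest-scoring nodes (ties broken by
ascending node index) and the edges among them. Scores are computed once on
the original graph and reused for every λ, never recomputed on
already-reduced graphs; this is what makes the retained node sets nested
(V_0.2 ⊆ V_0.4 ⊆ … ⊆ V_1.0) and is asserted as an invariant. Reduced graphs
may be disconnected or contain isolated nodes; that is legal and expected.
The λ = 1.0 level is the original graph space and is shared between
measures when both are requested, so the PR+BW plan has 9 levels, not 10.

## BP graph edit distance

The BP cost matrix is the standard (|V₁|+|V₂|)-square quadrant layout:

* substitution (i, j): α·node_sub(μ₁(uᵢ), μ₂(vⱼ)) + (1−α)·C_edge(uᵢ, vⱼ),
  where C_edge is the optimal assignment cost between the incident-edge
  label multisets of the two nodes (its own small assignment problem;
  short-circuited to |d₁ − d₂|·τ_edge when all incident labels coincide);
* deletion diagonal (i, i): α·τ_node + (1−α)·deg(uᵢ)·τ_edge; insertion
  quadrant symmetric;
* off-diagonal deletion/insertion cells carry a finite big-M equal to the
  total finite cost sum + 1, so `scipy.optimize.linear_sum_assignment`
  applies unchanged and those cells are never selected;
* the bottom-right quadrant is zero.

The solver's optimal assignment is then *re-costed* as the edit path it
induces: an edge of G₁ maps to an edge of G₂ iff both endpoint images are
adjacent in G₂, otherwise it is deleted; G₂ edges without preimage are
inserted. The induced cost — not the assignment objective — is the reported
distance, and it upper-bounds exact GED by construction. Distances are
homogeneous of degree 1 in (τ_node, τ_edge).

Symmetry: BP's tie-broken assignment can make d(G₁,G₂) ≠ d(G₂,G₁), so each
unordered pair is computed once with the operands sorted by graph id and
the value fills both cells of the distance matrix.

The **exact oracle** is a depth-first branch-and-bound over all injective
partial node mappings with deletions, pruned against the running best
(initialized from the always-feasible delete-everything/insert-everything
path, so the oracle stays independent of BP). It is guarded to
|V₁| + |V₂| ≤ 12 and exists for verification, not production; the test
suite additionally cross-checks it against `networkx.graph_edit_distance`
with α-weighted cost callbacks on tiny labeled pairs.

## Combination and optimization

The KNN operates directly on precomputed distance blocks (rows =
evaluation, columns = training). Ties are fully specified: equal distances
resolve by training-set order (stable argsort), vote ties by the smallest
summed distance among tied classes, then by sorted class order.

CoD sums the per-level matrices entrywise with simplex weights; CoP has
each subspace cast its weight for its predicted class (one-hot weighted
majority voting — arithmetic on class codes would be meaningless for
symbolic classes). Weights live on the *closed* simplex [0, 1]ⁿ: the
11-value grid itself contains 0.0 and 1.0, and corner vectors are exactly
the single-subspace baselines, which the tests require to be recovered
bit-for-bit.

**Grid search** enumerates the Cartesian grid (default {1.0, 0.9, …, 0.0}
per weight, 11⁵ = 161 051 raw points for five subspaces), drops the
all-zero point, normalizes each point onto the simplex and deduplicates
(152 041 unique directions remain); first-encountered wins ties. Raw grid
points mostly violate the sum-to-one constraint, so normalization is
applied; since KNN ranking is scale-invariant this changes no CoD decision,
only the reported weights.

**Genetic algorithm**: population 30 random simplex points, 100
generations, per-gene mutation probability 0.1. Unspecified operator
details were fixed as: tournament selection of size 2; single-point
crossover at a uniform random site with renormalization of both children;
mutation multiplies a gene by exp(N(0, 0.5²)), clips to [1e−6, 1] and
renormalizes (keeping chromosomes on the simplex); elitism of 1, which
makes the best-fitness history provably non-decreasing. All randomness
flows from one seeded `numpy` generator.

**Hyperparameter validation**: (α, k) are selected by stratified fivefold
cross-validation of the plain KNN on the *original* training graphs, over
α ∈ {0.1, 0.3, 0.5, 0.7, 0.9} and k ∈ {1, 3, 5}; ties prefer smaller k,
then smaller α. The selected pair is reused unchanged on every reduced
subspace (no per-level re-validation). The GA/grid fitness is validation
accuracy; the test set is evaluated exactly once, at the frozen best
weights — the overfitting risk of the GA is accepted and not regularized.

## Synthetic data

The generator emulates the target regime — collections of small simple
labeled graphs (2–6 classes, ~10–100 nodes, symbolic node labels, constant
edge labels) — not any real dataset's distribution. Class c draws node
counts uniformly from `size_range`, edges i.i.d. with density shifted by
±`structure_effect` across classes (infeasible shifts are a hard error),
and node labels from a categorical distribution tilted toward a
class-specific alphabet slice with odds multiplier exp(8·structure_effect),
perturbed by a `noise` probability of uniform relabeling. Defaults
(20 graphs/class, 2 classes, 10–20 nodes, density 0.25, effect 0.1, noise
0.05) were chosen once as a realistic moderately-separable regime;
`structure_effect = 0.09, noise = 0.1` empirically gives the ≈80 %
1-NN baseline used by the grid-dominance check, and 0.3 with density 0.35
gives near-separable classes. What a green test establishes is therefore
algorithmic correctness and the stated ordering/dominance properties on
this stated world — not benchmark-level accuracy on real molecules, which
additionally depends on repository cost settings and label alphabets the
generator does not model (no chemical validity, no degree distributions of
real compounds, no numeric coordinate labels by default).

## Numerical choices and limitations

* Simplex membership is enforced to 1e−9; distance/vote tie tolerances are
  1e−12 on accumulated floats.
* `exact_ged` beyond 12 total nodes, alternative suboptimal matchers
  (beam search, Hausdorff), other centrality measures, and kernel/SVM
  classifiers on the combined distances are out of scope.
* Real-benchmark reproduction requires the published per-dataset cost
  settings (only α is modeled here) and the repositories' own splits; the
  readers support those datasets, but no accuracy claims are made for
  them.
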