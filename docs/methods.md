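# Methods

This note documents the models and procedures behind `knmbp`, the
numerical and design choices that were genuinely open, what the synthetic
data generator does and does not emulate, and the known limitations.

## Model and assumptions

The core hypothesis is *guilt by association on both sides of a bipartite
network*: miRNAs that are functionally similar tend to interact with the
same diseases, and semantically similar diseases tend to involve the same
miRNAs. The predictor therefore needs (a) similarity networks that do not
themselves depend on the interaction matrix, so that rows/columns with no
known interactions remain predictable, and (b) a propagation mechanism
that spreads known interactions along both networks simultaneously.

### Disease semantic similarity

The disease vocabulary is modelled as a rooted DAG (MeSH-style; a virtual
root `ROOT*` is inserted when the edge table has several maximal terms,
because frequency normalization needs a unique root). For a corpus of
disease annotations (disease–gene or disease–GO-process edges), each
term's frequency accumulates over its direct children in reverse
topological order. A term with two parents contributes once per lineage —
the accumulation is defined recursively over children, and we keep that
literal behaviour as the default; a `union` mode that counts every
annotated descendant exactly once is available. Normalized frequencies
`PT = FT/FT(root)` play the role of an information content. (The
normalization is stated self-referentially in some descriptions of this
measure; dividing the accumulated frequency by the root's is the only
reading that keeps `0 ≤ PT ≤ 1`.)

Pair similarity maximizes `2·log PT(a) / (log PT(d₁)+log PT(d₂))` over the
most specific common ancestors `a` (a term counts as its own ancestor, so
self-similarity is 1 for informative terms). Conventions for degenerate
cases: the root (`PT = 1`, `log PT = 0`) contributes 0, never an error;
terms with `PT = 0` carry no information and score 0 against everything,
including themselves. "Most specific" (no descendant is also a common
ancestor) rather than "minimum depth" is adopted — the standard choice
for information-content measures, and the two coincide on trees. Since
`PT` is monotone along ancestor chains, maximizing over all common
ancestors would give the same value; the restriction to the most specific
set is kept for fidelity and clarity.

### miRNA functional similarity

Gene–gene log-likelihood scores are divided by the maximum score
(negative scores are clamped to 0 first; the normalization presumes
scores in `[0, MAX]`). When both orientations of a pair appear, the larger
value wins — a symmetric resolution of the lookup order. Self-similarity
`S^g(g,g)` is undefined by the data (no self-edges) and is set to 1 so
that identical target sets give similarity 1.

miRNA similarity uses the **cross-set** form: genes of set `G_i` are
best-matched against `G_j` and vice versa, normalized by `|G_i|+|G_j|`.
A within-set form (each gene matched against its own set) is identically
1 per gene and would make every pair maximally similar, so it cannot be
what this method family computes. miRNAs with empty target sets are
excluded with a warning — the measure is undefined for them.

### WKNNP profile correction

Absent entries in the interaction matrix mostly mean "untested". Each
row (and column) profile is replaced, where larger, by a decayed
similarity-weighted average of its `K = 15` most similar neighbours'
profiles with decay `α = 0.8`: neighbour `k` (descending similarity, ties
broken by ascending index) receives weight `α^(k−1)·S(i, n_k)`, and the
sum is normalized by `Q_i = Σ_{j∈N(i)} S(i,j)`. The weight's exact form is
a design choice — only `Q_i` and the decay factor are pinned down by the
method's description; the chosen form reduces to the plain
similarity-weighted mean at `α = 1` and to a pure similarity weight at
`K = 1`. The alternative `α^(k−1)`-only weighting is exposed as
`weight_mode="plain"`. Entities with `Q_i = 0` (no similar neighbour) keep
a zero profile rather than NaN. The final correction
`X̂ = max{X, ½(X_m+X_d)}` guarantees observed interactions are never
down-weighted.

### Kernel neighbourhood similarity

KSNS reconstructs each profile of `X̂` from the others in a Gaussian
feature space, with bandwidth `γ = Σ‖x_i‖²/N` (self-tuned to the overall
profile mass; all-zero input is rejected as degenerate). The weights
minimize a quadratic with three terms — kernel reconstruction error, a
penalty `μ₁` on weights outside the `⌊PN·N⌋`-nearest neighbourhoods of the
base similarity, and a ridge `μ₂` — subject to `W ≥ 0`, `diag W = 0`.

The multiplicative update `W ← W ⊙ (K + μ₁·W⊙C) ⊘ (KW + (μ₁+μ₂)W)` is the
standard ratio of the gradient's negative and positive parts, so it
preserves nonnegativity and zeros. Initialization is uniform off-diagonal
`1/(N−1)` with a zero diagonal: the update then enforces `diag W = 0`
forever without projection. The sum-to-one constraint that appears in the
full problem statement is *not* enforced by this update; the subsequent
degree normalization `SI = D^{-1/2} Wᵀ D^{-1/2}` (column sums; zero sums
replaced by 1) is applied unconditionally and absorbs the scale. `SI` is
symmetrized as `(SI+SIᵀ)/2` because the downstream fusion and Laplacian
require symmetric inputs. Convergence: max relative entry change below
1e-6 or 500 iterations; denominators are floored at 1e-12. Fixed points
satisfy the KKT stationarity of the constrained quadratic; this is
verified in the tests against a generic bounded L-BFGS-B minimizer
(agreement ~1e-9, far inside the 1e-3 contract).

### Diffusion fusion

Networks over the same entities are fused by comparing diffusion states:
`Q = p·(I − (1−p)·P)^{-1}` with `P` the row-normalized similarity
(isolated nodes get uniform rows so `Q` stays stochastic) and restart
`p = 0.5`. States are averaged across networks *before* the log (an
equal-weight integration with no extra parameters; per-network
concatenation of log matrices is available via `mode="concat"`), floored
by `ε = 1/N`, and factored by truncated SVD at `d = min(100, N−1)`. The
fused similarity is the Gram matrix of the node vectors `U√Σ`, min–max
rescaled to `[0,1]`, symmetrized, with unit diagonal. All of these
defaults are exposed; none is prescribed by the method's own description,
which delegates to the diffusion-component-analysis lineage.

A consequence worth knowing: diffusion deliberately re-weights pair
rankings by global connectivity, so the fused matrix's off-diagonal
ranking correlates strongly but not near-perfectly with a single input's
(Spearman ρ ≈ 0.75–0.85 on clustered 20-node fixtures). The fusion tests
assert a strongly positive association rather than rank preservation.

### Bidirectional propagation

Scores minimize `‖F−Y‖²_F + (λ_m/2)·tr(FᵀL_mF) + (λ_d/2)·tr(FL_dFᵀ)` with
symmetrically normalized Laplacians (zero-degree rows get unit degree).
The pairwise reading of the smoothness terms — the sum over unordered
pairs of `s_ij‖f_i/√d_i − f_j/√d_j‖²` — equals the trace form exactly,
and the tests verify this identity to 1e-8. `Y` is the WKNNP-corrected
`X̂` by default (`propagate_on="raw"` restores the binary matrix).

The objective is strictly convex (the identity block makes the Hessian
`2I + λ_m L_m ⊗ I + I ⊗ λ_d L_d ≻ 0`), so the minimizer is the unique
solution of `(2I + λ_m L_m)F + λ_d F L_d = 2Y`. Two solvers are provided:

* `solver="exact"` (pipeline default): diagonalize both Laplacians and
  solve the Sylvester system entrywise in the eigenbasis — exact,
  deterministic, O(N³) once.
* `solver="adagrad"`: per-element adaptive gradient descent from
  `F₀ = Y`, steps `η₀/√(G+ε)` with accumulated squared gradients,
  stopping on relative objective change < 1e-6 (defaults `η₀ = 0.1`,
  `ε = 1e-8`, 1000 iterations; a 10-iteration divergence streak halves
  the step once, then raises). Both solvers are verified against a dense
  Kronecker-product linear solve to ≤ 1.5e-7.

Since both routes reach the same optimum, the exact solver is used in
cross-validation loops for speed; the iterative solver exists because
adaptive gradient descent is the natural choice when the dense
eigendecomposition becomes the bottleneck at much larger scale.

## Evaluation protocol

* **CV designs.** `pairs` stratifies known and unknown entries separately
  into five folds (every fold sees the same class balance); `mirnas` /
  `diseases` partition whole rows/columns. For each fold the test units
  are zeroed in the training matrix and *everything* downstream of the
  interaction matrix (WKNNP, KSNS, fusion, propagation) is recomputed
  from the training matrix only.
* **Scoring.** Test scores are min–max normalized per fold (constant
  scores map to all-zero with a warning); positives are called at
  `score ≥ t` on a 1001-point grid over `[0,1]` (both endpoints included
  so the curve reaches (0,0) and (1,1)); TPR/FPR are averaged across
  folds per threshold and the AUC is the trapezoidal area under the mean
  curve. The final AUC is the mean over four seed repetitions by default.
  The grid AUC agrees with the rank-statistic (Mann–Whitney) AUC to
  ~1/1000.
* **Fisher test.** Top and bottom 20 of a ranked candidate list; the
  two-sided p-value sums all hypergeometric tables no more probable than
  the observed one — the convention that reproduces the published
  case-study values (5.2959e-7 for 18/20 vs 2/20; 1.4509e-11 = 2/C(40,20)
  for 20/20 vs 0/20).
* **Grid search.** Exhaustive AUC tables over
  `PN ∈ {0.1,0.3,0.5,0.7,0.9}`, `μ₁,μ₂ ∈ {2⁰..2⁴}`, `λ ∈ {2⁻²..2²}`
  (`λ_m = λ_d`), with max/mean/min marginal summaries. Pipeline defaults
  are the fixed constants `K = 15`, `α = 0.8` and the grid midpoints
  `PN = 0.5`, `μ₁ = μ₂ = 4`, `λ = 1`.

## Synthetic study systems

The generator produces all four inputs with the structural features the
method exploits, at the default scale of 200 miRNAs × 150 diseases ×
500 genes:

* a rooted disease DAG whose top-level branches form disease families
  (one family per latent factor, terms attaching to one or two earlier
  family members), with zero-inflated-Poisson annotation counts for two
  corpora — so within-family pairs share informative ancestors;
* a modular gene network (denser, stronger within-module edges) with
  miRNA target sets drawn ~80% from one module — so the functional
  similarity has block structure;
* an interaction matrix sampled from probabilities built by smoothing
  rank-5 Gaussian latent factors over both similarity graphs (two steps
  of the row-normalized similarity operator) and squashing through a
  logistic centred at the density quantile (~4% positives, matching the
  sparsity of curated interaction databases). 10% of sampled positives
  are held out as evaluation truth; 5% of the observed positives are then
  flipped against random negatives, emulating annotation errors.

What this does **not** emulate: the heavy-tailed degree distributions of
real curated databases, literature bias (well-studied miRNAs accumulate
annotations across all corpora), ontology depth heterogeneity, and the
correlated noise of shared curation pipelines. Passing the planted-signal
tests therefore shows the pipeline recovers the *kind* of structure it
assumes, under realistic sparsity and noise — not that it attains any
particular accuracy on real HMDD/CTD-derived data, which is out of scope
here.

With these defaults the full cross-validated pipeline reaches mean AUCs
of roughly 0.85–0.91 (pairs), 0.80–0.88 (miRNAs), 0.84–0.90 (diseases)
over five seeds, while entry-shuffled controls sit at 0.50 — the
separation the acceptance checks require. A full CVa/CVm/CVd run plus
control on one CPU takes ~3 s per fold, ~4 minutes in total; these
problem sizes were chosen so the whole evaluation stays interactive.

## Known limitations

* Memory: similarity matrices are dense `N×N` arrays; entity universes
  beyond ~20k would need sparse/low-rank variants of KSNS and the fusion.
* The DAG similarity is quadratic in the number of terms with set
  intersections per pair; fine to a few thousand terms.
* The exact propagation solver assumes both Laplacians fit in memory and
  diagonalize; at larger scale switch to `solver="adagrad"`.
* Fusion defaults (restart, dimension, log floor) follow the diffusion
  embedding lineage but are not uniquely determined by the method's
  description; conclusions that hinge on fusion details should sweep
  these settings.
* The generator's planted signal is low-rank and graph-aligned by
  construction; methods could look better on it than on real data
  precisely because the assumption is planted. The permuted control
  guards against leakage, not against over-optimism.
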