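# Methods

This note documents the models implemented in `kgcascade`, the defaults and
the reasoning behind them, what the synthetic generators do and do not
emulate, and the numerical choices that were genuinely open.

## Translation embedding (`transx`)

A fact (h, r, t) is scored by the dissimilarity d(h, r, t) = ‖h_p + r − t_p‖
under the L1 or L2 norm. For TransE the entity vectors are used directly
(entity and relation dimensions must agree); for TranSparse each relation
carries two m×n projection matrices M_rh, M_rt applied to the head and tail.
The *sparse degree* θ of a projection matrix is the fraction of structurally
zero entries; we assign it per relation and side as

    θ = 1 − (1 − θ_min) · N / N_max

where N counts the distinct head (or tail) entities the relation links and
N_max is the maximum over relations, so the busiest relation gets the densest
(most expressive) projection. We use the separate, unstructured variant —
independent masks per relation/side with the diagonal kept nonzero first and
the remaining nonzeros placed at random — because nothing in the problem
fixes a structured pattern. θ_min defaults to 0. The zero pattern is fixed at
initialization and conserved exactly through training (a property test checks
this).

Training minimizes the margin ranking loss Σ [γ + d(pos) − d(neg)]₊ by
minibatch SGD with exactly one corruption per positive per step. Corruptions
replace the head or tail (Bernoulli ½) with a uniform random entity and are
rejected while they collide with a known positive of the training set.
Entity vectors are renormalized to the unit L2 ball after each epoch;
relation vectors and projected vectors are not normalized. The L1 subgradient
at zero is taken as 0. An optional linear learning-rate decay (`lr_final`)
refines late training. Default hyper-parameters follow the reference
protocol for the full-scale biochemical graph: γ = 1.5, learning rate 0.001,
n = m = 100, 1000 epochs, L1 dissimilarity. The scaled-down studies in the
tests and the acceptance script use dim 4, margin 0.25, L2, learning rate
0.05 decaying to 0.002, 600 epochs, per-sample updates — settings sized for a
50-entity graph with ~200 facts, chosen once and recorded here.

Analytic gradients (including the masked projection-matrix gradients) are
verified against central finite differences to a relative error below 1e-4
for both models and both norms.

### Open choices resolved

* The dissimilarity subscript "L1/2" is read as "L1 or L2 norm"; the
  exponent-½ reading was rejected as inconsistent with "L1 is dissimilarity".
* The relation dimension m defaults to the entity dimension n, since a single
  embedding size is quoted for the reference experiments.

## Walk embedding (`walker`)

The multi-relational graph is homogenized — direction and relation labels
dropped, at most one edge per entity pair — before walking. (On the
biochemical dataset this collapse is lossless for connectivity because
distinct entity pairs carry at most one relation.) A second-order walk at
`cur` arriving from `prev` weights each neighbor x by 1/p if x = prev, 1 if x
is adjacent to prev, 1/q otherwise; the first step is uniform. Step
distributions are memoized per (prev, cur) state rather than materialized as
alias tables up front — same O(1) amortized sampling, no precomputation pass.

The skip-gram trainer is a vectorized numpy implementation of negative
sampling: for each (center, context) pair within the window, maximize
log σ(u_ctx·v_cen) and draw `negatives_per_sample` noise nodes from the
unigram distribution raised to 0.75. Gradients are scatter-summed per
minibatch, so the batch size is capped at the vocabulary size — with a large
batch on a small graph a frequent node would take the summed step of hundreds
of pairs at once and training diverges. The learning rate decays linearly
from 0.025. Defaults follow the reference protocol (p = q = 1, d = 128,
walk length 80, context 10, 3 walks per node); the desk-scale studies use
d = 16, length 40, 10 walks per node, context 5 for 50-entity graphs.
Correctness checks: exact transition weights on the canonical second-order
motif, χ² uniformity of realized steps at p = q = 1, and separation of two
bridged cliques in embedding space.

## Cascade (`cascade`)

Per triplet, the semantic feature F = |h_r + r − t_r| (elementwise absolute
residual, m-vector) and the graph feature G = u(h) ∗ u(t) (hadamard,
d-vector). Each cascade stage is a logistic classifier minimizing

    L(θ) = −Σ [y log p + (1 − y) log(1 − p)] + α‖θ‖²

with the bias unpenalized; the fit is delegated to a deterministic
quasi-Newton solver (lbfgs, tolerance 1e-6, C = 1/(2α)). The penalty is the
standard ridge α‖θ‖² — the quadratic reading of the L2 regularizer. α
defaults to 1.0 (no value is prescribed anywhere; unit ridge on roughly
unit-scale features).

The stage wiring is the one point where the framework is genuinely open: the
only stated constraint is that graph features pass through stage one alone
and are then concatenated with the knowledge-embedding features. We pin the
minimal reading: stage 1 fits on G; stage 2 fits on [F ∥ p₁] where p₁ =
σ(θ₁ᵀG + b₁) is stage 1's probability — a scalar refinement of G. The
ablation plans `s` (F only), `g` (G only) and `sg` (plain [F ∥ G]) are
implemented as single-stage fits; whether the reference ablations used one
or two stages is ambiguous, and a single stage is the simplest consistent
reading. Classifier training uses a fixed 1:1 positive:corruption ratio,
sampled once.

## Tasks (`tasks`)

Link classification fits a per-relation threshold δ_r maximizing 0/1
accuracy over all cut points (midpoints of adjacent sorted unique scores
plus ±∞, ties toward the smaller threshold — the more permissive cut), then
classifies held-out positives and an equal number of corruptions. Entity
ranking replaces the query's head or tail with every entity, removes
candidates forming other known-true facts (train ∪ test) in the *filtered*
setting, always retains the true candidate, and reports rank = 1 + the
number of strictly better candidates (optimistic tie handling — ranks are
otherwise ill-defined under score ties). Distance scorers rank
lower-is-better, probability scorers higher-is-better, through the same
machinery. ROC curves and AUC use the standard threshold sweep.

### Cross-fitted calibration

At full data scale (hundreds of thousands of facts) thresholds fitted on
training scores transfer to test data. At desk scale they do not: an
embedding trained on ~10² facts memorizes them, its training positives score
far better than held-out positives, and the accuracy-maximizing cut sits in
the inflated training gap. `crossfit_calibrated_scorer` (and
`crossfit_cascade_scorers` for the full stack) restore the intended behavior
by stacked generalization: K = 5 fold models are trained on fold
complements, each fold's positives and corruptions are scored *out of fold*,
thresholds are fitted on those unbiased scores, and test triplets are scored
by the fold ensemble (mean). This is a calibration protocol, not a change of
model; the scaled-down recovery studies use it and the package exposes it as
ordinary library surface.

## Meta-paths (`metapath`)

A meta-path is an ordered relation list; candidates for each step are the
entities observed as tails (or heads, when a step is traversed inversely —
an explicit flag, since relation directions in stored facts need not match
the traversal direction) of that relation anywhere in the fact set. Greedy
beam expansion keeps the top k continuations per frontier path (ties broken
by entity id), intermediate entities may not repeat, and reliability is the
product of step probabilities and the closing head–tail probability. Paths
whose every constituent triplet, closing link included, is already a known
fact are removed. k defaults to 10 and the output is truncated to the top
100 paths, matching the reference use. With k = |E| the beam provably equals
exhaustive enumeration (tested against an itertools oracle).

## Synthetic data (`synth`)

`make_translation_kg` draws latent entity points and relation offsets from a
standard normal in R^k (default k = 4, 50 entities, 2 relations) and emits,
per relation, the 100 ordered pairs with the smallest latent residual
‖h* + r* − t*‖ (+ optional Gaussian noise) — quantile emission makes the
per-relation count exact. With `n_clusters > 1` the latent points are drawn
around cluster centers, so emitted links are mostly intra-community and the
graph carries topological signal that a walk embedding can exploit alongside
the translation geometry. Note a structural property of quantile emission:
positives just below the cut and negatives just above it are arbitrarily
close in latent space, so no imperfect model can classify the boundary
region perfectly even at zero noise — ranking metrics are much less
sensitive to this than absolute-threshold accuracy.

`make_imbalanced_kg` emulates extreme fan-out and the long-tailed degree
profile of real biochemical relations: distinct head/tail pool sizes are set
from the targeted means (so the realized means land within 10%), every pool
member is used at least once, and extra occurrences are allocated by
preferential attachment, which concentrates degree on a few entities and
leaves the majority at degree 1.

`make_cascade_fixture` draws standard-normal features with Bernoulli(σ(θᵀx))
labels for parameter-recovery tests; unlike real semantic residuals its
"F block" is not nonnegative — it tests the optimizer, not feature
semantics.

What the generators do **not** emulate: multi-typed entities, relation
semantics, the coupling between relations sharing entities, and the sheer
scale of real biomedical graphs. Passing the scaled-down studies shows the
machinery is correct and that the cascade's qualitative behavior (fusion no
worse than the better single-signal model; graph features rescuing imbalanced
relations) reproduces — it does not certify full-scale accuracy numbers.

## Pipeline and reproducibility

`run_pipeline` executes split → translation training → walk training →
feature building → cascade fit → threshold fit → link and ranking
evaluation. One global seed fans out to per-stage seeds through
`numpy.random.SeedSequence`, every report embeds its seeds and sub-configs,
and a rerun with the same config reproduces the report exactly (all training
is single-threaded and deterministic). Degenerate inputs are defined
behavior: an empty triplet file loads as an empty graph, a relation with one
class of training scores gets a ±∞ threshold with a warning, an isolated
node yields a singleton walk, and corruption of a fully-connected slot
raises an exhaustion error.

## Known limitations

* The skip-gram and SGD trainers are plain numpy; they are sized for graphs
  of 10²–10⁴ nodes, not the 3·10⁵-entity full dataset (the reference-scale
  defaults exist but expect hours of CPU time).
* TranSparse shares TransE's training loop; Bernoulli relation-aware
  negative sampling and other corruption variants are out of scope.
* The cascade is limited to logistic stages; calibration beyond the logistic
  output (e.g. isotonic) is not attempted.
* Meta-path search assumes type compatibility can be inferred from observed
  relation usage; no explicit type system is modeled.
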