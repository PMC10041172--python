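# Methods

## Generative model

A lineage-tracing experiment is modeled as a rooted tree 𝒯 of height 1 whose
leaves are the n sequenced cells.  Time is measured in units of the
experiment duration, so every leaf sits at depth 1 (ultrametric).  The tree
carries an *implicit root* attached by a single edge: the progenitor's own
lifetime, during which edits can already accrue and be shared by every cell.

Each of the k characters evolves independently as an irreversible
continuous-time process: an unedited (state 0) character mutates along an
edge of length t with probability 1 − e^(−λt) and then adopts indel state
j ∈ {1..m} with probability q_j, never changing again.  The default state
distribution is uniform (q_j = 1/m), for which the collision probability
q = Σ q_j² equals 1/m.  Dropout renders entries unreadable (−1): *stochastic*
dropout masks each leaf entry independently, *heritable* dropout places
events on edges (probability 1 − e^(−rt) per character per edge) that mask
the character in the entire descendant clade.  `heritable_rate_for_total`
splits a target per-leaf missing probability p_d between the two mechanisms.

### Topology regimes

* **uniform** — a complete binary tree over n = 2^h leaves plus the implicit
  root edge; all log2(n)+1 edges on a root-to-leaf path have length
  1/(log2(n)+1).  This emulates a regular molecular clock; with n = 256
  every edge is 1/9.
* **asynchronous** — a forward-time Bellman-Harris branching process:
  division waiting times are a + Exp(birth_rate) with a = 0.05 the minimum
  time between divisions, death waiting times are Exp(death_rate), and all
  lineages stop at time 1.  Lineages that die are pruned and the resulting
  unifurcations suppressed (their edge lengths summed).  Trees are rejection
  sampled until the leaf count falls in [205, 307].  Note leaf edges are
  truncated at the collection time, so only division-to-division edges are
  bounded below by a.

The birth/death rates are not pinned down by the leaf-count window alone.
The defaults (birth_rate = 13.0, death_rate = 0.3) were chosen with
`scripts/calibrate_async.py` so that the median leaf count sits near the
middle of the acceptance window and roughly a quarter of draws are accepted;
any rates with a similar growth constant behave equivalently for the
questions studied here.

λ = 0 is accepted by the simulator as a degenerate no-editing control (all
leaves unedited); the closed-form model and bound functions require λ > 0.

## Triplet similarity theory

s(u, v) counts characters in which u and v carry the same nonzero,
nonmissing state.  For a triplet (a, b | c) with LCA depth d and ingroup
separation α, the exact expectations of the post-divergence counts are

    E[s_c(a,b)] = k e^(−λd) ((1 − e^(−λα)) + e^(−λα) (1 − e^(−λ(1−α−d)))² q)
    E[s_a(b,c)] = k e^(−λd) (1 − e^(−λ(1−d)))² q

(single shared event on the LCA→ingroup-ancestor path, plus homoplasy on the
two terminal paths; the outgroup can only match by homoplasy).  Using
0.6x ≤ 1 − e^(−x) ≤ x on [0, 1] (hence the standing assumption λℓ\* ≤ 1),
the gap is bounded below by k λ ℓ\* δ(d) with

    δ(d) = 0.6 (e^(−λd) (1 − q) + q e^(−λ(2−d))).

δ is convex in d with stationary point x₀ = (ln((1−q)/q) + 2λ) / (2λ), so

    δ* = min_{x ∈ [0, d*]} δ(x) = δ(clamp(x₀, 0, d*)),

with the limits q → 0 (minimum at d\*) and q → 1 (minimum at 0) handled
explicitly.  The test suite verifies this closed form against dense-grid
minimization to 10⁻⁹ over a 1000-point (λ, q, d\*) grid.

## Partial oracle and top-down reconstruction

The oracle compares the three pairwise similarities of a triplet against
t = ½ k λ ℓ\* δ\*: if one pair exceeds both others by more than t, the
remaining cell is declared the outgroup, otherwise the oracle abstains.
Only one margin can exceed a nonnegative threshold, so the answer is unique.
Under worst-case missing data, similarities are recomputed per triplet over
the characters observed in *all three* cells and the threshold is scaled by
(1 − p_d)³ (the worst-case probability that a character survives in all
three).

Two reconstruction strategies consume this signal:

* **Threshold splitting** — at each recursive call over cell set V, build the
  complete similarity-weighted graph and delete the globally minimum-weight
  edges (all ties at once, which keeps the procedure deterministic) until the
  graph disconnects; the connected components become child subproblems.
  Each call costs O(k|V|²) for the similarity matrix.  If every edge weight
  is equal the node becomes a multifurcation over its cells.
* **Aho supertree** — enumerate all C(n,3) triplets in lexicographic order,
  query the oracle, and assemble the non-null answers recursively: connect
  {a, b} for every resolved (a, b | c) inside the current set, recurse per
  connected component, and join under a new root.  A component that never
  splits (an irreducible constraint set) is emitted as a multifurcating node
  so the algorithm is total.

## Bottom-up reconstruction

Starting from singleton subtrees, repeatedly join the pair of subtrees whose
inferred roots share the most mutations, replacing them with a subtree rooted
at the two-child maximum-parsimony state: a character keeps a state only
when both children agree on that nonzero state, else it is reset to 0 (the
correct rule under irreversible mutation from an unedited ancestor).
Missing entries never match and thus force 0; the bottom-up guarantee regime
assumes no missing data, so this is a conservative convention rather than a
analyzed estimator.  Ties in the best pair are broken toward the
lexicographically smallest pair of sorted member-label tuples, making reruns
bit-identical.  The naive implementation scans all pairs per join (O(n²)
joins overall with an O(nk) update), which is ample at the scales studied.

## Sufficient character counts

With ζ the failure budget and natural logarithms throughout (the constants
96/32 and 20/10 absorb the concentration machinery, which is base-e; a
`log_base` switch exists for sensitivity analysis only):

* condition (i) (correct outgroup margins):
  k ≥ (96 ln n + 32 ln 1/ζ)(ℓ\* + (1 − e^(−λ)) q) /
  (0.6 λ ℓ\*² δ\* (1 − q + q e^(−2λ)))
* conditions (i)+(ii): the max of the above and
  (96 ln n + 32 ln 1/ζ) q / (ℓ\*² δ\*²)
* missing data: the two branches acquire (1 − p_d)³ and (1 − p_d)⁵
  denominators respectively — the dominating branch at small q is cubic in
  1/(1 − p_d)
* bottom-up (edges in [ℓ, cℓ], q_max ≤ (3/16)(1 − e^(−λcℓ)),
  β = λq·max(1, c) below 1/(1 + C + 2(e^(−λℓ) + 2λcℓq_max)²) with
  C = 2cℓe^(−λ) + 4λcℓq_max):
  k ≥ (20 ln n + 10 ln 1/ζ) / (λ e^(−λℓ) (1 − β(1+C)) (1 − β(1+C) −
  2β(e^(−λℓ) + 2λcℓq_max)²)).

Inadmissible parameter combinations raise (point queries) or are returned as
NaN cells (heatmap mode), mirroring excluded regions in bound surfaces.

**Scaling checks.**  The top-down bound is Θ(1/ℓ\*²) at fixed (λ, q, n, ζ);
the log-log slope over ℓ\* ∈ [10⁻⁴, 10⁻²] is −2 to within a few percent.
The bottom-up bound at *fixed* λ tends to a constant as ℓ → 0; its Θ(1/ℓ)
character emerges in the low-mutation-rate regime where λ shrinks with the
shortest cell cycle.  The scaling test therefore couples λ = ℓ and sets
q_max at half its admissibility cap, a path lying inside the admissible
region along which the bound is ≈ 20 ln n / λ = Θ(1/ℓ); the measured slope
is −1.

## Empirical minimum-k harness

For a parameter point and reconstruction method, a character count k is
*sufficient* when at least 9 of 10 replicates meet the scoring criterion —
exact reconstruction up to depth d\* (every leaf triplet with true LCA depth
≤ d\* resolved identically), or a triplet-fraction threshold.  Uniform-regime
replicates overlay 10 mutation datasets on one topology; asynchronous
replicates draw 10 topologies with one overlay each.  The search doubles k
from 1 until sufficiency or a cap (4096 without missing data, 8192 with),
then binary-searches the final bin; all (k, successes) pairs in the bin feed
a grouped-binomial logistic regression (per-replicate Bernoulli expansion is
also supported), and the reported minimum is the first integer k whose
fitted success probability reaches 0.9.  Pointwise 95% bands on the fitted
curve come from the delta method on the linear predictor; the interval's
upper (lower) end is the first k whose lower (upper) band reaches 0.9.
Degenerate bins (all-success/all-failure, or a separation the fit cannot
represent with a positive finite slope) fall back to the final bracket
midpoint with a flagged interval.  Every k is evaluated with an RNG derived
from (master seed, k), so recounts are identical and the whole search is
reproducible end to end.

**Triplet scoring** uses pairwise-LCA depth matrices built in O(n²) by
postorder accumulation; a triplet is resolved toward the pair whose LCA is
strictly deepest (edge-count depth, so inferred trees need no branch
lengths) and a multifurcation resolves nothing.  The depth gate uses the
true tree's branch-length depths.  A triplet unresolved in the true tree is
never counted as correct; simulated ground-truth trees are binary, so this
convention is only visible on artificial inputs.

## Problem sizes in the shipped tests

The test suite and acceptance script run the full pipeline at deliberately
modest scales — 16–64-cell uniform trees, 32-cell minimum-k grids over
λ ∈ {0.5, 4} × q ∈ {0.01, 0.5} with a 2048 cap, 10⁴-replicate Monte-Carlo
checks, 500-trial oracle guarantee checks — chosen so the whole suite
completes in about half a minute while still exercising every guarantee at
its stated confidence.  Larger surfaces (256-cell trees, asynchronous
topologies, full heatmaps) use exactly the same code paths through the
public API and CLI.

## What the simulator does and does not emulate

The generator realizes the model faithfully: ultrametric binary ground
truth, per-character Poisson editing with a state distribution, heritable
and stochastic dropout.  It does not model cassette-level correlations
(multi-site deletions or shared silencing beyond single characters),
sequencing error states, per-site editing-rate differences, or time-varying
Cas9 activity.  Passing tests therefore demonstrate correctness of the
algorithms and formulas *under the model*; on real data, where these
violations are present, the bounds should be read as design guidance rather
than guarantees.

## Numerical and design choices

* Tolerances: closed forms are checked to 10⁻⁹ relative/absolute; Monte
  Carlo agreement to 3 standard errors; statistical guarantees with 3σ
  binomial slack at 500 trials.
* The threshold splitter deletes all tied minimum edges in one batch — both
  one-at-a-time and batch deletion satisfy the correctness argument; batch
  is deterministic without an edge order.
* Reconstructed trees carry unit branch lengths: both algorithms recover
  topology only, and branch-length estimation is out of scope.
* Cells are sorted by label before reconstruction and triplets enumerated
  lexicographically, so outputs are stable across runs and platforms.
* Newick I/O goes through dendropy, TSV through pandas; the implicit-root
  edge survives round trips as a unifurcation at the tree base.
* Known limitations: the Aho reconstructor materializes all C(n,3) triplet
  queries (vectorized, but O(n³) memory in the triplet index), and the
  worst-case missing-data mode recounts similarities per triplet in chunks;
  both are fine for hundreds of cells but not tens of thousands.
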