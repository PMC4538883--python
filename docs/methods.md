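# Methods

## Model and scope

A *binary phylogenetic network* over a taxon set X is a rooted DAG whose
leaves (out-degree 0, in-degree 1) are bijectively labeled by X, whose
unique root has in-degree 0 and out-degree 1 or 2, and whose remaining
vertices are reticulations (in 2, out 1) or tree vertices (in 1, out 2).
Parallel arcs are legal — two attachment points adjacent on a support tree
may carry a linking arc — so arcs have their own identity throughout and
the graph is a multidigraph.  Branch lengths are parsed and ignored; only
topology enters any computation.  Non-binary and unrooted networks are out
of scope.

Tree-basedness is decided through admissible arc subsets: S is admissible
when it contains every arc of S1 (arcs whose source has out-degree 1 or
whose target has in-degree 1), keeps exactly one in-arc per reticulation
(C1) and at least one out-arc per bifurcation (C2).  Admissible subsets
are in bijection with support trees, which is what licenses counting
support trees by counting admissible subsets.

## Decision procedures

* **Propagation.**  All S1 arcs start labeled `t`; rules (C1)′ (a `t`/`f`
  on one in-arc of a reticulation forces `f`/`t` on the other) and (C2)′
  (an `f` on one out-arc of a bifurcation forces `t` on the other) are
  closed under a FIFO worklist seeded in ascending arc-id order.  Each rule
  is a sound implication of C1/C2, so the fixpoint is order-independent
  (the confluence test shuffles the seed order 20 ways); the fixed seeding
  only makes the *first conflict witness* deterministic.  Only the first
  conflict is reported, mirroring a procedure that stops at the first
  double label.
* **2-SAT.**  One boolean per arc; unit clauses for S1; (a ∨ b) ∧ (¬a ∨ ¬b)
  per reticulation (parallel arcs contribute two distinct variables even
  with identical endpoints); (c ∨ d) per bifurcation.  Solved by the
  implication-graph construction: unsatisfiable iff some variable shares a
  strongly connected component with its negation, with the satisfying
  assignment read off the condensation's topological order.  Propagation
  alone is not a complete decision procedure (open in-arc pairs can hide an
  unsatisfiable residual), so the `propagate` method falls back to 2-SAT on
  the residual instance; both methods are tested for agreement and against
  exhaustive subset search.
* **Enumeration.**  Support trees are enumerated by branching on the open
  in-arc pair of the lowest-id reticulation, trying `t` before `f`, with
  propagation after each choice — giving a reproducible output order.  Every
  emitted subset is re-verified against the full invariant block (S1
  containment, C1/C2, rooted spanning tree with leaves in X, independence
  of the linking arcs).  Enumeration is capped by `limit` (default 1024)
  with an explicit truncation flag, because the number of support trees can
  reach 2^k and exact counting is #P-hard; `is_based_on` therefore returns
  three-valued output (`True`/`False`/`"unknown"`) instead of silently
  truncating.

## Tree identity

Two reticulation-free networks are compared by their *sets* of leaf
clusters, which deliberately identifies trees differing only by a root
vertex of out-degree 1: a support tree may use just one of the root's two
out-arcs, leaving a root edge on the extracted base tree that carries no
phylogenetic information.  Without this identification the three-taxon
example network would appear to have four base trees rather than its three
distinct rooted triples.  General networks are compared by VF2 isomorphism
on the multidigraph with leaf labels as the node invariant and parallel-arc
multiplicities respected; this is adequate at desk scale (hundreds of
vertices), which is the regime all of these analyses target.

## Diagnostics

The maximum antichain (over ALL vertices, leaves included — the leaf set
itself is an antichain, so tree-based networks have maximum exactly |X|)
is computed by Dilworth's theorem: a maximum matching on the bipartite
split of the transitive closure gives the minimum chain cover, and the
König vertex cover recovers an antichain of matching size.  The
antichain-to-leaf property quantifies over antichains of NON-leaf vertices;
it suffices to check maximal ones (any antichain extends to a maximal one,
and arc-disjoint paths restrict to subsets), enumerated as maximal cliques
of the incomparability graph with a configurable cap (default 10^5,
exceeded ⇒ `"unknown"`).  Arc-disjoint path counts are unit-capacity
max-flow with each antichain member attached to a super-source with
capacity 1 and parallel arcs contributing their multiplicity.  The class
predicates (tree-child, tree-sibling, reticulation-visible, the
two-bifurcating-parents and two-unary-parents conditions) are evaluated
literally from their definitions; visibility tests, per reticulation,
whether removing it disconnects some leaf from the root.  The tree-sibling
check requires the in-degree-1 sibling through a shared parent, so a
reticulation reached by parallel arcs gains no sibling through that parent.

## Augmentation and temporal orderings

`make_tree_based` subdivides one in-arc per reticulation and hangs a new
leaf `x_<v>` off the subdivision point; which in-arc is a free choice, so
the lowest-arc-id rule is the deterministic default with the highest-id
rule exposed as an option.  The output restricts back to a network
isomorphic to the input; idempotence is *not* claimed (a tree-based input
with reticulations still gains leaves).

A weak temporal ordering is any topological numbering (lexicographic by
vertex id here, for determinism); it exists for every acyclic network.
Strong orderings relative to a support tree merge linking-arc endpoints
into equivalence classes; an ordering exists iff no support arc joins a
class to itself and the quotient graph is acyclic, in which case classes
are timed by longest-path levels — integer levels suffice since any
strictly monotone re-timing is equivalent.  The existence check over all
support trees reports `no` with a distinguishing reason when the network
has no support tree at all, since the notion is only defined relative to
one.

## Synthetic data

`random_base_tree(n, seed)` grows a rooted binary tree by sequential
uniform arc subdivision.  `add_linking_arcs(T, k, seed)` realizes the
generative definition of tree-based: each step subdivides two support-tree
arcs (never a linking arc) and joins the fresh attachment points, rejecting
placements that would close a directed cycle and failing loudly after
`max_tries` rather than returning a partial result.  Its outputs are
tree-based by construction with T among their base trees — a hard
guarantee, asserted over the sampled pool, not a statistical one.
`random_binary_network(n, k, seed)` uses the same growth but lets linking
arcs start or end on earlier linking arcs, which is exactly what the
generative process forbids; its outputs are valid binary networks with no
tree-basedness guarantee, and at n = 4, k = 3 both verdicts occur in the
seeded pool (frozen witness seeds are asserted in the tests).  All
randomness flows through per-call `random.Random(seed)` instances; no
global state.

What the generator does not emulate: branch lengths, non-uniform tree
shapes (no birth–death model), biased placement of reticulations, or any
inference noise — fixtures and samples exercise the combinatorial claims
only, so passing tests say nothing about estimating networks from sequence
data.

## Problem sizes and test design

The oracle sweeps run the implementation against independent brute force:
exhaustive subset search for tree-basedness and support-tree counts
(networks are kept to ≤ 15 non-S1 arcs), bitmask enumeration for maximum
antichains (≤ 14 vertices), pruned exhaustive time-assignment search for
strong orderings (≤ 8 vertices, values 0..|V|), and exhaustive assignment
search for random 2-SAT instances (≤ 12 variables).  Implication sweeps
(class ⇒ tree-based, antichain facts, count ceilings, base ⊆ displayed)
run over a 200-network seeded pool with n ∈ {3..6}, k ∈ {0..4} — sizes
chosen so the full suite completes in seconds while every code path,
including parallel arcs and failure modes, is exercised.

## Known limitations

* `is_based_on` is brute force over enumerated support trees; whether the
  question is decidable in polynomial time is open, and no attempt is made
  beyond honest three-valued reporting.
* Exact support-tree counting is #P-hard in general; the enumeration cap
  is the only defense, and counts are exact only when the flag shows no
  truncation.
* The 2-SAT solver is a straightforward SCC construction with no
  linear-time guarantees claimed.
* Isomorphism uses VF2 with leaf labels as the only invariant; adversarial
  unlabeled-symmetric networks beyond desk scale could be slow.
* eNewick support covers the `#H`-tag dialect with merged hybrid vertices
  and duplicate child listings for parallel arcs; exotic dialect features
  (per-occurrence branch annotations on hybrid references) are parsed for
  topology only.
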