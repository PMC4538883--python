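# treebasenet

Tools for deciding whether a rooted binary phylogenetic network is *merely a
tree with additional arcs* — a **tree-based network** — and for exploring the
trees it can be built from.

## The problem

Explicit phylogenetic networks place reticulate events (hybridization,
lateral gene transfer, endosymbiosis) as vertices with two incoming arcs.
A long-running question is whether such a network still admits an
"underlying species tree": can it be drawn as a rooted binary tree whose
arcs were subdivided, with extra *linking arcs* placed between the
subdivision points?  If yes, the network is *tree-based* and the tree is a
*base tree*; if not, no underlying-tree reading of the network exists for
the sampled taxa.  This matters to anyone interpreting hybridization or
transfer networks — e.g. the reticulate history of bread wheat, which is the
package's running example.

## The criterion

For a network N = (V, A) on leaf set X, let

```
S1 = { a in A : source(a) has out-degree 1, or target(a) has in-degree 1 }.
```

N is tree-based **iff** A has an *admissible* subset S with S ⊇ S1 such
that every reticulation keeps exactly one in-arc in S (C1) and every
bifurcation keeps at least one out-arc in S (C2).  Admissible subsets are
exactly the support trees (subdivided base trees) of N, and the conditions
are a 2-SAT instance — one boolean per arc — so recognition is
polynomial-time.  The package implements both decision routes:

* **label propagation** — start with every S1 arc labeled `t` ("in S") and
  close under the implication rules (C1)′/(C2)′; a doubly-labeled arc is a
  certificate of non-tree-basedness;
* **2-SAT** — an implication-graph / strongly-connected-components solver.

Around the decision procedure sit: exhaustive support-tree and base-tree
enumeration (branching over the ≤ 2^k choices at the k reticulations),
`displays` vs `based on` comparisons, structural screens (maximum antichain
vs |X|, the antichain-to-leaf property via unit-capacity max-flow, the
tree-child / tree-sibling / reticulation-visible class predicates), an
augmentation that makes any network tree-based by adding one unsampled
taxon per reticulation, and weak/strong temporal orderings.

## Worked example: the bread-wheat network

The bundled fixture `fig4_wheat` is a five-taxon, three-reticulation
network for wheat evolution (a = *Triticum urartu*, b = *T. turgidum*,
c = *T. aestivum*, d = *Aegilops tauschii*, e = *Ae. speltoides*).

```python
from treebasenet import (fixture, initial_labeling, propagate_labels,
                         enumerate_support_trees, base_tree, write_network)

wheat = fixture("fig4_wheat")
labeling = propagate_labels(wheat, initial_labeling(wheat))
print("open arcs:", len(labeling.unassigned()))
supports = enumerate_support_trees(wheat)
print("support trees:", len(supports))
for st in supports:
    print(write_network(base_tree(wheat, st), "newick"))
```

prints

```
open arcs: 6
support trees: 8
(((a,b),(c,d)),e);
((a,b),((c,d),e));
(((a,(b,c)),d),e);
((a,(b,c)),(d,e));
((a,(c,d)),(b,e));
(a,((b,e),(c,d)));
((a,d),((b,c),e));
(a,(((b,c),e),d));
```

Reading: after the forced `t` labels, six arcs (the in-arc pairs of the
three reticulations) remain open and no rule fires, so the network is
tree-based with one independent binary choice per reticulation — 2³ = 8
support trees — and here the eight base trees are all distinct.  The network
cannot tell which of the eight is "the" species tree.

The same analyses are available from a shell:

```sh
treebasenet check wheat.json            # exit 0 = tree-based, 1 = not
treebasenet support-trees wheat.json --limit 10
treebasenet classify wheat.json
treebasenet augment not_tree_based.json
```

All subcommands print a single JSON report; identical inputs and seeds give
byte-identical reports.

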