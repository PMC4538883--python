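"""Making any network tree-based by attaching new leaves at reticulations.

Every binary phylogenetic network N over X embeds in a tree-based network
N+ over a superset X+ of X with N = N+|X: for each reticulation v, subdivide
one of its incoming arcs and hang a new leaf off the subdivision point.  The
full arc set of N, with each chosen in-arc replaced by its two subdivision
halves plus the pendant arc, is then admissible.  Biologically the new
leaves stand for unsampled or extinct taxa whose presence would let the
observed reticulate history be drawn as a tree with linking arcs.
"""

from __future__ import annotations

from .errors import TreebasenetError
from .network_core import PhyloNetwork, require_valid


def make_tree_based(net: PhyloNetwork, choose: str = "lowest_arc_id") -> PhyloNetwork:
    """Return N+ : tree-based, one new leaf ``x_<v>`` per reticulation v.

    Which of the two incoming arcs is subdivided is a free choice;
    ``choose`` picks the one with the lowest (default) or highest arc id,
    deterministically.  Restricting N+ back to the original leaf set
    recovers a network isomorphic to N.
    """
    require_valid(net)
    if choose not in ("lowest_arc_id", "highest_arc_id"):
        raise ValueError(f"unknown choice rule {choose!r}")
    augmented = net.copy()
    existing = set(net.leaf_labels())
    for v in net.reticulations():
        in_arcs = augmented.in_arcs(v)
        arc = in_arcs[0] if choose == "lowest_arc_id" else in_arcs[-1]
        label = f"x_{v}"
        if label in existing:
            raise TreebasenetError(f"new-leaf label {label!r} collides with a taxon")
        attachment = f"w_{v}"
        while attachment in augmented.graph:
            attachment += "_"
        augmented.subdivide_arc(arc.id, attachment)
        leaf = f"leaf_x_{v}"
        while leaf in augmented.graph:
            leaf += "_"
        augmented.add_vertex(leaf, label)
        augmented.add_arc(attachment, leaf)
    return augmented
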