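"""Independent brute-force oracles used to cross-check the implementation.

Each oracle works straight from the definitions (exhaustive search over
subsets or assignments) and shares no code path with the algorithms it
checks.
"""

from itertools import combinations, product

from treebasenet.network_core import PhyloNetwork, s1_arcs


def count_admissible_subsets(net: PhyloNetwork) -> int:
    """Count arc subsets S >= S1 satisfying (C1)/(C2), by exhaustion.

    Only arcs outside S1 vary, so the search space is 2^(|A| - |S1|).
    """
    forced = s1_arcs(net)
    free = [a for a in net.arc_ids() if a not in forced]
    count = 0
    for bits in product((False, True), repeat=len(free)):
        S = set(forced)
        S.update(a for a, keep in zip(free, bits) if keep)
        ok = True
        for v in net.vertices():
            if net.in_degree(v) == 2:
                if sum(a.id in S for a in net.in_arcs(v)) != 1:
                    ok = False
                    break
            if net.out_degree(v) == 2:
                if not any(a.id in S for a in net.out_arcs(v)):
                    ok = False
                    break
        count += ok
    return count


def brute_force_tree_based(net: PhyloNetwork) -> bool:
    return count_admissible_subsets(net) > 0


def brute_force_max_antichain_size(net: PhyloNetwork) -> int:
    """Largest antichain over all vertices, by bitmask enumeration."""
    import networkx as nx

    vertices = net.vertices()
    index = {v: i for i, v in enumerate(vertices)}
    comparable = [0] * len(vertices)
    g = net.simple_digraph()
    for v in vertices:
        below = nx.descendants(g, v)
        for u in below:
            comparable[index[v]] |= 1 << index[u]
            comparable[index[u]] |= 1 << index[v]
    best = 0
    for mask in range(1 << len(vertices)):
        if mask.bit_count() <= best:
            continue
        ok = True
        probe = mask
        while probe:
            low = probe & -probe
            i = low.bit_length() - 1
            if comparable[i] & mask:
                ok = False
                break
            probe ^= low
        if ok:
            best = mask.bit_count()
    return best


def brute_force_sat(variables, clauses) -> bool:
    """Exhaustive 2-SAT satisfiability over <= ~15 variables."""
    variables = list(variables)
    for bits in product((False, True), repeat=len(variables)):
        assignment = dict(zip(variables, bits))
        if all(
            any(assignment[var] == pol for var, pol in clause) for clause in clauses
        ):
            return True
    return False


def brute_force_strong_ordering_exists(net: PhyloNetwork, support) -> bool:
    """Search integer time maps t: V -> {0..|V|} satisfying the strong
    conditions, assigning one vertex at a time with early pruning."""
    vertices = net.vertices()
    limit = len(vertices) + 1
    strict = []  # (u, v): t[u] < t[v]
    equal = []  # (u, v): t[u] == t[v]
    for aid in sorted(support.S):
        arc = net.arc(aid)
        strict.append((arc.source, arc.target))
    for aid in sorted(support.linking_arcs):
        arc = net.arc(aid)
        equal.append((arc.source, arc.target))

    def consistent(times) -> bool:
        for u, v in strict:
            if u in times and v in times and not times[u] < times[v]:
                return False
        for u, v in equal:
            if u in times and v in times and times[u] != times[v]:
                return False
        return True

    def assign(idx, times) -> bool:
        if idx == len(vertices):
            return True
        v = vertices[idx]
        for value in range(limit):
            times[v] = value
            if consistent(times) and assign(idx + 1, times):
                return True
        del times[v]
        return False

    return assign(0, {})


def all_pairs(items):
    return combinations(items, 2)
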