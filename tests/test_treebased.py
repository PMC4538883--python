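"""Propagation, 2-SAT, support/base-tree enumeration, based-on vs displays."""

import pytest
from _oracles import brute_force_sat, count_admissible_subsets

from treebasenet.generators import fixture, random_base_tree
from treebasenet.network_core import parse_network, same_network
from treebasenet.treebased import (
    Conflict,
    TwoSatInstance,
    base_tree,
    base_trees,
    build_2sat,
    displayed_trees,
    enumerate_support_trees,
    initial_labeling,
    is_based_on,
    is_tree_based,
    propagate_labels,
    solve_2sat,
    support_tree_violations,
)


class TestInitialLabeling:
    def test_tree_fully_labeled_true(self):
        tree = random_base_tree(5, 3)
        labeling = initial_labeling(tree)
        assert labeling.true_arcs() == set(tree.arc_ids())

    def test_wheat_leaves_six_arcs_open(self, wheat):
        assert len(initial_labeling(wheat).unassigned()) == 6

    def test_parallel_pair_open(self):
        net = fixture("parallel")
        labeling = initial_labeling(net)
        assert len(labeling.unassigned()) == 2
        assert all(net.arc(a).target == "w" for a in labeling.unassigned())


class TestPropagation:
    def test_fig3_conflicts_at_an_out_arc_of_v(self):
        net = fixture("fig3")
        outcome = propagate_labels(net, initial_labeling(net))
        assert isinstance(outcome, Conflict)
        assert net.arc(outcome.arc).source == "v"
        assert outcome.existing != outcome.attempted

    def test_wheat_does_not_extend(self, wheat):
        outcome = propagate_labels(wheat, initial_labeling(wheat))
        assert not isinstance(outcome, Conflict)
        assert len(outcome.unassigned()) == 6

    def test_tree_fixpoint_is_identity(self):
        tree = random_base_tree(4, 9)
        labeling = initial_labeling(tree)
        outcome = propagate_labels(tree, labeling)
        assert outcome.labels == labeling.labels

    def test_confluence_under_random_orders(self, valid_fixture_networks):
        """The fixpoint (or the fact of conflict) is order-independent."""
        for net in valid_fixture_networks.values():
            reference = propagate_labels(net, initial_labeling(net))
            for seed in range(20):
                shuffled = propagate_labels(net, initial_labeling(net), rng_seed=seed)
                if isinstance(reference, Conflict):
                    assert isinstance(shuffled, Conflict)
                else:
                    assert not isinstance(shuffled, Conflict)
                    assert shuffled.labels == reference.labels


class TestTwoSat:
    def test_tree_instance_is_all_units(self):
        tree = random_base_tree(4, 1)
        inst = build_2sat(tree)
        units = [c for c in inst.clauses if len(c) == 1]
        assert {c[0][0] for c in units} == set(tree.arc_ids())
        assert all(len(c) == 2 for c in inst.clauses if c not in units)

    def test_parallel_network_has_two_solutions(self):
        net = fixture("parallel")
        assert count_admissible_subsets(net) == 2
        assert solve_2sat(build_2sat(net)) is not None

    def test_fig2i_unsatisfiable(self):
        assert solve_2sat(build_2sat(fixture("fig2i"))) is None

    def test_unit_propagation_example(self):
        inst = TwoSatInstance(("x", "y"), ((("x", True),), (("x", False), ("y", True))))
        assignment = solve_2sat(inst)
        assert assignment == {"x": True, "y": True}

    def test_contradictory_units_unsat(self):
        inst = TwoSatInstance(("x",), ((("x", True),), (("x", False),)))
        assert solve_2sat(inst) is None

    def test_court_case_instance(self):
        """(Peter or Susan), (John or not Peter), (not John or not Susan)."""
        clauses = (
            (("peter", True), ("susan", True)),
            (("john", True), ("peter", False)),
            (("john", False), ("susan", False)),
        )
        assignment = solve_2sat(TwoSatInstance(("john", "peter", "susan"), clauses))
        assert assignment is not None
        assert all(
            any(assignment[var] == pol for var, pol in clause) for clause in clauses
        )

    def test_malformed_clause_rejected(self):
        with pytest.raises(ValueError):
            solve_2sat(TwoSatInstance(("x",), ((("x", True), ("x", True), ("x", True)),)))

    def test_agrees_with_exhaustive_search_on_random_instances(self):
        """SCC decision vs exhaustive assignment search, <= 12 variables."""
        import random

        rng = random.Random(20)
        for trial in range(60):
            nvars = rng.randint(1, 12)
            variables = tuple(f"x{i}" for i in range(nvars))
            clauses = tuple(
                tuple(
                    (rng.choice(variables), rng.random() < 0.5)
                    for _ in range(rng.randint(1, 2))
                )
                for _ in range(rng.randint(1, 3 * nvars))
            )
            inst = TwoSatInstance(variables, clauses)
            assert (solve_2sat(inst) is not None) == brute_force_sat(
                variables, clauses
            ), f"trial {trial}"
        # Returned assignments must actually satisfy their instances.
        inst = build_2sat(fixture("fig4_wheat"))
        assignment = solve_2sat(inst)
        assert all(
            any(assignment[var] == pol for var, pol in clause)
            for clause in inst.clauses
        )


class TestIsTreeBased:
    @pytest.mark.parametrize(
        "name,expected",
        [("fig2iii", True), ("fig3", False), ("fig4_wheat", True), ("fig2i", False)],
    )
    def test_fixture_verdicts(self, name, expected):
        net = fixture(name)
        assert is_tree_based(net, "2sat") is expected
        assert is_tree_based(net, "propagate") is expected

    def test_trees_are_tree_based(self):
        assert is_tree_based(random_base_tree(7, 2))

    def test_methods_agree_on_samples(self, samples_100):
        for net in samples_100:
            assert is_tree_based(net, "2sat") == is_tree_based(net, "propagate")


class TestEnumeration:
    def test_wheat_has_eight_support_trees(self, wheat):
        supports = enumerate_support_trees(wheat, 64)
        assert len(supports) == 8
        assert not supports.truncated
        for st in supports:
            assert support_tree_violations(wheat, st) == []

    def test_parallel_has_two(self):
        assert len(enumerate_support_trees(fixture("parallel"), 8)) == 2

    def test_not_tree_based_gives_empty(self):
        assert enumerate_support_trees(fixture("fig2i"), 8) == []

    def test_limit_truncates_with_flag(self, wheat):
        supports = enumerate_support_trees(wheat, 3)
        assert len(supports) == 3
        assert supports.truncated
        with pytest.raises(ValueError):
            enumerate_support_trees(wheat, 0)

    def test_count_matches_exhaustive_and_respects_ceiling(self, samples_100):
        """Bijection: enumerated support trees == admissible subsets <= 2^k."""
        for net in samples_100:
            count = len(enumerate_support_trees(net, 2048))
            assert count == count_admissible_subsets(net)
            assert count <= 2 ** net.reticulation_count

    def test_enumerated_sets_satisfy_invariants(self, samples_100):
        for net in samples_100[:40]:
            for st in enumerate_support_trees(net, 64):
                assert support_tree_violations(net, st) == []


class TestBaseTrees:
    def test_tree_is_its_own_base(self):
        tree = random_base_tree(5, 11)
        assert same_network(base_tree(tree, set(tree.arc_ids())), tree)
        bases = base_trees(tree, 8)
        assert len(bases) == 1 and same_network(bases[0], tree)

    def test_parallel_supports_share_one_base(self):
        net = fixture("parallel")
        trees = [base_tree(net, st) for st in enumerate_support_trees(net, 8)]
        assert same_network(trees[0], trees[1])
        assert trees[0].leaf_labels() == ["a"]

    def test_wheat_bases_pairwise_distinct(self, wheat):
        trees = [base_tree(wheat, st) for st in enumerate_support_trees(wheat, 64)]
        assert len(trees) == 8
        for i in range(8):
            for j in range(i + 1, 8):
                assert not same_network(trees[i], trees[j])

    def test_fig1_based_on_all_three_triples(self, triples):
        bases = base_trees(fixture("fig1"), 64)
        assert len(bases) == 3
        for tree in triples.values():
            assert any(same_network(tree, b) for b in bases)

    def test_non_admissible_set_rejected(self, wheat):
        with pytest.raises(ValueError):
            base_tree(wheat, set())


class TestBasedOnAndDisplays:
    def test_fig5_caption_claims(self, triples):
        net = fixture("fig5")
        assert is_based_on(net, triples["ab|c"]) is True
        assert is_based_on(net, triples["bc|a"]) is False
        displayed = displayed_trees(net, 64)
        assert any(same_network(triples["bc|a"], t) for t in displayed)
        assert any(same_network(triples["ab|c"], t) for t in displayed)

    def test_tree_based_on_and_displays_itself(self):
        tree = random_base_tree(4, 17)
        assert is_based_on(tree, tree) is True
        displayed = displayed_trees(tree, 8)
        assert len(displayed) == 1 and same_network(displayed[0], tree)

    def test_leaf_set_mismatch_rejected(self, wheat, triples):
        with pytest.raises(ValueError):
            is_based_on(wheat, triples["ab|c"])

    def test_truncated_search_reports_unknown(self, wheat):
        caterpillar = parse_network("((((a,b),c),d),e);", "newick")
        assert is_based_on(wheat, caterpillar, limit=64) is False
        assert is_based_on(wheat, caterpillar, limit=3) == "unknown"

    def test_bases_subset_of_displayed_on_samples(self, samples_100):
        for net in samples_100[:60]:
            displayed = displayed_trees(net, 256)
            for base in base_trees(net, 256):
                assert any(same_network(base, d) for d in displayed)

    def test_generated_networks_remember_their_base_tree(self, linked_samples):
        for tree, net in linked_samples:
            assert is_tree_based(net)
            assert any(same_network(tree, b) for b in base_trees(net, 256))
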