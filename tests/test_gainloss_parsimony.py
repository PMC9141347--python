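import itertools
import random

import pytest

from tecurate.fixtures import load_coccidian_instance, load_piroplasmid_instance
from tecurate.gainloss_parsimony import (
    dollo_scenario,
    enumerate_scenarios,
    replay_scenario,
    sankoff_min_cost,
)
from tecurate.io_formats import read_newick
from tecurate.tree import RootedTree, TreeNode


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate all 2^k internal labelings
# ---------------------------------------------------------------------------

def brute_force(tree: RootedTree, tip_states, gain_cost=1.0, loss_cost=1.0):
    internals = tree.internal_nodes
    best = None
    scenarios = set()
    for states in itertools.product((0, 1), repeat=len(internals)):
        labeling = {id(n): s for n, s in zip(internals, states)}
        for leaf in tree.leaves:
            labeling[id(leaf)] = 1 if tip_states[leaf.name] else 0
        gains, losses = set(), set()

        def walk(node, parent_state):
            s = labeling[id(node)]
            name = f"stem:{node.name}" if node is tree.root else node.name
            if s and not parent_state:
                gains.add(name)
            if parent_state and not s:
                losses.add(name)
            for child in node.children:
                walk(child, s)

        walk(tree.root, 0)
        cost = gain_cost * len(gains) + loss_cost * len(losses)
        if best is None or cost < best:
            best = cost
            scenarios = {(frozenset(gains), frozenset(losses))}
        elif cost == best:
            scenarios.add((frozenset(gains), frozenset(losses)))
    return best, scenarios


def random_tree(rng: random.Random, n_leaves: int) -> RootedTree:
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        parent = TreeNode(name="")
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return RootedTree(nodes[0])


class TestSankoffMinCost:
    def test_all_absent_zero(self):
        tree = read_newick("((A,B),C);")
        assert sankoff_min_cost(tree, {"A": False, "B": False, "C": False}) == 0

    def test_piroplasmid_cost_three(self):
        tree, states = load_piroplasmid_instance()
        assert sankoff_min_cost(tree, states) == 3

    def test_coccidian_cost_two(self):
        tree, states = load_coccidian_instance()
        assert sankoff_min_cost(tree, states) == 2

    def test_missing_leaf_state_error(self):
        tree = read_newick("((A,B),C);")
        with pytest.raises(ValueError, match="without a state"):
            sankoff_min_cost(tree, {"A": True})

    def test_asymmetric_costs(self):
        tree, states = load_piroplasmid_instance()
        # expensive gains force the single-gain scenario: 1 gain + 2 losses
        assert sankoff_min_cost(tree, states, gain_cost=10, loss_cost=1) == 12
        # expensive losses force the gains-only scenario: 3 gains
        assert sankoff_min_cost(tree, states, gain_cost=1, loss_cost=10) == 3


class TestEnumerateScenarios:
    def test_piroplasmid_scenarios(self):
        tree, states = load_piroplasmid_instance()
        scenarios = enumerate_scenarios(tree, states)
        assert all(s.cost == 3 for s in scenarios)
        signatures = sorted(s.signature() for s in scenarios)
        # the two published scenarios are among the optima ...
        assert (1, 2) in signatures and (2, 1) in signatures
        one_gain = next(s for s in scenarios if s.signature() == (1, 2))
        assert one_gain.loss_edges == frozenset({"B_bovis", tree.mrca({"C_felis", "T_parva"}).name})
        two_gain = next(s for s in scenarios if s.signature() == (2, 1))
        assert "T_equi" in two_gain.gain_edges
        assert two_gain.loss_edges == frozenset({"B_bovis"})
        # ... plus the equally parsimonious three-independent-gains scenario
        assert signatures == [(1, 2), (2, 1), (3, 0)]

    def test_coccidian_exactly_two_scenarios(self):
        tree, states = load_coccidian_instance()
        scenarios = enumerate_scenarios(tree, states)
        assert len(scenarios) == 2
        assert sorted(s.signature() for s in scenarios) == [(1, 1), (2, 0)]

    def test_star_tree_single_stem_gain(self):
        root = TreeNode("")
        for name in ("A", "B", "C"):
            root.add_child(TreeNode(name))
        tree = RootedTree(root)
        scenarios = enumerate_scenarios(tree, {"A": True, "B": True, "C": True})
        assert len(scenarios) == 1
        assert scenarios[0].n_gains == 1 and scenarios[0].n_losses == 0
        assert next(iter(scenarios[0].gain_edges)).startswith("stem:")

    def test_replay_reproduces_tips_every_scenario(self):
        for loader in (load_piroplasmid_instance, load_coccidian_instance):
            tree, states = loader()
            for scenario in enumerate_scenarios(tree, states):
                assert replay_scenario(tree, scenario) == states

    def test_minimum_matches_sankoff(self):
        tree, states = load_piroplasmid_instance()
        scenarios = enumerate_scenarios(tree, states)
        assert min(s.cost for s in scenarios) == sankoff_min_cost(tree, states)

    def test_oracle_agreement_100_random_trees(self):
        rng = random.Random(123)
        for trial in range(100):
            n_leaves = rng.randint(3, 13)  # <= 12 internal nodes
            tree = random_tree(rng, n_leaves)
            states = {leaf: rng.random() < 0.5 for leaf in tree.leaf_labels}
            best, oracle_scenarios = brute_force(tree, states)
            assert sankoff_min_cost(tree, states) == best, trial
            got = {(s.gain_edges, s.loss_edges) for s in enumerate_scenarios(tree, states)}
            assert got == oracle_scenarios, trial

    def test_theileria_clade_resolution_invariance(self):
        # internal order inside the all-absent Theileria clade cannot change
        # the scenario count
        alt1 = ("((((B_ovata,B_bigemina),B_bovis),B_divergens),"
                "(T_equi,(C_felis,(T_orientalis,(T_parva,T_annulata)))));")
        alt2 = ("((((B_ovata,B_bigemina),B_bovis),B_divergens),"
                "(T_equi,(C_felis,((T_orientalis,T_parva),T_annulata))));")
        states = {
            "B_ovata": True, "B_bigemina": True, "B_bovis": False,
            "B_divergens": True, "T_equi": True, "C_felis": False,
            "T_orientalis": False, "T_parva": False, "T_annulata": False,
        }
        counts = []
        for nwk in (alt1, alt2):
            tree = read_newick(nwk)
            scenarios = enumerate_scenarios(tree, states)
            counts.append(sorted(s.signature() for s in scenarios))
        assert counts[0] == counts[1]


class TestDolloScenario:
    def test_piroplasmid_one_gain_two_losses(self):
        tree, states = load_piroplasmid_instance()
        d = dollo_scenario(tree, states)
        assert d.n_gains == 1 and d.n_losses == 2
        assert d.cost == sankoff_min_cost(tree, states)  # equality here
        assert replay_scenario(tree, d) == states

    def test_single_present_tip(self):
        tree = read_newick("((A,B),C);")
        d = dollo_scenario(tree, {"A": True, "B": False, "C": False})
        assert d.gain_edges == frozenset({"A"}) and d.n_losses == 0

    def test_all_present_stem_gain(self):
        tree = read_newick("((A,B),C);")
        d = dollo_scenario(tree, {"A": True, "B": True, "C": True})
        assert d.n_gains == 1 and d.n_losses == 0
        assert next(iter(d.gain_edges)).startswith("stem:")

    def test_no_present_tips_error(self):
        tree = read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            dollo_scenario(tree, {"A": False, "B": False, "C": False})

    def test_dollo_never_beats_sankoff(self):
        rng = random.Random(9)
        for _ in range(50):
            tree = random_tree(rng, rng.randint(3, 10))
            states = {leaf: rng.random() < 0.5 for leaf in tree.leaf_labels}
            if not any(states.values()):
                continue
            assert dollo_scenario(tree, states).cost >= sankoff_min_cost(tree, states)
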