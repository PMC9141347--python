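"""Minimum gain/loss reconstruction of presence/absence characters on a
rooted tree, with complete enumeration of optimal scenarios.

The stem (ancestral) state is fixed to absent: every presence must be
explained by at least one gain somewhere on the tree, the stem edge above
the root being a legal gain location.  Edges are named by their child node;
the stem edge is named ``stem:<root name>``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .tree import RootedTree, TreeNode

ABSENT, PRESENT = 0, 1
_INF = float("inf")


@dataclass(frozen=True)
class GainLossScenario:
    gain_edges: frozenset[str]
    loss_edges: frozenset[str]
    cost: float

    @property
    def n_gains(self) -> int:
        return len(self.gain_edges)

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)

    def signature(self) -> tuple[int, int]:
        return (self.n_gains, self.n_losses)


def _edge_name(node: TreeNode, root: TreeNode) -> str:
    return f"stem:{node.name}" if node is root else node.name


def _check_states(tree: RootedTree, tip_states: Mapping[str, bool]) -> None:
    missing = [n.name for n in tree.leaves if n.name not in tip_states]
    if missing:
        raise ValueError(f"leaves without a state: {missing}")


def _transition_cost(gain_cost: float, loss_cost: float):
    # cost[parent_state][child_state]
    return (
        (0.0, gain_cost),
        (loss_cost, 0.0),
    )


def _down_pass(
    tree: RootedTree,
    tip_states: Mapping[str, bool],
    gain_cost: float,
    loss_cost: float,
) -> dict[int, tuple[float, float]]:
    """Sankoff leaf-to-root pass: per node, cost of its subtree given that
    the node is (absent, present)."""
    cost: dict[int, tuple[float, float]] = {}
    trans = _transition_cost(gain_cost, loss_cost)
    for node in tree.postorder():
        if node.is_leaf:
            present = bool(tip_states[node.name])
            cost[id(node)] = (_INF, 0.0) if present else (0.0, _INF)
        else:
            totals = []
            for state in (ABSENT, PRESENT):
                total = 0.0
                for child in node.children:
                    c = cost[id(child)]
                    total += min(
                        trans[state][ABSENT] + c[ABSENT],
                        trans[state][PRESENT] + c[PRESENT],
                    )
                totals.append(total)
            cost[id(node)] = (totals[0], totals[1])
    return cost


def sankoff_min_cost(
    tree: RootedTree,
    tip_states: Mapping[str, bool],
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> float:
    """Minimal total weighted event count, stem state fixed to absent."""
    _check_states(tree, tip_states)
    cost = _down_pass(tree, tip_states, gain_cost, loss_cost)
    root_cost = cost[id(tree.root)]
    return min(root_cost[ABSENT], gain_cost + root_cost[PRESENT])


def enumerate_scenarios(
    tree: RootedTree,
    tip_states: Mapping[str, bool],
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> list[GainLossScenario]:
    """All minimum-cost scenarios, deduplicated by their event-edge sets and
    sorted by (number of gains, lexicographic edge names).

    Internal-state labelings that map to the same (gains, losses) pair are
    collapsed into one scenario.
    """
    _check_states(tree, tip_states)
    cost = _down_pass(tree, tip_states, gain_cost, loss_cost)
    trans = _transition_cost(gain_cost, loss_cost)
    root = tree.root
    root_cost = cost[id(root)]
    best = min(root_cost[ABSENT], gain_cost + root_cost[PRESENT])

    scenarios: set[tuple[frozenset[str], frozenset[str]]] = set()

    # Walk optimal labelings with an explicit worklist of (node, state)
    # pairs, branching on ties and accumulating event edges.
    def walk(assignments: list[tuple[TreeNode, int]], gains: frozenset[str], losses: frozenset[str]) -> None:
        if not assignments:
            scenarios.add((gains, losses))
            return
        node, state = assignments[0]
        rest = assignments[1:]
        if node.is_leaf:
            walk(rest, gains, losses)
            return
        options_per_child = []
        for child in node.children:
            c = cost[id(child)]
            total = min(
                trans[state][ABSENT] + c[ABSENT],
                trans[state][PRESENT] + c[PRESENT],
            )
            opts = [
                s
                for s in (ABSENT, PRESENT)
                if trans[state][s] + c[s] == total
            ]
            options_per_child.append((child, opts))

        def product(idx: int, acc: list[tuple[TreeNode, int]], g: frozenset[str], l: frozenset[str]) -> None:
            if idx == len(options_per_child):
                walk(rest + acc, g, l)
                return
            child, opts = options_per_child[idx]
            name = _edge_name(child, root)
            for s in opts:
                g2, l2 = g, l
                if s == PRESENT and state == ABSENT:
                    g2 = g2 | {name}
                elif s == ABSENT and state == PRESENT:
                    l2 = l2 | {name}
                product(idx + 1, acc + [(child, s)], g2, l2)

        product(0, [], gains, losses)

    for root_state in (ABSENT, PRESENT):
        entry = (gain_cost if root_state == PRESENT else 0.0) + root_cost[root_state]
        if entry == best:
            gains = frozenset({_edge_name(root, root)} if root_state == PRESENT else set())
            walk([(root, root_state)], gains, frozenset())

    result = [
        GainLossScenario(g, l, gain_cost * len(g) + loss_cost * len(l))
        for g, l in scenarios
    ]
    result.sort(key=lambda s: (s.n_gains, tuple(sorted(s.gain_edges)), tuple(sorted(s.loss_edges))))
    return result


def dollo_scenario(
    tree: RootedTree, tip_states: Mapping[str, bool]
) -> GainLossScenario:
    """Single-gain scenario: one gain above the MRCA of present tips, plus
    the minimal losses explaining absent tips below it."""
    _check_states(tree, tip_states)
    present = {name for name, state in tip_states.items() if state}
    if not present:
        raise ValueError("dollo scenario requires at least one present tip")
    mrca = tree.mrca(present)
    gain_edge = _edge_name(mrca, tree.root)

    # any maximal subtree below the MRCA containing no present tip loses once
    has_present: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            has_present[id(node)] = node.name in present
        else:
            has_present[id(node)] = any(has_present[id(c)] for c in node.children)

    losses: set[str] = set()

    def place_losses(node: TreeNode) -> None:
        for child in node.children:
            if not has_present[id(child)]:
                losses.add(_edge_name(child, tree.root))
            else:
                place_losses(child)

    place_losses(mrca)
    return GainLossScenario(
        gain_edges=frozenset({gain_edge}),
        loss_edges=frozenset(losses),
        cost=1.0 + len(losses),
    )


def replay_scenario(
    tree: RootedTree, scenario: GainLossScenario
) -> dict[str, bool]:
    """Apply a scenario's events from a stem state of absent and return the
    resulting tip states (for validation)."""
    states: dict[str, bool] = {}

    def walk(node: TreeNode, state: bool) -> None:
        name = _edge_name(node, tree.root)
        if name in scenario.gain_edges and name in scenario.loss_edges:
            raise ValueError(f"edge {name} carries both a gain and a loss")
        if name in scenario.gain_edges:
            state = True
        elif name in scenario.loss_edges:
            state = False
        if node.is_leaf:
            states[node.name] = state
        for child in node.children:
            walk(child, state)

    walk(tree.root, False)
    return states
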