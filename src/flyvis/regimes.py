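"""Maximum-parsimony mapping of the binary host-finding regime onto a tree.

Small-parsimony (Fitch/Sankoff) dynamic programming gives the minimal number
of regime changes; backtracking over all optimal choices enumerates every
most-parsimonious ancestral labeling.  Each labeling is converted to a
*regime painting*: every branch carries the regime of its child node (the
convention expected by the Hansen-model weight matrix), and the root's own
state supplies the root term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io_fixtures import RegimeAssignment
from .trees import UltrametricTree

_INF = float("inf")


@dataclass(frozen=True)
class RegimePainting:
    """One assignment of a regime to every branch (keyed by child node)."""

    branch_regime: dict[int, str]
    root_regime: str
    n_changes: int
    reconstruction_index: int = 0
    node_state: dict[int, str] = field(default_factory=dict, repr=False)

    @property
    def regimes(self) -> list[str]:
        return sorted(set(self.branch_regime.values()) | {self.root_regime})

    def regime_of(self, node: int) -> str:
        return self.root_regime if node == 0 else self.branch_regime[node]


def _tip_states(tree: UltrametricTree, states) -> dict[int, str]:
    if isinstance(states, RegimeAssignment):
        mapping = states.regime
    else:
        mapping = dict(states)
    out = {}
    for node in tree.tip_indices:
        label = tree.labels[node]
        if label not in mapping:
            raise ValueError(f"tip {label!r} has no regime state")
        out[int(node)] = str(mapping[label])
    return out


def _sankoff_costs(
    tree: UltrametricTree, tip_state: dict[int, str], alphabet: list[str]
) -> np.ndarray:
    """cost[node, s] = minimal changes in the subtree given node has state s."""
    k = len(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    cost = np.zeros((tree.n_nodes, k))
    for node in tree.postorder():
        if not tree.children[node]:
            cost[node] = _INF
            cost[node, idx[tip_state[node]]] = 0.0
        else:
            for s in range(k):
                total = 0.0
                for child in tree.children[node]:
                    total += min(
                        cost[child, t] + (1.0 if t != s else 0.0) for t in range(k)
                    )
                cost[node, s] = total
    return cost


def fitch_score(tree: UltrametricTree, states) -> int:
    """Minimal number of regime changes on the tree (small parsimony)."""
    tip_state = _tip_states(tree, states)
    alphabet = sorted(set(tip_state.values()))
    cost = _sankoff_costs(tree, tip_state, alphabet)
    return int(cost[0].min())


def enumerate_mp_reconstructions(tree: UltrametricTree, states) -> list[RegimePainting]:
    """All ancestral labelings achieving the parsimony minimum.

    Ordered lexicographically by (node index, state string), so the
    ``reconstruction_index`` of each painting is stable across runs.
    """
    tip_state = _tip_states(tree, states)
    alphabet = sorted(set(tip_state.values()))
    cost = _sankoff_costs(tree, tip_state, alphabet)
    best = cost[0].min()

    def expand(node: int, s: int) -> list[dict[int, int]]:
        """All optimal labelings of the subtree at ``node`` given state s."""
        if not tree.children[node]:
            return [{node: s}]
        per_child = []
        for child in tree.children[node]:
            options = []
            child_min = min(
                cost[child, t] + (1.0 if t != s else 0.0)
                for t in range(len(alphabet))
            )
            for t in range(len(alphabet)):
                if cost[child, t] + (1.0 if t != s else 0.0) == child_min:
                    options.extend(expand(child, t))
            per_child.append(options)
        out = []
        for combo in itertools.product(*per_child):
            merged = {node: s}
            for part in combo:
                merged.update(part)
            out.append(merged)
        return out

    labelings: list[dict[int, int]] = []
    for s in range(len(alphabet)):
        if cost[0, s] == best:
            labelings.extend(expand(0, s))

    paintings = []
    for i, labeling in enumerate(labelings):
        node_state = {n: alphabet[s] for n, s in sorted(labeling.items())}
        branch = {n: st for n, st in node_state.items() if n != 0}
        n_changes = sum(
            1
            for n in branch
            if node_state[n] != node_state[int(tree.parent[n])]
        )
        paintings.append(
            RegimePainting(
                branch_regime=branch,
                root_regime=node_state[0],
                n_changes=n_changes,
                reconstruction_index=i,
                node_state=node_state,
            )
        )
    assert all(p.n_changes == int(best) for p in paintings)
    return paintings


def ancestral_state_summary(paintings: list[RegimePainting]) -> dict[int, frozenset]:
    """Per node, the set of states it takes across the given reconstructions."""
    if not paintings:
        raise ValueError("no paintings given")
    nodes = set(paintings[0].node_state)
    out: dict[int, set] = {n: set() for n in nodes}
    for p in paintings:
        for n, s in p.node_state.items():
            out[n].add(s)
    return {n: frozenset(s) for n, s in out.items()}


# ------------------------------------------------------------- serialization
def painting_to_dict(tree: UltrametricTree, painting: RegimePainting) -> dict:
    """JSON-friendly form: branches keyed by the sorted tip set of the clade."""
    branches = []
    for node, regime in sorted(painting.branch_regime.items()):
        tips = [tree.tip_labels[i] for i in tree.clade_tips(node)]
        branches.append({"clade_tips": tips, "regime": regime})
    return {
        "root_regime": painting.root_regime,
        "n_changes": painting.n_changes,
        "reconstruction_index": painting.reconstruction_index,
        "branches": branches,
    }


def painting_from_dict(tree: UltrametricTree, data: dict) -> RegimePainting:
    by_tips = {}
    for node in range(1, tree.n_nodes):
        tips = tuple(sorted(tree.tip_labels[i] for i in tree.clade_tips(node)))
        by_tips[tips] = node
    branch = {}
    node_state = {0: data["root_regime"]}
    for rec in data["branches"]:
        key = tuple(sorted(rec["clade_tips"]))
        if key not in by_tips:
            raise ValueError(f"painting branch {key} does not match any clade of the tree")
    for rec in data["branches"]:
        node = by_tips[tuple(sorted(rec["clade_tips"]))]
        branch[node] = rec["regime"]
        node_state[node] = rec["regime"]
    if set(branch) != set(range(1, tree.n_nodes)):
        raise ValueError("painting does not cover every branch of the tree")
    return RegimePainting(
        branch_regime=branch,
        root_regime=data["root_regime"],
        n_changes=int(data["n_changes"]),
        reconstruction_index=int(data.get("reconstruction_index", 0)),
        node_state=node_state,
    )
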