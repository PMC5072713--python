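"""Fitch small parsimony and most-parsimonious reconstruction enumeration.

Binary presence/absence characters (1 = functional gene, 0 = lost) are
traced on a rooted species tree.  ``fitch_score`` returns the minimal
number of state changes; ``enumerate_mprs`` lists every internal-state
assignment achieving that minimum, converts each to a branch event list
(gain = 0->1, loss = 1->0 along the branch to a child), and labels the
accelerated- and delayed-transformation reconstructions.

ACCTRAN pushes changes as close to the root as possible (favouring
reversals); DELTRAN delays them tipward (favouring parallelisms).  Here
the labels are assigned by ordering the enumerated reconstructions by the
sorted depths of their change branches: the lexicographically smallest
profile is ACCTRAN, the largest DELTRAN.

When the set of optimal root states is ambiguous, the root is fixed by
default to the state of the outgroup — the first leaf of the newick
string — reflecting that the outgroup condition is plesiomorphic; pass
``root_policy="free"`` to enumerate over both root states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import dendropy

INF = float("inf")


@dataclass
class Node:
    name: str
    children: list["Node"] = field(default_factory=list)
    index: int = -1       # preorder index
    depth: int = 0        # edges from root

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """A rooted tree with uniquely labelled leaves."""

    root: Node

    def __post_init__(self) -> None:
        self.nodes: list[Node] = []
        self._preorder(self.root, 0)
        names = [n.name for n in self.nodes if n.is_leaf]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for n in self.nodes:
            if not n.is_leaf and len(n.children) < 2:
                raise ValueError(f"internal node {n.name!r} has fewer than 2 children")

    def _preorder(self, node: Node, depth: int) -> None:
        node.index = len(self.nodes)
        node.depth = depth
        self.nodes.append(node)
        for c in node.children:
            self._preorder(c, depth + 1)

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_leaf]

    @property
    def outgroup(self) -> Node:
        """First leaf in preorder — the outgroup of a ladderised tree."""
        return self.leaves[0]


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a rooted PhyloTree.

    Branch lengths are accepted and ignored.  Unbalanced parentheses raise
    a parse error carrying the offending position; duplicate leaf labels
    raise ``ValueError``.
    """
    if text.count("(") != text.count(")"):
        pos = len(text.rstrip())
        raise ValueError(f"unbalanced parentheses in newick (near offset {pos}): "
                         f"{text.count('(')} '(' vs {text.count(')')} ')'")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"newick parse error: {exc}") from exc

    counter = itertools.count(1)

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        children = [convert(c) for c in dnode.child_nodes()]
        if label is None:
            label = f"N{next(counter)}"
        return Node(name=label.replace(" ", "_"), children=children)

    return PhyloTree(root=convert(dtree.seed_node))


def load_tree(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Scoring (unit-cost Sankoff, equals the Fitch minimum; handles polytomies)
# ---------------------------------------------------------------------------

def _subtree_costs(tree: PhyloTree, character: dict[str, int]) -> dict[int, list[float]]:
    """cost[node][s] = min changes in the subtree if the node has state s."""
    cost: dict[int, list[float]] = {}
    for node in reversed(tree.nodes):  # reverse preorder = children first
        if node.is_leaf:
            if node.name not in character:
                raise ValueError(f"no state for leaf {node.name!r}")
            s = int(character[node.name])
            if s not in (0, 1):
                raise ValueError(f"state for {node.name!r} must be 0 or 1")
            cost[node.index] = [0 if s == st else INF for st in (0, 1)]
        else:
            totals = [0.0, 0.0]
            for st in (0, 1):
                for c in node.children:
                    cc = cost[c.index]
                    totals[st] += min(cc[0] + (st != 0), cc[1] + (st != 1))
            cost[node.index] = totals
    return cost


def fitch_score(tree: PhyloTree, character: dict[str, int]) -> int:
    """Minimum number of state changes of a binary character on the tree."""
    cost = _subtree_costs(tree, character)
    return int(min(cost[tree.root.index]))


# ---------------------------------------------------------------------------
# MPR enumeration
# ---------------------------------------------------------------------------

@dataclass
class Reconstruction:
    """One most-parsimonious internal-state assignment for a character."""

    character: str
    node_states: dict[str, int]               # every node (leaves included)
    events: list[tuple[str, str]]             # (child node name, gain|loss)
    n_changes: int
    labels: tuple[str, ...] = ()              # ACCTRAN / DELTRAN / other-MPR

    @property
    def label(self) -> str:
        return "/".join(self.labels) if self.labels else "other-MPR"


def enumerate_mprs(tree: PhyloTree, character: dict[str, int],
                   name: str = "", root_policy: str = "outgroup") -> list[Reconstruction]:
    """Enumerate all most-parsimonious reconstructions of a binary character.

    ``root_policy="outgroup"`` (default) fixes the root to the outgroup
    leaf's state whenever both root states are equally parsimonious;
    ``"free"`` keeps both.  Each reconstruction carries its branch events
    and an ACCTRAN/DELTRAN label (both labels on the same reconstruction
    when only one MPR exists).
    """
    if root_policy not in ("outgroup", "free"):
        raise ValueError("root_policy must be 'outgroup' or 'free'")
    cost = _subtree_costs(tree, character)
    root_costs = cost[tree.root.index]
    best = min(root_costs)
    root_states = [s for s in (0, 1) if root_costs[s] == best]
    if len(root_states) > 1 and root_policy == "outgroup":
        root_states = [int(character[tree.outgroup.name])]

    assignments: list[dict[int, int]] = []

    def expand(node: Node, state: int, partial: dict[int, int]) -> list[dict[int, int]]:
        """All optimal state maps for the subtree of ``node`` given its state."""
        partial = dict(partial)
        partial[node.index] = state
        results = [partial]
        for child in node.children:
            cc = cost[child.index]
            child_opts = []
            opt = min(cc[0] + (state != 0), cc[1] + (state != 1))
            for cs in (0, 1):
                if cc[cs] + (state != cs) == opt:
                    child_opts.append(cs)
            new_results = []
            for r in results:
                for cs in child_opts:
                    if child.is_leaf:
                        nr = dict(r)
                        nr[child.index] = cs
                        new_results.append(nr)
                    else:
                        new_results.extend(expand(child, cs, r))
            results = new_results
        return results

    for rs in root_states:
        assignments.extend(expand(tree.root, rs, {}))

    by_name = {n.index: n for n in tree.nodes}
    recons = []
    for assign in assignments:
        events = []
        for node in tree.nodes:
            for child in node.children:
                a, b = assign[node.index], assign[child.index]
                if a != b:
                    events.append((child.name, "gain" if b == 1 else "loss"))
        recons.append(Reconstruction(
            character=name,
            node_states={by_name[i].name: s for i, s in assign.items()},
            events=events, n_changes=len(events)))

    expected = fitch_score(tree, character)
    assert all(r.n_changes == expected for r in recons)

    # de-duplicate (distinct root states can reach identical assignments only
    # if enumeration overlapped; keep unique state maps)
    unique: dict[tuple, Reconstruction] = {}
    for r in recons:
        key = tuple(sorted(r.node_states.items()))
        unique[key] = r
    recons = list(unique.values())

    depth_of = {n.name: n.depth for n in tree.nodes}

    def profile(r: Reconstruction):
        depths = tuple(sorted(depth_of[child] for child, _ in r.events))
        branches = tuple(sorted((depth_of[c], c, t) for c, t in r.events))
        return depths, branches

    recons.sort(key=profile)
    for r in recons:
        labels = []
        if r is recons[0]:
            labels.append("ACCTRAN")
        if r is recons[-1]:
            labels.append("DELTRAN")
        r.labels = tuple(labels) if labels else ("other-MPR",)
    return recons
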