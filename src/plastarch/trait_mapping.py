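"""Parsimony mapping of architecture characters on a phylogeny.

A discrete, unordered character (for example "gene at the IR/SSC
junction: ycf1 vs ndhF") is mapped onto a rooted tree by small
parsimony. The count pass is Hartigan's generalisation of Fitch's
algorithm: at each internal node, every state is scored by how many
child state-sets contain it; the node keeps the majority states and the
change count grows by (number of children − majority count). On strictly
bifurcating trees this is exactly Fitch's intersection/union rule; on
polytomies it still yields the true minimum change count, which the
plain intersection/union rule does not (a star with tip states 1,1,0,0
needs two changes, not one).

A synapomorphy test then asks whether a derived state arose exactly once,
on the stem edge of a named clade, with no reversal inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional

import dendropy

State = Hashable


class TraitMappingError(ValueError):
    pass


@dataclass
class ChangeEdge:
    """A state change on the edge into `clade` (the leaf set below it)."""

    clade: frozenset[str]
    from_state: State
    to_state: State


@dataclass
class TraitMapping:
    change_count: int
    state_sets: dict[frozenset[str], frozenset]   # clade leaf-set -> Hartigan set
    assignment: dict[frozenset[str], State]        # one most-parsimonious labelling
    change_edges: list[ChangeEdge]
    tree: dendropy.Tree = field(repr=False, default=None)


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _sort_key(state: State):
    return (str(type(state)), str(state))


def fitch_parsimony(tree: dendropy.Tree,
                    states: Mapping[str, State]) -> TraitMapping:
    """Minimum-change mapping of a character onto a rooted tree.

    `states` maps leaf labels to states; leaves absent from the mapping
    (or mapped to None) are treated as missing and contribute the full
    state set without ever incrementing the count. Unrooted trees are
    processed from dendropy's seed node with a logged note — parsimony
    length is root-invariant so the count is unaffected.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(states) - leaves
    if unknown:
        raise TraitMappingError(
            f"taxa in the character matrix absent from the tree: "
            f"{sorted(unknown)!r}")
    observed = {s for s in states.values() if s is not None}
    if not observed:
        raise TraitMappingError("all states missing")
    scored = [t for t in leaves if states.get(t) is not None]
    if len(scored) < 2:
        raise TraitMappingError("need >= 2 leaves with non-missing states")
    full = frozenset(observed)

    node_set: dict[dendropy.Node, frozenset] = {}
    count = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.taxon.label)
            node_set[node] = frozenset([s]) if s is not None else full
            continue
        children = node.child_nodes()
        votes = {s: sum(1 for c in children if s in node_set[c])
                 for s in observed}
        m = max(votes.values())
        node_set[node] = frozenset(s for s, v in votes.items() if v == m)
        count += len(children) - m

    assignment: dict[dendropy.Node, State] = {}
    change_edges: list[ChangeEdge] = []
    for node in tree.preorder_node_iter():
        sset = node_set[node]
        if node.parent_node is None:
            assignment[node] = min(sset, key=_sort_key)
            continue
        parent_state = assignment[node.parent_node]
        if parent_state in sset:
            assignment[node] = parent_state
        else:
            assignment[node] = min(sset, key=_sort_key)
            change_edges.append(ChangeEdge(clade=_leafset(node),
                                           from_state=parent_state,
                                           to_state=assignment[node]))

    by_clade_sets = {_leafset(n): s for n, s in node_set.items()}
    by_clade_assign = {_leafset(n): s for n, s in assignment.items()}
    return TraitMapping(change_count=count, state_sets=by_clade_sets,
                        assignment=by_clade_assign,
                        change_edges=change_edges, tree=tree)


def test_synapomorphy(mapping: TraitMapping, clade: set[str],
                      derived_state: State) -> bool:
    """True iff the derived state arose exactly once, on the clade's stem,
    with no reversal inside the clade.

    The clade must be monophyletic in the mapped tree (else an error).
    """
    clade = frozenset(clade)
    if clade not in mapping.state_sets:
        raise TraitMappingError(
            f"leaf set {sorted(clade)!r} is not monophyletic in the tree")
    gains = [e for e in mapping.change_edges if e.to_state == derived_state]
    if len(gains) != 1 or gains[0].clade != clade:
        return False
    inside = [e for e in mapping.change_edges
              if e.clade < clade]  # strictly within the clade
    return not inside


def character_matrix_from_shifts(shift_rows: Mapping[str, Mapping[str, bool]],
                                 junction: str) -> dict[str, int]:
    """Extract one junction's boolean shift column as a 0/1 character."""
    return {taxon: int(row[junction]) for taxon, row in shift_rows.items()}
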