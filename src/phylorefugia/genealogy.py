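"""Lightweight rooted genealogies with branch lengths in generations.

The simulators and the sorting-events statistic only need a minimal tree:
children, branch lengths, and a deme label on each tip.  Newick round-trips
go through dendropy so observed genealogies from external tools can be used
directly.
"""

from __future__ import annotations

from typing import Callable, Iterator, Mapping

import dendropy

__all__ = ["Node", "from_newick", "to_newick", "min_sorting_events"]


class Node:
    """A node of a rooted genealogy.

    Parameters
    ----------
    name:
        Tip label (``None`` for internal nodes).
    length:
        Branch length to the parent, in generations.
    deme:
        Deme/population label carried by tips.
    """

    __slots__ = ("name", "length", "deme", "children", "time")

    def __init__(self, name=None, length=0.0, deme=None, children=None, time=0.0):
        self.name = name
        self.length = float(length)
        self.deme = deme
        self.children = list(children) if children else []
        self.time = float(time)

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if not n.children]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self)

    def height(self) -> float:
        """Maximum root-to-tip path length in generations."""
        best = 0.0
        stack = [(self, 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf:
                best = max(best, d)
            for c in node.children:
                stack.append((c, d + c.length))
        return best

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.name or '<internal>'}, tips={self.n_leaves()})"


def _to_dendropy(root: Node) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: Node, dnode):
        dnode.edge.length = node.length
        if node.is_leaf:
            dnode.taxon = taxa.require_taxon(label=str(node.name))
        for child in node.children:
            build(child, dnode.new_child())

    build(root, tree.seed_node)
    return tree


def to_newick(root: Node) -> str:
    return _to_dendropy(root).as_string(schema="newick", suppress_rooting=True).strip()


def from_newick(source: str, deme_of: Mapping[str, str] | None = None) -> Node:
    """Parse a newick string or file path into a :class:`Node` tree.

    ``deme_of`` maps tip names to deme labels; unknown tips keep ``deme=None``.
    """
    text = source
    if "\n" not in source and "(" not in source:
        with open(source) as fh:
            text = fh.read()
    tree = dendropy.Tree.get(data=text, schema="newick")

    def build(dnode) -> Node:
        node = Node(length=dnode.edge.length or 0.0)
        if dnode.is_leaf():
            node.name = dnode.taxon.label if dnode.taxon else None
            if deme_of is not None and node.name is not None:
                node.deme = deme_of.get(node.name)
        node.children = [build(c) for c in dnode.child_nodes()]
        return node

    return build(tree.seed_node)


def min_sorting_events(root: Node, label_of: Callable[[Node], str] | Mapping[str, str] | None = None) -> int:
    """Minimum number of deme-label changes on the tree (Slatkin–Maddison s).

    Computed by Hartigan's generalization of Fitch parsimony for unordered
    states, which is exact on trees of arbitrary degree: at each internal
    node the states held by the maximal number of children are kept, and
    every child not carrying one of those states contributes one change.

    ``label_of`` may be a mapping from tip *name* to state; by default the
    tip's ``deme`` attribute is used.  An unlabeled tip raises ``ValueError``.
    """
    if label_of is None:
        get = lambda n: n.deme
    elif callable(label_of):
        get = label_of
    else:
        get = lambda n: label_of.get(n.name)

    changes = 0
    states: dict[int, frozenset] = {}
    for node in root.postorder():
        if node.is_leaf:
            state = get(node)
            if state is None:
                raise ValueError(f"tip {node.name!r} has no deme label")
            states[id(node)] = frozenset([state])
        else:
            count: dict[str, int] = {}
            for child in node.children:
                for s in states[id(child)]:
                    count[s] = count.get(s, 0) + 1
            kmax = max(count.values())
            keep = frozenset(s for s, c in count.items() if c == kmax)
            changes += len(node.children) - kmax
            states[id(node)] = keep
    return changes
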