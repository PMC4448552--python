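"""Lightweight rooted-tree structure shared by the simulation, inference and
reconstruction stages.

The tree is stored rooted (possibly with a multifurcating root); modules that
treat it as unrooted (likelihood, bipartitions) simply ignore the root
placement. Branch lengths are substitutions/site and must be non-negative;
``support`` holds bootstrap/consensus percentages in [0, 100].
"""

from __future__ import annotations

import io as _io
from typing import Callable, Iterator, Optional

import dendropy


class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        if length is not None and length < 0:
            raise ValueError(f"negative branch length {length!r} on node {name!r}")
        self.name = name
        self.length = length
        self.support = support
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    # -- topology ----------------------------------------------------------
    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, len={self.length}, nchild={len(self.children)})"


class PhyloTree:
    """A rooted phylogenetic tree with unique tip labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [n.name for n in root.postorder() if n.is_leaf]
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if any(n is None for n in names):
            raise ValueError("every tip must be labeled")

    # -- queries -----------------------------------------------------------
    def tip_names(self) -> list[str]:
        return [n.name for n in self.root.postorder() if n.is_leaf]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def find(self, name: str) -> TreeNode:
        for n in self.root.preorder():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.root.preorder())

    def mrca(self, names) -> TreeNode:
        """Most recent common ancestor of the named tips."""
        want = set(names)
        if not want:
            raise ValueError("mrca of an empty tip set")
        tipsets = {}
        best = None
        for node in self.root.postorder():
            s = {node.name} if node.is_leaf else set().union(
                *(tipsets[id(c)] for c in node.children)
            )
            tipsets[id(node)] = s
            if want <= s and best is None:
                best = node
        if best is None:
            missing = want - set(self.tip_names())
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        return best

    def tipset(self, node: TreeNode) -> frozenset:
        return frozenset(n.name for n in node.postorder() if n.is_leaf)

    def depths(self) -> dict:
        """Root-to-node path lengths (missing lengths count as 0)."""
        out = {id(self.root): 0.0}
        for node in self.root.preorder():
            for c in node.children:
                out[id(c)] = out[id(node)] + (c.length or 0.0)
        return out

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.root.preorder() if n.parent is not None)

    # -- editing -----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def rec(n: TreeNode) -> TreeNode:
            m = TreeNode(n.name, n.length, n.support)
            for c in n.children:
                m.add_child(rec(c))
            return m

        return PhyloTree(rec(self.root))

    def suppress_unifurcations(self) -> None:
        """Collapse nodes with a single child, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.root.preorder()):
                if not node.is_leaf and len(node.children) == 1 and node.parent is not None:
                    child = node.children[0]
                    if child.length is not None or node.length is not None:
                        child.length = (child.length or 0.0) + (node.length or 0.0)
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                    changed = True
            if self.root is not None and len(self.root.children) == 1 and not self.root.is_leaf:
                only = self.root.children[0]
                if not only.is_leaf:
                    only.parent = None
                    only.length = None
                    self.root = only
                    changed = True

    # -- serialization -----------------------------------------------------
    def to_newick(self, support_as_label: bool = True, digits: int = 10) -> str:
        def fmt_len(x: Optional[float]) -> str:
            if x is None:
                return ""
            return f":{x:.{digits}g}"

        def rec(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.name}{fmt_len(n.length)}"
            inner = ",".join(rec(c) for c in n.children)
            label = ""
            if support_as_label and n.support is not None:
                label = f"{n.support:g}"
            elif n.name is not None:
                label = n.name
            return f"({inner}){label}{fmt_len(n.length)}"

        return rec(self.root) + ";"


def from_dendropy(dtree: "dendropy.Tree") -> PhyloTree:
    def rec(dn) -> TreeNode:
        label = None
        if dn.taxon is not None:
            label = dn.taxon.label
        elif dn.label is not None:
            label = dn.label
        length = dn.edge.length
        if length is not None and length < 0:
            raise ValueError(f"negative branch length {length} in input tree")
        node = TreeNode(name=label, length=length)
        # internal labels that parse as numbers in [0,100] double as supports
        if label is not None and dn.child_nodes():
            try:
                val = float(label)
            except ValueError:
                pass
            else:
                if 0 <= val <= 100:
                    node.support = val
        for c in dn.child_nodes():
            node.add_child(rec(c))
        return node

    return PhyloTree(rec(dtree.seed_node))


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick tree (dendropy does the lexing/validation)."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    return from_dendropy(dtree)


def parse_newick_list(text: str) -> list[PhyloTree]:
    """Parse a multi-tree Newick file (one tree per line/semicolon)."""
    trees = dendropy.TreeList.get(
        data=text, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return [from_dendropy(t) for t in trees]
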