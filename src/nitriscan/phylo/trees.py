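"""Lightweight phylogenetic trees with newick I/O.

The internal structure is a plain rooted node hierarchy (a trifurcating root
represents an unrooted tree, as produced by neighbor joining).  Branch
lengths are substitutions per site; internal-node supports are bootstrap
percentages in [0, 100].  Newick parsing is delegated to dendropy; writing is
direct string assembly.
"""

from __future__ import annotations

from typing import Iterator

import dendropy


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str = "", length: float = 0.0,
                 support: float | None = None):
        self.name = name
        self.length = length  # length of the edge above this node
        self.support: float | None = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- traversal -------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    # -- copying ---------------------------------------------------------
    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            clone = Node(node.name, node.length, node.support)
            for c in node.children:
                clone.add(rec(c))
            return clone
        return Tree(rec(self.root))

    # -- bipartitions ----------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as canonical leaf-name sets.

        Each internal edge splits the leaves in two; the side *not* containing
        the lexicographically smallest leaf is the canonical representative,
        making the set rooting-invariant.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if node is self.root:
                    continue
                side = s if anchor not in s else all_leaves - s
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(side)
        return out

    def clade_leafsets(self) -> dict[int, frozenset[str]]:
        """id(node) -> leaf names below node."""
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        return below

    # -- rerooting -------------------------------------------------------
    def rerooted_at(self, leaf_name: str) -> "Tree":
        """Return a copy rooted at the edge above the named leaf.

        Used to verify root-invariance of reversible-model likelihoods.
        """
        tree = self.copy()
        target = next(n for n in tree.postorder() if n.is_leaf and n.name == leaf_name)
        path = []
        node = target
        while node is not None:
            path.append(node)
            node = node.parent
        new_root = Node("")
        edge_len = target.length
        new_root.add(target)
        target.length = edge_len / 2.0
        # walk back up the old path, reversing parent links
        prev = new_root
        carry = edge_len / 2.0
        for i in range(1, len(path)):
            old = path[i]
            old.children = [c for c in old.children if c is not path[i - 1]]
            length_above = old.length
            old.length = carry
            prev.add(old)
            carry = length_above
            prev = old
        # the old root may now have a single child; splice it out
        _suppress_unifurcations(new_root)
        return Tree(new_root)

    # -- newick ----------------------------------------------------------
    def to_newick(self, with_supports: bool = True) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(rec(c) for c in node.children)
            label = ""
            if with_supports and node.support is not None:
                label = f"{node.support:.10g}"
            elif node.name:
                label = node.name
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.10g}"
        return rec(self.root) + ";"

    def write(self, path: str, with_supports: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(with_supports=with_supports) + "\n")


def _suppress_unifurcations(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        changed = True
        while changed:
            changed = False
            for i, c in enumerate(node.children):
                if len(c.children) == 1:
                    gc = c.children[0]
                    gc.length += c.length
                    gc.parent = node
                    node.children[i] = gc
                    changed = True
        stack.extend(node.children)


def read_newick(source: str) -> Tree:
    """Parse a newick string (or path ending in .nwk/.tree/.newick).

    Internal-node labels that parse as numbers are taken as bootstrap
    supports.
    """
    if source.strip().endswith(";"):
        dt = dendropy.Tree.get(data=source, schema="newick")
    else:
        with open(source) as fh:
            dt = dendropy.Tree.get(file=fh, schema="newick")
    return _from_dendropy(dt)


def _from_dendropy(dt: dendropy.Tree) -> Tree:
    def rec(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            node = Node(name.replace(" ", "_"),
                        dnode.edge.length or 0.0)
            return node
        node = Node("", dnode.edge.length or 0.0)
        label = dnode.label
        if label is not None:
            try:
                node.support = float(label)
            except ValueError:
                node.name = label
        for c in dnode.child_nodes():
            node.add(rec(c))
        return node
    return Tree(rec(dt.seed_node))
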