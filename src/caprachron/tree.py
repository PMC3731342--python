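"""Lightweight rooted/unrooted tree structure used across the package.

Each non-root node carries the length of the branch above it. Unrooted trees
are represented with a basal trifurcation. Newick parsing and serialization
go through dendropy so that quoting/comment conventions are handled by an
established reader.
"""

from __future__ import annotations

import dendropy

from .errors import UsageError


class Node:
    __slots__ = ("name", "length", "children", "parent", "support", "age")

    def __init__(self, name=None, length=None):
        self.name = name
        self.length = length
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.support: float | None = None
        self.age: float | None = None  # used by chronograms / simulated genealogies

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Tree with branch lengths; the branch above each non-root node."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(dt.seed_node))

    def to_newick(self, support: bool = False, digits: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = node.name or ""
            else:
                label = ""
                if support and node.support is not None:
                    label = f"{node.support:g}"
                elif node.name:
                    label = node.name
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + label
            if node.length is not None:
                core += f":{node.length:.{digits}g}"
            return core

        return fmt(self.root) + ";"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )

    # ------------------------------------------------------------ traversal
    def postorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def preorder(self) -> list[Node]:
        return list(reversed(self.postorder()))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[Node]:
        """Non-root nodes; each identifies the branch above it."""
        return [n for n in self.postorder() if n.parent is not None]

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise UsageError(f"leaf {name!r} not in tree")

    def mrca(self, names) -> Node:
        names = set(names)
        below: dict[Node, set] = {}
        best = None
        for node in self.postorder():
            s = {node.name} if node.is_leaf else set().union(
                *(below[c] for c in node.children)
            )
            below[node] = s
            if names <= s and best is None:
                best = node
        if best is None:
            raise UsageError(f"no MRCA: {names} not all in tree")
        return best

    def clade_leafset(self, node: Node) -> frozenset:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the smaller-side leafset keyed by
        a canonical frozenset (the side not containing the first leaf)."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        parts = set()
        for node in self.branches():
            side = self.clade_leafset(node)
            if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
                continue
            if anchor in side:
                side = all_leaves - side
            parts.add(side)
        return parts

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            new.age = node.age
            for child in node.children:
                new.add(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.branches())

    # ------------------------------------------------------------- rooting
    def suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in self.postorder():
                if node.parent is not None and len(node.children) == 1:
                    child = node.children[0]
                    child.length = (child.length or 0.0) + (node.length or 0.0)
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                    changed = True
            if len(self.root.children) == 1 and not self.root.children[0].is_leaf:
                new_root = self.root.children[0]
                new_root.parent = None
                new_root.length = None
                self.root = new_root
                changed = True

    def root_with_outgroup(self, outgroup_names) -> "PhyloTree":
        """Return a copy rooted at the midpoint of the outgroup stem."""
        tree = self.copy()
        names = set(outgroup_names)
        if not names:
            raise UsageError("empty outgroup")
        leaf_names = set(tree.leaf_names())
        if not names <= leaf_names:
            raise UsageError(f"outgroup leaves missing: {names - leaf_names}")
        # find the node whose clade is exactly the outgroup (either side)
        target = None
        for node in tree.branches():
            side = tree.clade_leafset(node)
            if side == names:
                target = node
                break
            if leaf_names - side == names:
                target = node  # outgroup is on the rootward side; same edge
                break
        if target is None:
            if len(names) == 1:
                target = tree.find_leaf(next(iter(names)))
            else:
                raise UsageError("outgroup is not a bipartition side of this tree")
        # split the edge above `target` with a new root at its midpoint
        old_parent = target.parent
        if old_parent is None:
            raise UsageError("outgroup edge is already the root")
        half = (target.length or 0.0) / 2.0
        old_parent.children.remove(target)
        new_root = Node()
        new_root.add(target)
        target.length = half
        # re-hang the path from old_parent up to the old root
        path = []
        node = old_parent
        while node is not None:
            path.append(node)
            node = node.parent
        new_root.children.append(path[0])
        path[0].parent = new_root
        prev_length = half
        for i, node in enumerate(path):
            upper = path[i + 1] if i + 1 < len(path) else None
            saved_length = node.length
            node.length = prev_length
            if upper is not None:
                upper.children.remove(node)
                node.children.append(upper)
                upper.parent = node
            prev_length = saved_length
        result = PhyloTree(new_root)
        result.suppress_unifurcations()
        return result
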