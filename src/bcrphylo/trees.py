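"""Lineage tree structure: germline-rooted trees with branch lengths in
expected substitutions per codon site.

The germline acts as the known root state, identified by a reserved tip
label (default ``GERMLINE``) in Newick input.  Multifurcations are resolved
deterministically (by child order) into bifurcations with zero-length
edges.  Newick parsing/writing is delegated to dendropy; the in-memory
structure is a light node class so the likelihood engine can traverse it
cheaply.
"""

from __future__ import annotations

import io
from typing import Iterator

import dendropy
import numpy as np

GERMLINE_LABEL = "GERMLINE"


class TreeNode:
    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.label = label
        self.length = length  # length of the edge above this node

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class LineageTree:
    """A rooted lineage tree whose root is the germline node."""

    def __init__(self, root: TreeNode, germline_label: str = GERMLINE_LABEL):
        self.root = root
        self.germline_label = germline_label

    # -- traversal -------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def nonroot_nodes(self) -> list[TreeNode]:
        """Nodes below the root in a fixed (postorder) order; their
        ``length`` attributes form the branch-length vector."""
        return [n for n in self.postorder() if n is not self.root]

    # -- branch lengths --------------------------------------------------
    def branch_lengths(self) -> np.ndarray:
        return np.array([n.length for n in self.nonroot_nodes()])

    def set_branch_lengths(self, lengths) -> None:
        nodes = self.nonroot_nodes()
        if len(lengths) != len(nodes):
            raise ValueError("branch length vector has wrong size")
        for n, t in zip(nodes, lengths):
            if t < 0:
                raise ValueError("branch lengths must be >= 0")
            n.length = float(t)

    def tree_length(self) -> float:
        return float(self.branch_lengths().sum())

    def mean_root_to_tip(self) -> float:
        depths = []
        def _walk(node: TreeNode, d: float) -> None:
            if node.is_tip and node is not self.root:
                depths.append(d)
            for c in node.children:
                _walk(c, d + c.length)
        _walk(self.root, 0.0)
        return float(np.mean(depths)) if depths else 0.0

    def copy(self) -> "LineageTree":
        def _cp(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add_child(_cp(c))
            return new
        return LineageTree(_cp(self.root), self.germline_label)

    # -- shape fixes -----------------------------------------------------
    def resolve_multifurcations(self) -> None:
        """Resolve every polytomy into bifurcations, deterministically by
        child order, inserting zero-length edges."""
        for node in list(self.postorder()):
            while len(node.children) > 2:
                a, b = node.children[0], node.children[1]
                joint = TreeNode(None, 0.0)
                joint.add_child(a)
                joint.add_child(b)
                node.children = [joint] + node.children[2:]
                joint.parent = node

    # -- Newick ----------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, germline_label: str = GERMLINE_LABEL) -> "LineageTree":
        """Parse a Newick string and root the tree at the germline node.

        The germline may appear either as the existing root label or as a
        tip; in the latter case the tree is re-rooted so the germline
        becomes the root and its former pendant edge leads to the rest of
        the tree.
        """
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)

        def _convert(dnode) -> TreeNode:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = TreeNode(label, dnode.edge.length or 0.0)
            for c in dnode.child_nodes():
                node.add_child(_convert(c))
            return node

        root = _convert(dt.seed_node)
        tree = cls(root, germline_label)
        if root.label == germline_label:
            return tree
        germ = next((n for n in tree.postorder() if n.label == germline_label), None)
        if germ is None:
            raise ValueError(f"germline node {germline_label!r} not found in Newick tree")
        if not germ.is_tip:
            raise ValueError("germline label attached to an internal node")
        tree._reroot_at(germ)
        return tree

    def _reroot_at(self, germ: TreeNode) -> None:
        """Make the germline tip the root; its pendant edge becomes the
        edge to the rest of the tree (direction of all edges on the path to
        the old root is reversed)."""
        path = []
        node = germ
        while node is not None:
            path.append(node)
            node = node.parent
        orig_len = [n.length for n in path]
        # reverse parent/child relations along path germ -> old root
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
        for child, parent in zip(path, path[1:]):
            child.add_child(parent)
        for (child, parent), length in zip(zip(path, path[1:]), orig_len):
            parent.length = length
        germ.parent = None
        germ.length = 0.0
        # drop degree-1 pass-through nodes created at the old root
        self.root = germ
        self._suppress_unifurcations()

    def _suppress_unifurcations(self) -> None:
        for node in list(self.postorder()):
            if node is self.root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent

    def to_newick(self) -> str:
        def _fmt(node: TreeNode) -> str:
            if node.is_tip:
                core = node.label or ""
            else:
                core = "(" + ",".join(_fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node is self.root:
                return core
            return f"{core}:{node.length:.10g}"
        return _fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LineageTree({len(self.tips())} tips, length={self.tree_length():.4g})"


def read_trees_tsv(path) -> dict[str, LineageTree]:
    """Read a two-column TSV (clone_id <TAB> newick) of lineage trees."""
    out: dict[str, LineageTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            clone_id, newick = line.split("\t", 1)
            out[clone_id] = LineageTree.from_newick(newick)
    return out


def write_trees_tsv(trees: dict[str, LineageTree], path) -> None:
    with open(path, "w") as fh:
        for clone_id, tree in trees.items():
            fh.write(f"{clone_id}\t{tree.to_newick()}\n")
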