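"""Rooted species trees: Newick I/O, MRCA queries, refinement, compatibility.

An S-tree is a rooted tree whose leaves are bijectively labelled by the
species set and whose internal nodes all have outdegree at least two.  The
framework is purely topological: branch lengths in Newick input are read
and discarded, and trees compare equal up to reordering of children
(canonical form sorts children by their smallest contained species label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import dendropy

from .errors import InvalidRefinementError, ParseError
from .posets import Poset

logger = logging.getLogger(__name__)


class TreeNode:
    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str | None = None):
        self.label = label  # species label on leaves, None on internal nodes
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):
        return f"<TreeNode {self.label or '*'} deg={len(self.children)}>"


class STree:
    """A rooted species tree over an explicit species set."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._leaf_index: dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.is_leaf:
                if node.label is None:
                    raise ParseError("leaf without a label")
                if node.label in self._leaf_index:
                    raise ParseError(f"duplicate leaf label {node.label!r}")
                self._leaf_index[node.label] = node
            elif node is not self.root and len(node.children) < 2:
                raise ParseError("internal node with outdegree < 2")

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._leaf_index)

    def leaf(self, label: str) -> TreeNode:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise KeyError(f"no leaf labelled {label!r}") from None

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def depth(self, node: TreeNode) -> int:
        """Edges from the root (root depth 0, increasing toward leaves)."""
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def copy(self) -> "STree":
        return self.copy_with_map()[0]

    def copy_with_map(self) -> tuple["STree", dict[TreeNode, TreeNode]]:
        mapping: dict[TreeNode, TreeNode] = {}

        def rec(node: TreeNode) -> TreeNode:
            clone = TreeNode(node.label)
            mapping[node] = clone
            for c in node.children:
                clone.add(rec(c))
            return clone

        return STree(rec(self.root)), mapping

    def canonical_newick(self) -> str:
        return write_newick(self)

    def __eq__(self, other):
        if not isinstance(other, STree):
            return NotImplemented
        return self.canonical_newick() == other.canonical_newick()

    def __hash__(self):
        return hash(self.canonical_newick())

    def __repr__(self):
        return f"STree({self.canonical_newick()!r})"


def _collapse_unary(node: TreeNode) -> TreeNode:
    """Remove outdegree-1 chains below (and including) ``node``."""
    node.children = [_collapse_unary(c) for c in node.children]
    for c in node.children:
        c.parent = node
    if len(node.children) == 1:
        logger.info("collapsed outdegree-1 node during parse")
        child = node.children[0]
        child.parent = None
        return child
    return node


def parse_newick(text: str) -> STree:
    """Parse a rooted Newick string into an :class:`STree`.

    Branch lengths and internal labels are accepted and discarded;
    outdegree-1 chains are collapsed with a log notice.  Duplicate leaf
    labels or malformed syntax raise :class:`ParseError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        node = TreeNode()
        if not dnode.child_nodes():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if label is None:
                raise ParseError("leaf without a label")
            node.label = str(label)
        for c in dnode.child_nodes():
            node.add(convert(c))
        return node

    root = _collapse_unary(convert(dtree.seed_node))
    return STree(root)


def _newick_rec(node: TreeNode) -> tuple[str, str]:
    """Return (min species label, newick fragment) with sorted children."""
    if node.is_leaf:
        return node.label, node.label
    parts = sorted(_newick_rec(c) for c in node.children)
    return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"


def write_newick(t: STree) -> str:
    """Canonical Newick: children sorted by smallest contained species label."""
    return _newick_rec(t.root)[1] + ";"


def mrca(t: STree, u: str, v: str) -> TreeNode:
    """Most recent common ancestor of the leaves labelled ``u`` and ``v``."""
    nu, nv = t.leaf(u), t.leaf(v)
    ancestors = set()
    node = nu
    while node is not None:
        ancestors.add(id(node))
        node = node.parent
    node = nv
    while node is not None:
        if id(node) in ancestors:
            return node
        node = node.parent
    raise RuntimeError("disconnected tree")  # unreachable on a valid STree


def species_set(t: STree, u: TreeNode) -> frozenset[str]:
    """Leaf labels of the subtree rooted at ``u``."""
    out = []
    stack = [u]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            out.append(node.label)
        else:
            stack.extend(node.children)
    return frozenset(out)


def refine_step(t: STree, x: TreeNode, group: Iterable[TreeNode]) -> STree:
    """One refinement step: a new node adopts ``group`` among ``x``'s children.

    ``group`` must be a proper subset of the children of ``x`` with at least
    two members, so both ``x`` and the new node keep outdegree >= 2.  The
    input tree is left untouched; a refined copy is returned.
    """
    group = list(group)
    ids = {id(c) for c in x.children}
    if any(id(g) not in ids for g in group):
        raise InvalidRefinementError("group members must be children of x")
    if len({id(g) for g in group}) != len(group):
        raise InvalidRefinementError("group contains duplicates")
    if len(group) < 2:
        raise InvalidRefinementError("a refinement step needs at least two children")
    if len(group) >= len(x.children):
        raise InvalidRefinementError("group must be a proper subset of x's children")
    new_t, m = t.copy_with_map()
    nx_, ngroup = m[x], [m[g] for g in group]
    picked = {id(g) for g in ngroup}
    y = TreeNode()
    y.children = ngroup
    for g in ngroup:
        g.parent = y
    nx_.children = [c for c in nx_.children if id(c) not in picked]
    nx_.add(y)
    return STree(new_t.root)


@dataclass(frozen=True)
class CompatibilityResult:
    compatible: bool
    violation: tuple[str, str, str] | None = None  # (focal, s_j, s_k)

    def __bool__(self) -> bool:
        return self.compatible


def is_compatible(p: Poset, t: STree) -> CompatibilityResult:
    """Does the tree's MRCA structure honour every relation of the poset?

    ``s_j < s_k`` in the poset anchored at ``s_i`` requires the shortest
    path from ``s_i`` (or ``s_j``) to ``s_k`` to pass through
    ``MRCA(s_i, s_j)`` — equivalently, ``MRCA(s_i, s_k)`` must be at most as
    deep as ``MRCA(s_i, s_j)``.  Incomparable species impose no constraint.
    """
    if p.species != t.species:
        raise ValueError(
            f"species mismatch: poset over {sorted(p.species)}, "
            f"tree over {sorted(t.species)}"
        )
    focal = p.focal
    depth_to = {s: t.depth(mrca(t, focal, s)) for s in p.species}
    for s_j, s_k in sorted(p.pairs):
        if depth_to[s_k] > depth_to[s_j]:
            return CompatibilityResult(False, (focal, s_j, s_k))
    return CompatibilityResult(True)
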