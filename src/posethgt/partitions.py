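"""Tree bipartitions: contradiction testing and minimum common refinement.

Cutting any edge of a rooted tree splits the species set into the leaves
below the edge and everything else — a *2-partition*.  Two 2-partitions
contradict when a quadruple of species crosses them (two species together
on each side of one partition but split by the other); two trees contradict
when any pair of their induced 2-partitions does.  Non-contradictory trees
have a unique minimum common refinement whose 2-partition set is the union
of theirs, and a tree is reconstructible from its own 2-partition set.

A reserved label ``s0`` hung under the root keeps the two sides of every
root edge distinguishable when partition sets from different trees are
united.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ContradictionError, LabelCollisionError
from .trees import STree, TreeNode, species_set

AUGMENT_LABEL = "s0"


class TwoPartition:
    """An unordered pair of disjoint species sets covering the species set.

    Canonical form: the sides are ordered by (size, lexicographically
    smallest member), so equal partitions compare and hash equal.
    """

    __slots__ = ("sides",)

    def __init__(self, a: Iterable[str], b: Iterable[str]):
        a, b = frozenset(a), frozenset(b)
        if not a or not b:
            raise ValueError("2-partition sides must be nonempty")
        if a & b:
            raise ValueError(f"2-partition sides overlap: {sorted(a & b)}")
        lo, hi = sorted((a, b), key=lambda s: (len(s), sorted(s)))
        self.sides: tuple[frozenset[str], frozenset[str]] = (lo, hi)

    def sort_key(self):
        return tuple((len(s), tuple(sorted(s))) for s in self.sides)

    def __eq__(self, other):
        if not isinstance(other, TwoPartition):
            return NotImplemented
        return self.sides == other.sides

    def __hash__(self):
        return hash(self.sides)

    def __lt__(self, other):  # deterministic ordering for witness reports
        return self.sort_key() < other.sort_key()

    def __repr__(self):
        return f"TwoPartition({sorted(self.sides[0])}, {sorted(self.sides[1])})"

    @property
    def universe(self) -> frozenset[str]:
        return self.sides[0] | self.sides[1]

    def __str__(self):
        return (
            "{" + ",".join(sorted(self.sides[0]))
            + " | " + ",".join(sorted(self.sides[1])) + "}"
        )


def _augment(t: STree) -> STree:
    if AUGMENT_LABEL in t.species:
        raise LabelCollisionError(
            f"species set already contains the reserved label {AUGMENT_LABEL!r}"
        )
    t2 = t.copy()
    t2.root.add(TreeNode(AUGMENT_LABEL))
    return STree(t2.root)


def find_two_partitions(t: STree, augment: bool = False) -> frozenset[TwoPartition]:
    """The 2-partitions induced by cutting each edge of ``t``.

    With ``augment`` a reserved leaf ``s0`` is first attached under the
    root, so that the partitions of distinct trees over the same species
    never coincide merely because a root edge splits them identically.
    Duplicates (e.g. the two edges of a 2-leaf tree) are removed.
    """
    if augment:
        t = _augment(t)
    full = t.species
    if len(full) < 2:
        return frozenset()
    parts = set()
    for node in t.preorder():
        if node is t.root:
            continue
        below = species_set(t, node)
        parts.add(TwoPartition(below, full - below))
    return frozenset(parts)


def partitions_contradict(x: TwoPartition, y: TwoPartition) -> bool:
    """True iff a species quadruple crosses the two partitions.

    Witnesses ``s1, s2 in X1``, ``s3, s4 in X2`` with ``s1, s3 in Y1`` and
    ``s2, s4 in Y2`` exist exactly when all four pairwise side
    intersections are nonempty.
    """
    if x.universe != y.universe:
        raise ValueError("partitions are over different species sets")
    x1, x2 = x.sides
    y1, y2 = y.sides
    return bool(x1 & y1) and bool(x1 & y2) and bool(x2 & y1) and bool(x2 & y2)


@dataclass(frozen=True)
class TreeContradiction:
    contradict: bool
    witness: tuple[TwoPartition, TwoPartition] | None = None
    all_witnesses: tuple[tuple[TwoPartition, TwoPartition], ...] = ()

    def __bool__(self) -> bool:
        return self.contradict


def trees_contradict(
    t1: STree, t2: STree, all_witnesses: bool = False
) -> TreeContradiction:
    """Do any 2-partitions of the two trees contradict?

    Returns the first witness pair (in canonical partition order); with
    ``all_witnesses`` every contradicting pair is collected for reports.
    """
    if t1.species != t2.species:
        raise ValueError("trees have different leaf sets")
    p1 = sorted(find_two_partitions(t1))
    p2 = sorted(find_two_partitions(t2))
    found = []
    for a in p1:
        for b in p2:
            if partitions_contradict(a, b):
                if not all_witnesses:
                    return TreeContradiction(True, (a, b), ((a, b),))
                found.append((a, b))
    if found:
        return TreeContradiction(True, found[0], tuple(found))
    return TreeContradiction(False)


def construct_tree_from_partitions(q: Iterable[TwoPartition]) -> STree:
    """Rebuild the tree whose edge cuts induce the given (augmented) set.

    Expects partitions over the species set plus the reserved ``s0`` leaf.
    Singleton-sided partitions are dropped; then, repeatedly, the pending
    partition whose species side (the side without ``s0``) is smallest —
    ties broken lexicographically — has that side's members joined under a
    new parent, which replaces them throughout.  A root adopts whatever
    remains, and ``s0`` is stripped before returning.
    """
    q = sorted(set(q))
    if not q:
        raise ValueError("empty 2-partition set")
    universe = q[0].universe
    if AUGMENT_LABEL not in universe:
        raise ValueError(f"expected an {AUGMENT_LABEL}-augmented partition set")
    for p in q:
        if p.universe != universe:
            raise ValueError("partitions are over different species sets")
    for i, a in enumerate(q):
        for b in q[i + 1 :]:
            if partitions_contradict(a, b):
                raise ContradictionError(
                    f"partition set contradicts itself: {a} vs {b}",
                    witness=(a, b),
                )
    species = universe - {AUGMENT_LABEL}
    # work on the non-s0 side of each partition, as a set of current labels
    sides = {
        side
        for p in q
        for side in [min(p.sides, key=lambda s: AUGMENT_LABEL in s)]
        if AUGMENT_LABEL not in side and 1 < len(side) < len(species)
    }
    nodes: dict[str, TreeNode] = {s: TreeNode(s) for s in species}
    active = set(species)
    counter = 0
    pending = set(sides)
    while pending:
        side = min(pending, key=lambda s: (len(s), sorted(s)))
        pending.discard(side)
        if len(side) < 2:
            continue
        counter += 1
        label = f"u{counter}"
        parent = TreeNode()
        for member in sorted(side):
            parent.add(nodes[member])
        nodes[label] = parent
        active -= side
        active.add(label)
        pending = {
            frozenset(s - side | {label}) if side <= s else s for s in pending
        }
    remaining = sorted(active)
    if len(remaining) == 1:
        root = nodes[remaining[0]]
    else:
        root = TreeNode()
        for lab in remaining:
            root.add(nodes[lab])
    return STree(root)


def min_common_refinement(t1: STree, t2: STree) -> STree:
    """The least-refined common refinement of two non-contradictory trees.

    Its 2-partition set is exactly the union of the inputs' (augmented)
    2-partition sets.  Contradictory inputs raise
    :class:`ContradictionError` naming a witness partition pair.
    """
    if t1.species != t2.species:
        raise ValueError("trees have different leaf sets")
    verdict = trees_contradict(t1, t2)
    if verdict:
        a, b = verdict.witness
        raise ContradictionError(
            f"trees contradict: {a} vs {b}; no common refinement exists",
            witness=(a, b),
        )
    q = find_two_partitions(t1, augment=True) | find_two_partitions(t2, augment=True)
    return construct_tree_from_partitions(q)
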