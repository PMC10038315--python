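"""Reconstruct a species tree from a poset family via the sibling matrix.

The sibling matrix ``A`` has ``A(i, j) = |{s_x : s_j < s_x in the poset
anchored at s_i}|`` and ``-1`` on the diagonal.  For a consistent family
``A`` is symmetric, and equal maximal off-diagonal values identify sibling
groups: the higher the value, the deeper the siblings sit in the tree.
Construction repeatedly merges the current maximal sibling groups into
parent nodes — collapsing their rows and columns — until every remaining
value is zero, at which point a root adopts whatever is left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateMatrixError, InconsistentFamilyError
from .posets import PosetFamily
from .trees import STree, TreeNode

logger = logging.getLogger(__name__)


@dataclass
class SiblingMatrix:
    """Square integer closeness-count matrix over current node labels.

    ``provenance`` maps each label (a species, or a merged node) to the set
    of original species beneath it.
    """

    labels: list[str]
    values: np.ndarray
    provenance: dict[str, frozenset[str]]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def value(self, a: str, b: str) -> int:
        return int(self.values[self.index(a), self.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def build_matrix(fam: PosetFamily) -> SiblingMatrix:
    """Sibling matrix of a family: counts of species above each species."""
    labels = sorted(fam.species)
    n = len(labels)
    values = np.full((n, n), -1, dtype=int)
    for i, si in enumerate(labels):
        p = fam.poset(si)
        above_count: dict[str, int] = {}
        for a, _ in p.pairs:
            above_count[a] = above_count.get(a, 0) + 1
        for j, sj in enumerate(labels):
            if i != j:
                values[i, j] = above_count.get(sj, 0)
    return SiblingMatrix(
        labels=labels,
        values=values,
        provenance={s: frozenset({s}) for s in labels},
    )


def validate_matrix(a: SiblingMatrix) -> bool:
    """True iff the matrix is symmetric (holds for consistent families)."""
    return bool(np.array_equal(a.values, a.values.T))


def find_max(a: SiblingMatrix) -> int:
    """Maximum off-diagonal entry (0 when everything left is unrelated)."""
    if a.n < 2:
        raise DegenerateMatrixError("need at least a 2x2 matrix")
    off = a.values[~np.eye(a.n, dtype=bool)]
    return int(off.max())


def find_sibling_groups(a: SiblingMatrix, max_value: int) -> list[frozenset[str]]:
    """Label groups joined by edges carrying the current maximum value.

    Groups are the connected components of the graph whose edges are the
    pairs with value ``max_value``.  A component that is a clique is a plain
    sibling group; a connected non-clique component (a node tied equally to
    members of otherwise unrelated groups) is returned whole, to be placed
    under a single shared parent.  Components are ordered by their smallest
    original-species label.
    """
    if max_value <= 0:
        return []
    g = nx.Graph()
    idx = {lab: i for i, lab in enumerate(a.labels)}
    for x in a.labels:
        for y in a.labels:
            if x < y and a.values[idx[x], idx[y]] == max_value:
                g.add_edge(x, y)
    groups = []
    for comp in nx.connected_components(g):
        comp = frozenset(comp)
        members = sorted(comp)
        clique = all(
            a.values[idx[x], idx[y]] == max_value
            for i, x in enumerate(members)
            for y in members[i + 1 :]
        )
        if not clique:
            logger.warning(
                "max-valued edges on %s do not form a clique; "
                "placing all members under one shared parent",
                members,
            )
        groups.append(comp)
    return sorted(groups, key=lambda c: min(min(a.provenance[m]) for m in c))


def merge_siblings(
    a: SiblingMatrix, group: frozenset[str], forest: dict[str, TreeNode]
) -> tuple[SiblingMatrix, dict[str, TreeNode]]:
    """Collapse a sibling group into one parent node and one matrix label.

    Every outside label must relate identically to all group members;
    disagreement means the posets carry conflicting information and no
    compatible tree exists.
    """
    members = sorted(group)
    outside = [lab for lab in a.labels if lab not in group]
    merged_species = frozenset().union(*(a.provenance[m] for m in members))
    new_label = "+".join(sorted(merged_species))

    parent = TreeNode()
    for m in members:
        parent.add(forest.pop(m))
    forest = dict(forest)
    forest[new_label] = parent

    idx = {lab: i for i, lab in enumerate(a.labels)}
    new_labels = [new_label] + outside
    n = len(new_labels)
    values = np.full((n, n), -1, dtype=int)
    for j, w in enumerate(outside, start=1):
        vals = {int(a.values[idx[m], idx[w]]) for m in members}
        if len(vals) != 1:
            raise InconsistentFamilyError(
                f"siblings {members} disagree about {w}: values {sorted(vals)}"
            )
        values[0, j] = values[j, 0] = vals.pop()
    for j, w in enumerate(outside, start=1):
        for k, v in enumerate(outside, start=1):
            if j != k:
                values[j, k] = a.values[idx[w], idx[v]]
    prov = {lab: a.provenance[lab] for lab in outside}
    prov[new_label] = merged_species
    return SiblingMatrix(labels=new_labels, values=values, provenance=prov), forest


def construct_tree(fam: PosetFamily) -> STree:
    """Build the species tree compatible with a consistent poset family.

    Raises :class:`InconsistentFamilyError` when the matrix is asymmetric or
    a merge finds disagreeing values — i.e. when the posets carry missing or
    incorrect information admitting no compatible tree.
    """
    if len(fam.species) == 1:
        (only,) = fam.species
        return STree(TreeNode(only))
    a = build_matrix(fam)
    if not validate_matrix(a):
        asym = np.argwhere(a.values != a.values.T)
        i, j = asym[0]
        raise InconsistentFamilyError(
            f"gene {fam.gene}: sibling matrix asymmetric at "
            f"({a.labels[i]}, {a.labels[j]}): "
            f"{a.values[i, j]} vs {a.values[j, i]}"
        )
    forest: dict[str, TreeNode] = {s: TreeNode(s) for s in a.labels}
    while a.n > 1:
        m = find_max(a)
        if m == 0:
            break
        for group in find_sibling_groups(a, m):
            a, forest = merge_siblings(a, group, forest)
    remaining = [forest[lab] for lab in a.labels]
    if len(remaining) == 1:
        root = remaining[0]
    else:
        root = TreeNode()
        for node in remaining:
            root.add(node)
    return STree(root)
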