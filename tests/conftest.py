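"""Shared fixtures: worked-example trees and families, independent oracles."""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import HealthCheck, settings

import posethgt as ph

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Worked-example objects
# ---------------------------------------------------------------------------


@pytest.fixture
def caterpillar5():
    """5-taxon tree: root children ((s1,s2),s3) and (s4,s5)."""
    return ph.parse_newick("(((s1,s2),s3),(s4,s5));")


@pytest.fixture
def caterpillar5_family(caterpillar5):
    return ph.generate_posets(caterpillar5, gene="g1")


@pytest.fixture
def two_triples6():
    """6-taxon tree: two sibling triples under the root."""
    return ph.parse_newick("((s1,s2,s3),(s4,s5,s6));")


@pytest.fixture
def printed_family4():
    """The 4-species poset family given pairwise in the construction text."""
    sp = frozenset({"s1", "s2", "s3", "s4"})
    raw = {
        "s1": [("s1", "s2"), ("s1", "s3"), ("s1", "s4"), ("s2", "s4"), ("s3", "s4")],
        "s2": [("s2", "s1"), ("s2", "s3"), ("s2", "s4"), ("s1", "s4"), ("s3", "s4")],
        "s3": [("s3", "s1"), ("s3", "s2"), ("s3", "s4"), ("s1", "s4"), ("s2", "s4")],
        "s4": [("s4", "s1"), ("s4", "s2"), ("s4", "s3")],
    }
    posets = {f: ph.Poset.build(f, pairs, sp) for f, pairs in raw.items()}
    return ph.PosetFamily(gene="gA", species=sp, posets=posets)


@pytest.fixture
def quartet_majority():
    return ph.parse_newick("((s1,s2),(s3,s4));")


@pytest.fixture
def quartet_transfer():
    """The alternative quartet topology grouping {s1,s3} and {s2,s4}."""
    return ph.parse_newick("((s1,s3),(s2,s4));")


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def leaf_path(t: ph.STree, u: str, v: str) -> list:
    """Node sequence of the unique path between two leaves."""
    nu, nv = t.leaf(u), t.leaf(v)
    up_u, node = [], nu
    while node is not None:
        up_u.append(node)
        node = node.parent
    seen = {id(n): i for i, n in enumerate(up_u)}
    up_v, node = [], nv
    while id(node) not in seen:
        up_v.append(node)
        node = node.parent
    return up_u[: seen[id(node)] + 1] + list(reversed(up_v))


def compatible_by_path_walk(p: ph.Poset, t: ph.STree) -> bool:
    """Literal path-membership oracle for poset-tree compatibility.

    For every relation s_j < s_k anchored at s_i, the path from the focal
    leaf to s_k must pass through MRCA(s_i, s_j).  Enumerates paths node by
    node; no depth comparisons.
    """
    for s_j, s_k in p.pairs:
        w = ph.mrca(t, p.focal, s_j)
        if not any(n is w for n in leaf_path(t, p.focal, s_k)):
            return False
    return True


def contradict_by_quadruples(x: ph.TwoPartition, y: ph.TwoPartition) -> bool:
    """Exhaustive witness search over species quadruples and side orderings."""
    universe = sorted(x.universe)
    for s1, s2, s3, s4 in itertools.permutations(universe, 4):
        for x1, x2 in (x.sides, x.sides[::-1]):
            for y1, y2 in (y.sides, y.sides[::-1]):
                if (
                    s1 in x1 and s2 in x1 and s3 in x2 and s4 in x2
                    and s1 in y1 and s3 in y1 and s2 in y2 and s4 in y2
                ):
                    return True
    return False


def random_contraction(t: ph.STree, rng: random.Random, prob: float = 0.5) -> ph.STree:
    """Contract each internal non-root node with the given probability."""
    t2 = t.copy()
    for node in list(t2.preorder()):
        if not node.is_leaf and node.parent is not None and rng.random() < prob:
            parent = node.parent
            i = parent.children.index(node)
            parent.children[i : i + 1] = node.children
            for c in node.children:
                c.parent = parent
    return ph.STree(t2.root)


def random_refinement(t: ph.STree, rng: random.Random) -> ph.STree:
    """Apply refinement steps at random multifurcations until none remain or luck runs out."""
    for _ in range(10):
        multis = [n for n in t.internal_nodes() if len(n.children) >= 3]
        if not multis or rng.random() < 0.3:
            break
        x = rng.choice(multis)
        k = rng.randint(2, len(x.children) - 1)
        group = rng.sample(x.children, k)
        t = ph.refine_step(t, x, group)
    return t
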