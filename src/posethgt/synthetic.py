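"""Seeded generators: random species trees, transfer injection, corruption.

These emulate the framework's study conditions end to end: a base species
tree shared by all genes, poset families derived from it, and for selected
genes a horizontal transfer simulated as a leaf regraft — the recipient
leaf is detached and reattached as sibling of the donor, the smallest
topological move that creates a contradicting quartet.  Score-derived
posets model ranked similarity (e.g. BLAST bit-score) input, where ties
map to incomparability.

All randomness flows through explicit seeds; identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

import random
import warnings
from itertools import product
from typing import Mapping, Sequence

import pandas as pd

from .partitions import trees_contradict
from .poset_generation import generate_posets
from .posets import Poset, PosetFamily
from .trees import STree, TreeNode

__all__ = [
    "random_stree",
    "inject_hgt",
    "random_transfer_pair",
    "make_dataset",
    "corrupt_posets",
    "posets_from_scores",
]


def random_stree(
    species: Sequence[str],
    seed: int | None = None,
    binary: bool = True,
    multifurcation_prob: float = 0.25,
) -> STree:
    """A random rooted species tree over ``species``.

    Built by uniform sequential leaf attachment (a random binary shape);
    with ``binary=False`` each internal non-root node is then contracted
    into its parent with probability ``multifurcation_prob``, producing
    polytomies while keeping every outdegree at least two.
    """
    labels = list(species)
    if not labels:
        raise ValueError("need at least one species")
    if len(set(labels)) != len(labels):
        raise ValueError("species labels must be unique")
    rng = random.Random(seed)
    order = labels[:]
    rng.shuffle(order)
    root = TreeNode(order[0])
    nodes = [root]
    for label in order[1:]:
        target = rng.choice(nodes)
        parent = TreeNode()
        leaf = TreeNode(label)
        if target.parent is None:
            parent.add(target)
            parent.add(leaf)
            root = parent
        else:
            gp = target.parent
            gp.children[gp.children.index(target)] = parent
            parent.parent = gp
            parent.add(target)
            parent.add(leaf)
        nodes.extend([parent, leaf])
    if not binary and multifurcation_prob > 0:
        t = STree(root)
        for node in list(t.preorder()):
            if (
                not node.is_leaf
                and node.parent is not None
                and rng.random() < multifurcation_prob
            ):
                parent = node.parent
                i = parent.children.index(node)
                parent.children[i : i + 1] = node.children
                for c in node.children:
                    c.parent = parent
        return STree(root)
    return STree(root)


def inject_hgt(t: STree, a: str, b: str, seed: int | None = None) -> STree:
    """Simulate a transfer between ``a`` and ``b`` by regrafting leaf ``b``.

    Leaf ``b`` is detached (collapsing any outdegree-1 remnant) and
    reattached as sibling of ``a``, so the gene tree groups the pair the
    species tree separates.  The operation is deterministic; ``seed`` is
    accepted for generator-interface uniformity.  With fewer than four
    species, or when the regraft yields no contradicting quartet (``a`` and
    ``b`` already exclusive siblings), a warning is issued — in the latter
    case the regrafted tree is still returned.
    """
    del seed
    if a == b:
        raise ValueError("transfer endpoints must differ")
    if a not in t.species or b not in t.species:
        raise KeyError(f"species {a!r}/{b!r} not both in the tree")
    if len(t.species) < 4:
        warnings.warn(
            "fewer than four species: no quartet can witness a transfer; "
            "tree returned unchanged",
            stacklevel=2,
        )
        return t.copy()
    t2 = t.copy()
    node_b = t2.leaf(b)
    parent = node_b.parent
    parent.children.remove(node_b)
    if len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        gp = parent.parent
        gp.children[gp.children.index(parent)] = only
        only.parent = gp
    root = t2.root
    if len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    t2 = STree(root)
    node_a = t2.leaf(a)
    gp = node_a.parent
    graft = TreeNode()
    if gp is None:  # a is the whole remaining tree
        graft.add(node_a)
        graft.add(node_b)
        return STree(graft)
    gp.children[gp.children.index(node_a)] = graft
    graft.parent = gp
    graft.add(node_a)
    graft.add(node_b)
    out = STree(t2.root)
    if not trees_contradict(t, out):
        warnings.warn(
            f"regrafting {b} beside {a} produced no detectable contradiction",
            stacklevel=2,
        )
    return out


def random_transfer_pair(
    t: STree, rng: random.Random, max_tries: int = 200
) -> tuple[str, str]:
    """Sample a species pair whose regraft contradicts ``t``."""
    labels = sorted(t.species)
    if len(labels) < 4:
        raise ValueError("need at least four species for a detectable transfer")
    for _ in range(max_tries):
        a, b = rng.sample(labels, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t2 = inject_hgt(t, a, b)
        if trees_contradict(t, t2):
            return a, b
    raise RuntimeError("no contradicting transfer pair found")


def make_dataset(
    n_species: int,
    n_genes: int,
    hgt_genes: Sequence[tuple[str, str, str]] = (),
    seed: int = 0,
    binary: bool = True,
    multifurcation_prob: float = 0.25,
) -> tuple[dict[str, PosetFamily], dict]:
    """Per-gene poset families from one base tree, with injected transfers.

    Species are ``s1..sN`` and genes ``g1..gM``.  Each entry of
    ``hgt_genes`` is ``(gene, donor, recipient)``: that gene's family is
    generated from the regrafted tree instead of the base tree.  Returns
    the families plus a ground-truth record (base tree, injected genes and
    pairs) for evaluating recovery.
    """
    species = [f"s{i}" for i in range(1, n_species + 1)]
    genes = [f"g{k}" for k in range(1, n_genes + 1)]
    rng = random.Random(seed)
    base = random_stree(
        species,
        seed=rng.randrange(2**31),
        binary=binary,
        multifurcation_prob=multifurcation_prob,
    )
    injected: dict[str, tuple[str, str]] = {}
    trees = {}
    for gene, a, b in hgt_genes:
        if gene not in genes:
            raise ValueError(f"unknown gene {gene!r} (have g1..g{n_genes})")
        if a not in base.species or b not in base.species:
            raise ValueError(f"unknown species in transfer ({a}, {b})")
        trees[gene] = inject_hgt(base, a, b)
        injected[gene] = (a, b)
    families = {
        gene: generate_posets(trees.get(gene, base), gene=gene) for gene in genes
    }
    truth = {
        "seed": seed,
        "species": species,
        "base_tree": base.canonical_newick(),
        "injected": {g: list(pair) for g, pair in injected.items()},
    }
    return families, truth


def corrupt_posets(
    fam: PosetFamily, mode: str, rate: float, seed: int | None = None
) -> PosetFamily:
    """Degrade a family by dropping or reversing relation pairs.

    ``drop`` removes each non-focal pair with probability ``rate`` and then
    restores focal minimality only (no transitive re-closure), emulating
    missing data; ``flip`` reverses non-focal pairs with probability
    ``rate``, emulating incorrect data.  The output may be invalid or
    inconsistent by design — that is the point.
    """
    if mode not in ("drop", "flip"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = random.Random(seed)
    posets = {}
    for focal in sorted(fam.posets):
        p = fam.posets[focal]
        pairs = set()
        for a, b in sorted(p.pairs):
            if a == focal:
                pairs.add((a, b))
                continue
            hit = rng.random() < rate
            if mode == "drop":
                if not hit:
                    pairs.add((a, b))
            else:
                pairs.add((b, a) if hit else (a, b))
        for s in p.species - {focal}:
            pairs.add((focal, s))
        posets[focal] = Poset(focal=focal, species=p.species, pairs=frozenset(pairs))
    return PosetFamily(gene=fam.gene, species=fam.species, posets=posets)


def posets_from_scores(
    scores: pd.DataFrame, gene: str = "g", focal_per_row: bool = True
) -> PosetFamily:
    """Rank a species-by-species similarity matrix into a poset family.

    For each focal species (a row, or a column with ``focal_per_row``
    False), a strictly greater similarity score means strictly closer; tied
    scores leave species incomparable (same level).  The diagonal is
    ignored.  Scores must be numeric and nonnegative, with matching row and
    column labels — e.g. per-gene BLAST bit scores.
    """
    if scores.shape[0] != scores.shape[1]:
        raise ValueError("score matrix must be square")
    if set(scores.index) != set(scores.columns):
        raise ValueError("row and column labels must coincide")
    if not focal_per_row:
        scores = scores.T
    values = scores.astype(float)
    if (values.to_numpy()[~pd.isna(values.to_numpy())] < 0).any():
        raise ValueError("scores must be nonnegative")
    species = frozenset(str(s) for s in scores.index)
    posets = {}
    for focal in sorted(species):
        row = values.loc[focal]
        others = sorted(species - {focal})
        pairs = {(focal, s) for s in others}
        for x, y in product(others, others):
            if x != y and row[x] > row[y]:
                pairs.add((x, y))
        posets[focal] = Poset(focal=focal, species=species, pairs=frozenset(pairs))
    return PosetFamily(gene=gene, species=species, posets=posets)
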