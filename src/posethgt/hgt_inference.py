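"""Flag horizontal-transfer candidate genes from per-gene tree incongruence.

One species tree is built per gene from its poset family.  Trees are then
clustered by pairwise contradiction: each tree joins the first existing
cluster whose representative it does not contradict, else founds a new one.
Since most genes descend vertically, the largest cluster is declared the
majority topology; genes outside it are HGT candidates, each annotated with
the contradicting partition pairs and the species pairs they unite that the
majority tree separates.  Transfer direction is not resolved — both arcs
are reported per pair.

Incongruence has other causes (gene duplication, gene loss, incomplete
lineage sorting); the report names them as confounders rather than
modelling them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import PosetHGTError
from .partitions import TwoPartition, find_two_partitions, partitions_contradict, trees_contradict
from .posets import PosetFamily
from .tree_construction import construct_tree
from .trees import STree

logger = logging.getLogger(__name__)

CONFOUNDERS = (
    "gene duplication",
    "gene loss",
    "incomplete lineage sorting",
)


@dataclass(frozen=True)
class TransferWitness:
    """One contradicting partition pair and the species pairs it implicates.

    ``pairs`` are the two unordered species pairs placed together by the
    candidate tree but separated by the majority tree; ``arcs`` lists both
    possible transfer directions for each pair.
    """

    partition_candidate: TwoPartition
    partition_majority: TwoPartition
    pairs: tuple[tuple[str, str], tuple[str, str]]
    arcs: tuple[tuple[str, str], ...]

    def to_dict(self) -> dict:
        return {
            "partition_a": [sorted(s) for s in self.partition_candidate.sides],
            "partition_b": [sorted(s) for s in self.partition_majority.sides],
            "pairs": [list(p) for p in self.pairs],
            "arcs": [list(a) for a in self.arcs],
        }


@dataclass
class Cluster:
    genes: list[str]
    trees: list[STree]

    @property
    def representative(self) -> STree:
        return self.trees[0]


@dataclass
class HGTReport:
    """Clustering outcome: majority topology, candidate genes, witnesses."""

    clusters: list[Cluster]
    majority: int | None
    candidates: list[str]
    witnesses: dict[str, tuple[TransferWitness, ...]]
    unconstructible: list[str] = field(default_factory=list)
    ambiguous: bool = False

    def to_dict(self) -> dict:
        return {
            "confounders": list(CONFOUNDERS),
            "clusters": [
                {
                    "genes": list(c.genes),
                    "representative_newick": c.representative.canonical_newick(),
                }
                for c in self.clusters
            ],
            "majority": self.majority,
            "ambiguous": self.ambiguous,
            "candidates": [
                {
                    "gene": g,
                    "witnesses": [w.to_dict() for w in self.witnesses.get(g, ())],
                }
                for g in self.candidates
            ],
            "unconstructible": list(self.unconstructible),
        }


def cluster_trees(
    trees: Sequence[tuple[str, STree]], strict: bool = False
) -> list[Cluster]:
    """Group gene trees into mutually non-contradicting clusters.

    Sequential first-fit: each tree is tested against the representative
    (first member) of each cluster in creation order and joins the first it
    does not contradict.  Contradiction is not transitive, so in ``strict``
    mode a tree must be non-contradictory with *every* member to join.
    """
    clusters: list[Cluster] = []
    leafset = None
    for gene, tree in trees:
        if leafset is None:
            leafset = tree.species
        elif tree.species != leafset:
            raise ValueError(f"gene {gene}: leaf set differs from the other trees")
        for cluster in clusters:
            others = cluster.trees if strict else [cluster.representative]
            if not any(trees_contradict(tree, other) for other in others):
                cluster.genes.append(gene)
                cluster.trees.append(tree)
                break
        else:
            clusters.append(Cluster(genes=[gene], trees=[tree]))
    return clusters


def witness_transfers(candidate: STree, majority: STree) -> tuple[TransferWitness, ...]:
    """Possible transfers explaining why ``candidate`` contradicts ``majority``.

    For each contradicting partition pair, the candidate partition's sides
    each contain a species pair that the majority partition splits; a
    transfer within either pair (in either direction) would produce the
    observed grouping.  Representatives are chosen lexicographically for
    determinism.  Empty when the trees do not contradict.
    """
    out = []
    for pc in sorted(find_two_partitions(candidate)):
        for pm in sorted(find_two_partitions(majority)):
            if not partitions_contradict(pc, pm):
                continue
            (x1, x2), (y1, y2) = pc.sides, pm.sides
            pair1 = (min(x1 & y1), min(x1 & y2))
            pair2 = (min(x2 & y1), min(x2 & y2))
            pair1, pair2 = tuple(sorted(pair1)), tuple(sorted(pair2))
            arcs = (
                pair1, (pair1[1], pair1[0]),
                pair2, (pair2[1], pair2[0]),
            )
            out.append(
                TransferWitness(
                    partition_candidate=pc,
                    partition_majority=pm,
                    pairs=(pair1, pair2),
                    arcs=arcs,
                )
            )
    return tuple(out)


def infer_hgt(
    families: Mapping[str, PosetFamily], strict: bool = False
) -> HGTReport:
    """End-to-end inference: per-gene trees, clustering, candidate calling.

    Genes whose families admit no compatible tree (missing or corrupt
    closeness data) are reported as unconstructible and excluded.  A tie
    for the largest cluster yields an explicit no-call (``majority`` None,
    ``ambiguous`` True) rather than an arbitrary pick.
    """
    trees: list[tuple[str, STree]] = []
    unconstructible: list[str] = []
    for gene, fam in families.items():
        try:
            trees.append((gene, construct_tree(fam)))
        except PosetHGTError as exc:
            logger.warning("gene %s: no compatible tree (%s); excluded", gene, exc)
            unconstructible.append(gene)
    clusters = cluster_trees(trees, strict=strict)
    if not clusters:
        return HGTReport([], None, [], {}, unconstructible)
    sizes = [len(c.genes) for c in clusters]
    top = max(sizes)
    if sizes.count(top) > 1:
        logger.warning("majority tie between clusters of size %d: no call", top)
        return HGTReport(clusters, None, [], {}, unconstructible, ambiguous=True)
    majority = sizes.index(top)
    rep = clusters[majority].representative
    candidates: list[str] = []
    witnesses: dict[str, tuple[TransferWitness, ...]] = {}
    for i, cluster in enumerate(clusters):
        if i == majority:
            continue
        for gene, tree in zip(cluster.genes, cluster.trees):
            candidates.append(gene)
            witnesses[gene] = witness_transfers(tree, rep)
    return HGTReport(clusters, majority, candidates, witnesses, unconstructible)
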