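"""Species-anchored partial orders (posets) and their file format.

The framework represents the relative closeness of species to a focal
species ``s_i`` as an *s_i-poset*: a strict partial order over the species
set ``S`` in which ``s_i`` is the unique minimum and ``(a, b)`` means "``a``
is strictly closer to ``s_i`` than ``b``".  One poset per species, for a
single gene, forms a :class:`PosetFamily` — the unit of input for tree
construction.

Internally the strict relation ``<`` is the canonical form: reflexive pairs
are never stored, and the pair set is kept transitively closed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    AntisymmetryError,
    IncompleteFamilyError,
    ParseError,
)

logger = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"[A-Za-z0-9_.-]+\Z")

Pair = tuple[str, str]


def transitive_closure(pairs: Iterable[Pair]) -> frozenset[Pair]:
    """Smallest transitively closed superset of ``pairs``.

    Self-pairs ``(a, a)`` are rejected, and so is any input whose closure
    would assert both ``(a, b)`` and ``(b, a)`` — the offending cycle is
    named in the raised :class:`AntisymmetryError`.  Idempotent and monotone.
    """
    pairs = set(pairs)
    for a, b in pairs:
        if a == b:
            raise AntisymmetryError(f"self-pair ({a}, {a}) is not a strict relation")
    g = nx.DiGraph()
    g.add_edges_from(pairs)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = " < ".join(str(u) for u, _ in cycle) + f" < {cycle[-1][1]}"
        raise AntisymmetryError(f"closure violates antisymmetry: {path}")
    closed = nx.transitive_closure(g)
    return frozenset(closed.edges())


@dataclass(frozen=True)
class Poset:
    """A strict partial order over ``species`` anchored at ``focal``.

    ``pairs`` holds ordered pairs ``(a, b)`` meaning ``a <_focal b``.  Use
    :meth:`build` to construct from raw (possibly cover-only) pairs; the
    constructor itself stores exactly what it is given.
    """

    focal: str
    species: frozenset[str]
    pairs: frozenset[Pair]

    @classmethod
    def build(
        cls,
        focal: str,
        pairs: Iterable[Pair],
        species: Iterable[str],
        *,
        add_focal_minimum: bool = True,
    ) -> "Poset":
        """Close ``pairs`` transitively and complete the focal minimum.

        Input pairs may be Hasse-diagram covers or the full relation; the
        two representations close to the same poset.  Missing ``(focal, s)``
        pairs are added (the definition of an anchored poset forces them)
        with a log notice.
        """
        species = frozenset(species)
        closed = set(transitive_closure(pairs))
        if add_focal_minimum:
            missing = {
                (focal, s) for s in species if s != focal and (focal, s) not in closed
            }
            if missing:
                logger.info(
                    "poset %s: auto-added %d focal-minimum pair(s)", focal, len(missing)
                )
                closed |= missing
                closed = set(transitive_closure(closed))
        return cls(focal=focal, species=species, pairs=frozenset(closed))

    def above(self, s: str) -> frozenset[str]:
        """Species strictly farther from the focal than ``s``."""
        return frozenset(b for a, b in self.pairs if a == s)

    def levels(self) -> list[frozenset[str]]:
        """Stratify species by the number of species strictly below them.

        For tree-derived posets this recovers the closeness levels used by
        the generator; for arbitrary posets it is a longest-chain ranking.
        """
        below: dict[str, set[str]] = {s: set() for s in self.species}
        for a, b in self.pairs:
            below[b].add(a)
        depth = {s: 0 for s in self.species}
        for s in sorted(self.species, key=lambda x: len(below[x])):
            depth[s] = max((depth[a] + 1 for a in below[s]), default=0)
        out: dict[int, set[str]] = {}
        for s, d in depth.items():
            out.setdefault(d, set()).add(s)
        return [frozenset(out[d]) for d in sorted(out)]


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    errors: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.valid


def validate_poset(p: Poset) -> ValidationResult:
    """Check the four anchored-poset invariants; never raises.

    Verifies label domain, antisymmetry (no self or reversed pairs),
    transitive closure, and that the focal species sits strictly below
    every other species.
    """
    errors: list[str] = []
    bad_labels = {x for pair in p.pairs for x in pair} - p.species
    if p.focal not in p.species:
        errors.append(f"focal {p.focal} not in species set")
    if bad_labels:
        errors.append(f"labels outside species set: {sorted(bad_labels)}")
    for a, b in sorted(p.pairs):
        if a == b:
            errors.append(f"reflexive pair ({a}, {b}) stored")
        elif (b, a) in p.pairs and a < b:
            errors.append(f"antisymmetry violated: both ({a}, {b}) and ({b}, {a})")
    succ: dict[str, set[str]] = {}
    for a, b in p.pairs:
        succ.setdefault(a, set()).add(b)
    for a, bs in succ.items():
        for b in bs:
            gap = succ.get(b, set()) - bs
            for c in sorted(gap):
                errors.append(f"not transitively closed: ({a}, {b}), ({b}, {c}) without ({a}, {c})")
    if p.focal in p.species:
        for s in sorted(p.species - {p.focal}):
            if (p.focal, s) not in p.pairs:
                errors.append(f"focal minimum violated: ({p.focal}, {s}) missing")
    return ValidationResult(valid=not errors, errors=tuple(errors))


@dataclass(frozen=True)
class PosetFamily:
    """One anchored poset per species, for a single gene."""

    gene: str
    species: frozenset[str]
    posets: Mapping[str, Poset] = field(hash=False)

    def __post_init__(self):
        object.__setattr__(self, "posets", dict(self.posets))

    def poset(self, focal: str) -> Poset:
        try:
            return self.posets[focal]
        except KeyError:
            raise IncompleteFamilyError(
                f"gene {self.gene}: no poset anchored at {focal}"
            ) from None

    def __eq__(self, other):
        if not isinstance(other, PosetFamily):
            return NotImplemented
        return (
            self.gene == other.gene
            and self.species == other.species
            and dict(self.posets) == dict(other.posets)
        )


@dataclass(frozen=True)
class ConsistencyResult:
    consistent: bool
    violation: tuple[str, str, str] | None = None  # (focal_i, s_j, s_k)

    def __bool__(self) -> bool:
        return self.consistent


def is_consistent(fam: PosetFamily) -> ConsistencyResult:
    """Mutual-agreement check across a family's posets.

    The family is consistent when, whenever ``s_j < s_k`` in the poset
    anchored at ``s_i``, also ``s_i <= s_k`` in the poset anchored at
    ``s_j``.  Consistency is what makes the sibling matrix symmetric and a
    compatible tree constructible.  Returns the first violating triple
    ``(s_i, s_j, s_k)`` on failure.
    """
    for focal in sorted(fam.species):
        if focal not in fam.posets:
            raise IncompleteFamilyError(f"gene {fam.gene}: no poset anchored at {focal}")
    for focal in sorted(fam.species):
        p_i = fam.posets[focal]
        for s_j, s_k in sorted(p_i.pairs):
            if s_k == focal:
                continue
            p_j = fam.posets.get(s_j)
            if p_j is None:
                raise IncompleteFamilyError(f"gene {fam.gene}: no poset anchored at {s_j}")
            if (focal, s_k) not in p_j.pairs:
                return ConsistencyResult(False, (focal, s_j, s_k))
    return ConsistencyResult(True)


# ---------------------------------------------------------------------------
# File format
#
# Tab-separated, one strict pair per line:
#   #species<TAB>s1,s2,s3        (per gene block; declares the species set)
#   gene<TAB>focal<TAB>lesser<TAB>greater
# '#' starts a comment; labels match [A-Za-z0-9_.-]+.
# ---------------------------------------------------------------------------


def _check_label(label: str, line: int) -> str:
    if not _LABEL_RE.match(label):
        raise ParseError(f"bad label {label!r}", line)
    return label


def read_poset_file(path: str | Path) -> dict[str, PosetFamily]:
    """Read a poset TSV into families keyed by gene.

    Pairs are transitively closed on load and missing focal-minimum pairs
    completed with a log notice, so the file may store covers only.  Species
    with no data lines get the focal-minimum-only poset.
    """
    path = Path(path)
    species_current: frozenset[str] | None = None
    gene_species: dict[str, frozenset[str]] = {}
    gene_pairs: dict[str, dict[str, set[Pair]]] = {}
    gene_lines: dict[str, int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#species\t"):
                labels = [s.strip() for s in line.split("\t", 1)[1].split(",")]
                species_current = frozenset(
                    _check_label(s, lineno) for s in labels if s
                )
                if not species_current:
                    raise ParseError("empty species declaration", lineno)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"expected 4 tab-separated fields, got {len(fields)}", lineno
                )
            gene, focal, lesser, greater = (
                _check_label(f.strip(), lineno) for f in fields
            )
            if species_current is None:
                raise ParseError("data line before any #species declaration", lineno)
            if gene not in gene_species:
                gene_species[gene] = species_current
                gene_pairs[gene] = {}
                gene_lines[gene] = lineno
            sp = gene_species[gene]
            for lab in (focal, lesser, greater):
                if lab not in sp:
                    raise ParseError(
                        f"unknown species label {lab!r} for gene {gene}", lineno
                    )
            if lesser == greater:
                raise ParseError(
                    f"self-pair ({lesser}, {greater}) violates antisymmetry", lineno
                )
            bucket = gene_pairs[gene].setdefault(focal, set())
            if (greater, lesser) in bucket:
                raise ParseError(
                    f"pair ({lesser}, {greater}) reverses an earlier pair "
                    f"for (gene {gene}, focal {focal})",
                    lineno,
                )
            bucket.add((lesser, greater))
    families: dict[str, PosetFamily] = {}
    for gene, sp in gene_species.items():
        posets = {}
        for focal in sorted(sp):
            pairs = gene_pairs[gene].get(focal, set())
            try:
                posets[focal] = Poset.build(focal, pairs, sp)
            except AntisymmetryError as exc:
                raise ParseError(
                    f"gene {gene}, focal {focal}: {exc}", gene_lines[gene]
                ) from exc
        families[gene] = PosetFamily(gene=gene, species=sp, posets=posets)
    return families


def write_poset_file(families: Mapping[str, PosetFamily], path: str | Path) -> None:
    """Write families in the poset TSV dialect (full closed relation)."""
    path = Path(path)
    with path.open("w") as fh:
        for gene in sorted(families):
            fam = families[gene]
            fh.write("#species\t" + ",".join(sorted(fam.species)) + "\n")
            for focal in sorted(fam.posets):
                for a, b in sorted(fam.posets[focal].pairs):
                    fh.write(f"{gene}\t{focal}\t{a}\t{b}\n")
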