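"""Generate the compatible poset family from a species tree.

Walking from a leaf ``s_i`` up to the root, each successive ancestor's
subtree contributes the leaves not yet seen as the next closeness level;
the anchored poset is the strict weak order "lower level < higher level",
with species inside a level mutually incomparable.  The resulting family is
consistent, and every poset in it is compatible with the source tree.
"""

from __future__ import annotations

from .posets import Poset, PosetFamily
from .trees import STree, species_set


def generate_posets(t: STree, gene: str = "g") -> PosetFamily:
    """One anchored poset per leaf of ``t``, as a family labelled ``gene``.

    Output is the full strict relation (not covers): every pair of species
    on different levels is recorded.
    """
    posets: dict[str, Poset] = {}
    for focal in sorted(t.species):
        level: dict[str, int] = {focal: 0}
        node = t.leaf(focal)
        lvl = 0
        while node.parent is not None:
            node = node.parent
            new = species_set(t, node) - level.keys()
            if new:
                lvl += 1
                for s in new:
                    level[s] = lvl
        pairs = frozenset(
            (a, b) for a in level for b in level if level[a] < level[b]
        )
        posets[focal] = Poset(focal=focal, species=t.species, pairs=pairs)
    return PosetFamily(gene=gene, species=t.species, posets=posets)
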