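# Methods

## Model and assumptions

posethgt treats phylogenetic signal per gene as a family of
species-anchored strict partial orders.  An *sᵢ-poset* over the species
set *S* has sᵢ as unique minimum; a pair (a, b) asserts that a is strictly
closer to sᵢ than b.  The canonical internal form is the strict relation
(<): reflexive pairs are never stored, the pair set is kept transitively
closed, and input given as Hasse covers closes to the same object as the
full relation.

A rooted species tree (S-tree) has leaves bijectively labelled by *S* and
every internal outdegree ≥ 2.  The framework is purely topological — no
branch lengths, no dating.  A poset is *compatible* with a tree when, for
every asserted (sⱼ, sₖ), MRCA(sᵢ, sₖ) is at most as deep as MRCA(sᵢ, sⱼ);
incomparable species impose no constraint.  This depth formulation is
equivalent to requiring the leaf-to-leaf path from sᵢ to sₖ to pass
through MRCA(sᵢ, sⱼ), which is what the test suite's independent oracle
checks by literal path enumeration.  A family is *consistent* when
sⱼ ≤ᵢ sₖ always implies sᵢ ≤ⱼ sₖ; consistency makes the sibling matrix
symmetric and is what tree construction requires.

Key assumptions inherited by the whole pipeline:

- Closeness orders are correct and complete for constructible genes; a
  family with missing or wrong pairs either still reconstructs (if the
  errors cancel) or raises an inconsistency error, in which case the gene
  is reported "unconstructible" and excluded from inference rather than
  guessed at.
- Vertical descent dominates: HGT candidates are the genes whose trees
  contradict the largest cluster, so the call is meaningless if transfers
  affect half the gene set.  A tie for the largest cluster is an explicit
  no-call.
- Tree incongruence is attributed to HGT; duplication, loss and incomplete
  lineage sorting produce the same signal and are listed as confounders in
  every report, not modelled.

## Algorithms and numerical choices

**Sibling-matrix construction** is the count A(i, j) of species strictly
above sⱼ in the sᵢ-poset (diagonal −1).  Sibling groups at each round are
the connected components of the graph whose edges carry the current
maximum value.  A component that is a clique is an ordinary sibling group.
A connected non-clique component — one node tied equally to members of
otherwise unrelated groups — is placed whole under a single shared parent
(the "star rule"); this reproduces the documented multifurcating example
and is logged, since the underlying family cannot be fully consistent.
All groups at the current maximum are merged in the same round; components
are processed in order of their smallest original species label, and
merged labels are named by the sorted concatenation of their species
("s1+s2"), so construction is deterministic.  When a merge finds group
members disagreeing about an outside label, or when the matrix is
asymmetric, construction raises an inconsistency error.  When the maximum
reaches zero a single root adopts everything left.

**Poset generation** walks each leaf's path to the root; the leaves newly
contributed by each ancestor form level 1, 2, …, and the output is the
full strict weak order (every cross-level pair), not covers.  Sibling
leaves of the focal's parent are all level 1 regardless of multifurcation
size.

**2-partitions** are stored canonically (sides ordered by size, then
lexicographically) and deduplicated.  Contradiction between two partitions
is the four-nonempty-intersections rule, proven against an exhaustive
quadruple-search oracle in tests for |S| ≤ 8.  For reconstruction from a
partition set, and for partition-set unions across trees, a reserved leaf
``s0`` is hung under the root first so the two sides of a root edge stay
distinguishable; ``s0`` may not be a real species name.  Reconstruction
drops singleton-sided partitions, then repeatedly joins the smallest
pending species side (ties broken by lexicographic member order — the
processing order is otherwise unconstrained, so this is a determinism
choice) under a new parent that replaces its members throughout.
Non-contradiction makes the side family laminar, so the replacement is
always whole-group.  The minimum common refinement is reconstruction from
the union of the two augmented partition sets; contradictory inputs raise
an error naming a witness pair.

**Clustering** is sequential first-fit: each gene tree is compared with
the representative (first member) of each cluster in creation order and
joins the first it does not contradict.  Contradiction is not transitive,
so membership can depend on order; a ``strict`` mode requires
non-contradiction with every member instead.  Witness extraction picks,
for each contradicting partition pair, the lexicographically smallest
species in each of the four side intersections, yielding the two pairs
united by the candidate tree but split by the majority tree; both transfer
directions are emitted per pair because nothing in the framework resolves
direction.

## Synthetic data

The generator builds a random base tree by uniform sequential leaf
attachment (optionally collapsing internal nodes with a configurable
probability to create polytomies), gives every clean gene the base tree's
poset family, and simulates a transfer as a *leaf regraft*: the recipient
leaf is detached and reattached as the donor's sibling.  This is the
smallest topological move that creates a contradicting quartet, and it is
what the detection criterion keys on; it does not emulate sequence
evolution, rate variation, or noisy similarity scores.  Regrafting a leaf
that is already the donor's only sibling changes nothing detectable — the
generator warns in that case, and `random_transfer_pair` resamples until
the regraft genuinely contradicts the base tree.  Passing tests on these
datasets therefore show the combinatorial machinery recovers planted
topological signal exactly; they do not show robustness to the noisy,
partially inconsistent posets real similarity scores would produce — by
design, such families raise errors rather than yield trees.

Corruption utilities produce that kind of degraded input on purpose:
``drop`` removes pairs (then restores only focal minimality), ``flip``
reverses them; outputs may be invalid or inconsistent.  Score-derived
posets rank a nonnegative similarity matrix row per focal species;
strictly greater score means strictly closer, ties mean incomparable.

## Defaults that matter

- `random_stree(multifurcation_prob=0.25)` — contraction probability per
  internal node when non-binary trees are requested; 0 gives binary trees
  (the default `binary=True` skips contraction entirely).
- Simulation scale for the recovery suite: 20 genes, 1–3 injected
  transfers, 6–10 species, 50 seeded replicates — comfortably inside the
  regime where a unique majority cluster exists (≥ 17 clean genes).
- Property suites run on random trees up to 12 species, 200+ seeds, sizes
  at which exhaustive oracles and full pairwise partition comparisons
  remain cheap.
- All seeds are plain integers fed to `random.Random`; derived seeds stay
  below 2³¹.

## Degenerate inputs and edge cases

Single-species families construct a single-leaf tree; 2-species matrices
are all-zero off-diagonal and go straight to the shared root.  Newick
input with outdegree-1 chains is collapsed with a log notice; duplicate
leaf labels are parse errors.  A refinement step must take a proper subset
(≥ 2) of a node's children so both nodes keep outdegree ≥ 2.  The poset
TSV reader closes pairs transitively, auto-completes focal-minimum pairs
with a log notice, and treats reversed duplicate pairs as parse errors
with line numbers.

## Known limitations

- Recovery from inconsistent or incomplete families is out of scope; such
  genes are excluded, not repaired.
- Candidate calling depends on the sequential clustering order in
  pathological cases (a tree non-contradictory with several cluster
  representatives); the strict mode trades this for over-splitting.
- No statistical assessment of contradiction counts, no direction
  resolution, and no separation of HGT from duplication/loss/ILS.
- Supertree settings (genes with differing species sets) are unsupported:
  all trees compared must share one leaf set.
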