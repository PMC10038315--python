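# posethgt

Detect horizontal gene transfer (HGT) from species-anchored partial orders.

## The problem

Given genomes for a species set *S* = {s₁, …, sₙ} and a gene set *G*, the
relative closeness of species can be summarised per gene and per focal
species as a partial order: an *sᵢ-poset* ranks all species by closeness to
sᵢ (e.g. by ranking BLAST bit scores of the gene against each genome),
with sᵢ as the unique minimum and tied species left incomparable.  Genes
inherited vertically all induce the same species tree; a gene acquired by
horizontal transfer induces a tree that groups the donor and recipient
lineages and therefore *contradicts* the majority topology.  posethgt
implements the full pipeline:

1. **Tree construction** — from a poset family (one poset per species) build
   the compatible rooted species tree via the sibling matrix
   *A(i, j) = |{sₓ : sⱼ <ᵢ sₓ}|* (diagonal −1).  For a consistent family
   *A* is symmetric; groups of labels joined by the maximal off-diagonal
   value are siblings, get merged under a parent, and the matrix is reduced
   until all values hit zero.
2. **Poset generation** — the inverse: walking from each leaf to the root,
   the leaves newly contributed by each ancestor form closeness levels, and
   the anchored poset is the strict weak order "lower level < higher level".
3. **Contradiction** — cutting a tree edge yields a 2-partition of *S*; two
   partitions contradict when a species quadruple crosses them (equivalently,
   all four pairwise side intersections are nonempty).  Two trees contradict
   when any pair of their 2-partitions does.  Non-contradictory trees have a
   unique minimum common refinement whose 2-partition set is the union of
   theirs.
4. **HGT inference** — one tree per gene, clustered by pairwise
   contradiction; the largest cluster is the majority topology and every
   gene outside it is an HGT candidate, reported with the species pairs its
   tree unites that the majority tree separates (transfer direction is left
   as both alternatives).

## Worked example

```python
import posethgt as ph

tree = ph.parse_newick("(((s1,s2),s3),(s4,s5));")
fam = ph.generate_posets(tree)
print(ph.build_matrix(fam).to_frame())
```

```
    s1  s2  s3  s4  s5
s1  -1   3   2   0   0
s2   3  -1   2   0   0
s3   2   2  -1   0   0
s4   0   0   0  -1   3
s5   0   0   0   3  -1
```

The maximum 3 pairs s1 with s2 and s4 with s5 (three species sit strictly
above s2 in the s1-anchored poset); after merging those cherries the
reduced maximum 2 makes s3 the sibling of the {s1,s2} node, and
`ph.construct_tree(fam)` returns the original tree exactly.

End to end from the shell:

```sh
posethgt simulate --n-species 8 --n-genes 10 --hgt "g4:s3:s6" --seed 2 --out-dir demo
posethgt infer-hgt --posets demo/posets.tsv --out demo/report.json
```

The simulated dataset gives nine genes the base tree
`((((((s1,s5),s6),(s3,s4)),s8),s2),s7);` and regrafts s6 next to s3 for
gene g4.  The report clusters the nine clean genes together (majority) and
flags exactly `g4`, with first witness pairs `[["s3","s6"],["s1","s4"]]` —
the injected pair among them — and both transfer directions per pair as
possible arcs.

Other subcommands: `gen-posets`, `build-tree` (with `--emit-matrix`),
`check` (prints COMPATIBLE/CONTRADICTORY), `refine` (minimum common
refinement; exits 1 with a witness on contradictory inputs).

## Input format

Posets are tab-separated text: a `#species<TAB>s1,s2,...` header per gene
block, then `gene<TAB>focal<TAB>lesser<TAB>greater` lines meaning
*lesser < greater* in the poset anchored at *focal*.  Pairs may be Hasse
covers; transitive closure and focal-minimum completion are applied on
read.  Trees are rooted Newick (branch lengths accepted and ignored).
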