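"""2-partitions: extraction, contradiction, reconstruction, refinement."""

import random

import pytest
from hypothesis import given, strategies as st

import posethgt as ph
from posethgt.errors import ContradictionError, LabelCollisionError

from .conftest import contradict_by_quadruples, random_contraction, random_refinement


def part(a, b):
    return ph.TwoPartition(a.split(), b.split())


class TestFindTwoPartitions:
    def test_augmented_partitions_of_triple_plus_pair(self):
        t = ph.parse_newick("((s1,s2,s3),(s4,s5));")
        q = ph.find_two_partitions(t, augment=True)
        assert q == {
            part("s0", "s1 s2 s3 s4 s5"),
            part("s1", "s0 s2 s3 s4 s5"),
            part("s2", "s0 s1 s3 s4 s5"),
            part("s3", "s0 s1 s2 s4 s5"),
            part("s4", "s0 s1 s2 s3 s5"),
            part("s5", "s0 s1 s2 s3 s4"),
            part("s1 s2 s3", "s0 s4 s5"),
            part("s4 s5", "s0 s1 s2 s3"),
        }

    def test_two_leaf_tree_deduplicates(self):
        q = ph.find_two_partitions(ph.parse_newick("(s1,s2);"))
        assert q == {part("s1", "s2")}

    def test_star_tree_augmented(self):
        q = ph.find_two_partitions(ph.parse_newick("(s1,s2,s3);"), augment=True)
        assert len(q) == 4
        assert all(len(p.sides[0]) == 1 for p in q)

    def test_label_collision(self):
        t = ph.parse_newick("(s0,s1);")
        with pytest.raises(LabelCollisionError):
            ph.find_two_partitions(t, augment=True)


class TestPartitionsContradict:
    def test_crossing_quartet(self):
        assert ph.partitions_contradict(
            part("s1 s2", "s3 s4"), part("s1 s3", "s2 s4")
        )

    def test_identical_partitions(self):
        p = part("s1 s2", "s3 s4")
        assert not ph.partitions_contradict(p, part("s1 s2", "s3 s4"))

    def test_singleton_side_cannot_contradict(self):
        a = part("s1", "s2 s3 s4")
        for b in (part("s1 s2", "s3 s4"), part("s1 s3", "s2 s4"), a):
            assert not ph.partitions_contradict(a, b)

    def test_differing_universe_raises(self):
        with pytest.raises(ValueError):
            ph.partitions_contradict(part("s1", "s2"), part("s1", "s3"))

    @given(st.integers(0, 500))
    def test_agrees_with_quadruple_oracle(self, seed):
        """Intersection rule equals exhaustive witness search, |S| <= 8."""
        rng = random.Random(seed)
        n = rng.randint(4, 8)
        universe = [f"s{i}" for i in range(1, n + 1)]
        k1 = rng.randint(1, n - 1)
        k2 = rng.randint(1, n - 1)
        a_side = set(rng.sample(universe, k1))
        b_side = set(rng.sample(universe, k2))
        x = ph.TwoPartition(a_side, set(universe) - a_side)
        y = ph.TwoPartition(b_side, set(universe) - b_side)
        assert ph.partitions_contradict(x, y) == contradict_by_quadruples(x, y)


class TestTreesContradict:
    def test_conflicting_cherries(self):
        t1 = ph.parse_newick("(((s1,s2),s3),s4);")
        t2 = ph.parse_newick("(((s1,s3),s2),s4);")
        verdict = ph.trees_contradict(t1, t2)
        assert verdict
        a, b = verdict.witness
        assert ph.partitions_contradict(a, b)

    def test_refinement_never_contradicts_base(self):
        t1 = ph.parse_newick("(s1,s2,s3,s4);")
        t2 = ph.parse_newick("((s1,s2),(s3,s4));")
        assert not ph.trees_contradict(t1, t2)

    def test_identical_trees(self, caterpillar5):
        assert not ph.trees_contradict(caterpillar5, caterpillar5.copy())

    def test_leaf_set_mismatch(self, caterpillar5):
        with pytest.raises(ValueError):
            ph.trees_contradict(caterpillar5, ph.parse_newick("(s1,s2);"))

    @given(st.integers(0, 150))
    def test_own_partition_set_self_consistent(self, seed):
        """No tree's 2-partition set contains a contradicting pair."""
        rng = random.Random(seed)
        n = rng.randint(2, 10)
        t = ph.random_stree([f"s{i}" for i in range(1, n + 1)],
                            seed=rng.randrange(2**31),
                            binary=False, multifurcation_prob=0.4)
        q = sorted(ph.find_two_partitions(t, augment=True))
        for i, a in enumerate(q):
            for b in q[i + 1:]:
                assert not ph.partitions_contradict(a, b)

    @given(st.integers(0, 150))
    def test_refinements_are_non_contradictory(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 10)
        t = ph.random_stree([f"s{i}" for i in range(1, n + 1)],
                            seed=rng.randrange(2**31),
                            binary=False, multifurcation_prob=0.6)
        refined = random_refinement(t, rng)
        assert not ph.trees_contradict(t, refined)
        assert ph.find_two_partitions(t) <= ph.find_two_partitions(refined)


class TestConstructFromPartitions:
    def test_worked_nine_partition_set(self):
        q = {
            part("s0", "s1 s2 s3 s4 s5"),
            part("s1", "s0 s2 s3 s4 s5"),
            part("s2", "s0 s1 s3 s4 s5"),
            part("s3", "s0 s1 s2 s4 s5"),
            part("s4", "s0 s1 s2 s3 s5"),
            part("s5", "s0 s1 s2 s3 s4"),
            part("s1 s2", "s0 s3 s4 s5"),
            part("s1 s2 s3", "s0 s4 s5"),
            part("s0 s1 s2 s3", "s4 s5"),
        }
        t = ph.construct_tree_from_partitions(q)
        assert t == ph.parse_newick("(((s1,s2),s3),(s4,s5));")

    def test_star_only_singletons(self):
        q = ph.find_two_partitions(ph.parse_newick("(s1,s2,s3);"), augment=True)
        t = ph.construct_tree_from_partitions(q)
        assert t == ph.parse_newick("(s1,s2,s3);")

    def test_contradicting_set_raises(self):
        q = {
            part("s1 s2", "s0 s3 s4"),
            part("s1 s3", "s0 s2 s4"),
        }
        with pytest.raises(ContradictionError):
            ph.construct_tree_from_partitions(q)

    @given(st.integers(0, 150))
    def test_inverts_find_two_partitions(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 10)
        t = ph.random_stree([f"s{i}" for i in range(1, n + 1)],
                            seed=rng.randrange(2**31),
                            binary=False, multifurcation_prob=0.4)
        q = ph.find_two_partitions(t, augment=True)
        assert ph.construct_tree_from_partitions(q) == t


class TestMinCommonRefinement:
    def test_one_step_refinement_example(self):
        t1 = ph.parse_newick("((s1,s2),s3,s4);")
        t2 = ph.parse_newick("((s1,s2),(s3,s4));")
        assert ph.min_common_refinement(t1, t2) == t2

    def test_triple_pair_example(self):
        t1 = ph.parse_newick("((s1,s2,s3),(s4,s5));")
        t2 = ph.parse_newick("(((s1,s2),s3),s4,s5);")
        t3 = ph.min_common_refinement(t1, t2)
        assert t3 == ph.parse_newick("(((s1,s2),s3),(s4,s5));")
        union = (ph.find_two_partitions(t1, augment=True)
                 | ph.find_two_partitions(t2, augment=True))
        assert ph.find_two_partitions(t3, augment=True) == union
        assert len(union) == 9

    def test_idempotent(self, caterpillar5):
        assert ph.min_common_refinement(caterpillar5, caterpillar5) == caterpillar5

    def test_contradictory_inputs_raise_with_witness(self, quartet_majority, quartet_transfer):
        with pytest.raises(ContradictionError) as exc:
            ph.min_common_refinement(quartet_majority, quartet_transfer)
        assert exc.value.witness is not None

    @given(st.integers(0, 150))
    def test_partition_union_equality(self, seed):
        """The refinement's partition set is exactly the union of the inputs'."""
        rng = random.Random(seed)
        n = rng.randint(3, 10)
        base = ph.random_stree([f"s{i}" for i in range(1, n + 1)],
                               seed=rng.randrange(2**31),
                               binary=False, multifurcation_prob=0.3)
        t1 = random_contraction(base, rng)
        t2 = random_contraction(base, rng)
        q1 = ph.find_two_partitions(t1, augment=True)
        q2 = ph.find_two_partitions(t2, augment=True)
        t3 = ph.min_common_refinement(t1, t2)
        assert ph.find_two_partitions(t3, augment=True) == q1 | q2
        # the result refines both inputs (partition-superset criterion)
        assert q1 <= ph.find_two_partitions(t3, augment=True)
        assert q2 <= ph.find_two_partitions(t3, augment=True)
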