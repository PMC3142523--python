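"""Triplet extraction, retention rule, and the Eq.-style dissimilarities."""

from fractions import Fraction

import numpy as np
import pytest

from tripdist import (
    BootstrapForest,
    UndefinedTripletDistance,
    count_forest_triplets,
    extract_triplets,
    forest_forest_distance,
    pairwise_matrix,
    parse_newick,
    retained_triplets,
    tree_forest_distance,
)
from tripdist.triplets import (
    NonBinaryReferenceError,
    retained_resolution_codes,
)

from oracles import (
    oracle_triplets,
    random_tuple_tree,
    tuple_to_newick,
)


class TestExtract:
    def test_three_leaf_tree(self):
        assert extract_triplets(parse_newick("((a,b),c);")) == {
            frozenset("abc"): frozenset("ab")
        }

    def test_balanced_quartet_all_four_triplets(self, quartet):
        assert extract_triplets(quartet) == {
            frozenset("abc"): frozenset("ab"),
            frozenset("abd"): frozenset("ab"),
            frozenset("acd"): frozenset("cd"),
            frozenset("bcd"): frozenset("cd"),
        }

    def test_star_is_unresolved(self):
        assert extract_triplets(parse_newick("(a,b,c);")) == {frozenset("abc"): None}

    def test_too_few_leaves_raises(self):
        with pytest.raises(ValueError):
            extract_triplets(parse_newick("(a,b);"))

    def test_matches_oracle_on_random_trees(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(30):
            tup = random_tuple_tree(labels, rng)
            tree = parse_newick(tuple_to_newick(tup))
            assert extract_triplets(tree) == oracle_triplets(tup)


class TestForestCounts:
    def test_identical_copies(self, quartet):
        table = count_forest_triplets(BootstrapForest("L", [quartet] * 100))
        assert table.n_trees == 100
        assert np.all(table.counts.max(axis=1) == 100)
        assert np.all(table.absent == 0)

    def test_two_conflicting_trees(self):
        f = BootstrapForest(
            "L", [parse_newick("((a,b),c);"), parse_newick("((a,c),b);")]
        )
        table = count_forest_triplets(f)
        # single triple {a,b,c}: ab|c once, ac|b once
        assert table.counts.tolist() == [[1, 1, 0, 0]]

    def test_star_counts_as_unresolved(self):
        f = BootstrapForest("L", [parse_newick("(a,b,c);"), parse_newick("((a,b),c);")])
        table = count_forest_triplets(f)
        assert table.counts.tolist() == [[1, 0, 0, 1]]

    def test_missing_leafset_counts_absent(self):
        f = BootstrapForest(
            "L",
            [parse_newick("((a,b),(c,d));"), parse_newick("((a,b),c);")],
            taxa={"a", "b", "c", "d"},
        )
        table = count_forest_triplets(f)
        trio_of = dict(zip(table.taxa, range(4)))
        assert table.absent.sum() == 3  # abd, acd, bcd absent in second tree


class TestRetention:
    def _table(self, n_majority, alt="((a,c),b);", n=100):
        trees = [parse_newick("((a,b),c);")] * n_majority
        trees += [parse_newick(alt)] * (n - n_majority)
        return count_forest_triplets(BootstrapForest("L", trees))

    def test_majority_51_retained(self):
        assert retained_triplets(self._table(51)) == {
            frozenset("abc"): frozenset("ab")
        }

    def test_exact_half_dropped(self):
        assert retained_triplets(self._table(50)) == {}

    @pytest.mark.parametrize("count, kept", [(55, False), (61, True)])
    def test_sixty_percent_threshold_is_strict(self, count, kept):
        result = retained_triplets(self._table(count), threshold=0.6)
        assert bool(result) is kept

    def test_threshold_below_half_rejected(self):
        with pytest.raises(ValueError):
            retained_triplets(self._table(60), threshold=0.4)

    def test_at_most_one_resolution_per_leafset(self):
        rng = np.random.default_rng(1)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(20):
            trees = [
                parse_newick(tuple_to_newick(random_tuple_tree(labels, rng)))
                for _ in range(9)
            ]
            table = count_forest_triplets(BootstrapForest("L", trees))
            codes = retained_resolution_codes(table, Fraction(1, 2))
            retained = retained_triplets(table)
            assert len(retained) == int(np.sum(codes >= 0))

    def test_present_denominator_option(self):
        trees = [parse_newick("((a,b),c);")] * 2 + [parse_newick("((a,b),(c,d));")] * 2
        table = count_forest_triplets(BootstrapForest("L", trees, taxa="abcd"))
        strict = retained_triplets(table, denominator="forest")
        lenient = retained_triplets(table, denominator="present")
        # abd/acd/bcd present in only 2 of 4 trees: retained only under the
        # present-trees denominator
        assert frozenset("abd") not in strict
        assert lenient[frozenset("abd")] == frozenset("ab")


class TestTreeForestDistance:
    def test_identity_forest(self, quartet):
        cmp_ = tree_forest_distance(quartet, BootstrapForest("L", [quartet] * 100))
        assert cmp_.distance == 0.0 and cmp_.n_same == 4

    def test_fully_conflicting_forest(self, quartet, conflicting_quartet):
        cmp_ = tree_forest_distance(
            quartet, BootstrapForest("L", [conflicting_quartet] * 100)
        )
        assert cmp_.distance == 1.0 and cmp_.n_diff == 4

    def test_sixty_forty_mixture_matches_reference(self, quartet, conflicting_quartet):
        forest = BootstrapForest(
            "L", [quartet] * 60 + [conflicting_quartet] * 40
        )
        cmp_ = tree_forest_distance(quartet, forest)
        assert cmp_.distance == 0.0
        assert cmp_.n_retained == 4  # every triple keeps the 60% resolution

    def test_no_retained_triplets_is_explicit(self, quartet, conflicting_quartet):
        forest = BootstrapForest("L", [quartet] * 50 + [conflicting_quartet] * 50)
        cmp_ = tree_forest_distance(quartet, forest)
        with pytest.raises(UndefinedTripletDistance):
            cmp_.distance

    def test_nonbinary_reference_rejected(self, quartet):
        star = parse_newick("(a,b,c,d);")
        with pytest.raises(NonBinaryReferenceError):
            tree_forest_distance(star, BootstrapForest("L", [quartet] * 10))

    def test_monotone_contamination(self, quartet, conflicting_quartet):
        distances = []
        for k in range(0, 101, 10):
            forest = BootstrapForest(
                "L", [quartet] * k + [conflicting_quartet] * (100 - k)
            )
            cmp_ = tree_forest_distance(quartet, forest)
            try:
                distances.append(cmp_.distance)
            except UndefinedTripletDistance:
                distances.append(None)  # k == 50: nothing retained
        defined = [d for d in distances if d is not None]
        assert all(a >= b for a, b in zip(defined, defined[1:]))
        assert all(d == 0.0 for k, d in zip(range(0, 101, 10), distances)
                   if d is not None and k > 50)

    def test_thresholds_agree_when_support_exceeds_sixty(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(7)]
        ref_tup = random_tuple_tree(labels, rng)
        ref = parse_newick(tuple_to_newick(ref_tup))
        # forest dominated by one topology: every retained triple has
        # support >= 80/100 > 60%
        other = parse_newick(tuple_to_newick(random_tuple_tree(labels, rng)))
        forest = BootstrapForest("L", [ref] * 80 + [other] * 20)
        d50 = tree_forest_distance(ref, forest, threshold=0.5)
        d60 = tree_forest_distance(ref, forest, threshold=0.6)
        table = count_forest_triplets(forest)
        if np.all(table.counts.max(axis=1) > 60):
            assert d50.distance == d60.distance


class TestForestForestDistance:
    def test_identity(self, quartet):
        f = BootstrapForest("A", [quartet] * 10)
        assert forest_forest_distance(f, f).distance == 0.0

    def test_fully_conflicting(self, quartet, conflicting_quartet):
        fa = BootstrapForest("A", [quartet] * 100)
        fb = BootstrapForest("B", [conflicting_quartet] * 100)
        assert forest_forest_distance(fa, fb).distance == 1.0

    def test_symmetry_on_random_forests(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(6)]

        def forest(locus):
            trees = [
                parse_newick(tuple_to_newick(random_tuple_tree(labels, rng)))
                for _ in range(7)
            ]
            return BootstrapForest(locus, trees)

        for _ in range(5):
            fa, fb = forest("A"), forest("B")
            ab = forest_forest_distance(fa, fb)
            ba = forest_forest_distance(fb, fa)
            assert (ab.n_same, ab.n_diff) == (ba.n_same, ba.n_diff)

    def test_one_sided_retention_diagnostic(self, quartet, conflicting_quartet):
        fa = BootstrapForest("A", [quartet] * 10)
        fb = BootstrapForest(
            "B", [quartet] * 5 + [conflicting_quartet] * 5
        )  # nothing retained in B
        cmp_ = forest_forest_distance(fa, fb)
        assert cmp_.n_retained == 0
        assert cmp_.n_one_sided == 4


class TestPairwiseMatrix:
    def test_identical_forests_zero_matrix(self, quartet):
        forests = [BootstrapForest(f"L{i}", [quartet] * 5) for i in range(3)]
        M = pairwise_matrix(forests)
        assert np.allclose(M.values, 0.0)

    def test_composition_with_conflict(self, quartet, conflicting_quartet):
        fa = BootstrapForest("A1", [quartet] * 10)
        fa2 = BootstrapForest("A2", [quartet] * 10)
        fb = BootstrapForest("B", [conflicting_quartet] * 10)
        M = pairwise_matrix([fa, fa2, fb])
        assert M.values.tolist() == [[0, 0, 1], [0, 0, 1], [1, 1, 0]]

    def test_shape_and_symmetry_on_synthetic_study(self, small_study):
        mask = small_study.annotations["rel_dist_centromere"].notna()
        forests = [f for f, ok in zip(small_study.forests, mask) if ok]
        M = pairwise_matrix(forests)
        n = len(forests)
        assert M.values.shape == (n, n)
        assert np.allclose(M.values, M.values.T, equal_nan=True)
        assert np.allclose(np.diag(M.values), 0.0)
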