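"""Rooted-triplet extraction, retention, and the triplet-fit dissimilarities.

For three leaves {a, b, c} of a rooted tree the *triplet resolution* states
which pair is more closely related: ab|c means the MRCA of (a, b) is a strict
descendant of the MRCA of the whole triple.  A triple whose three pairwise
MRCAs coincide (a polytomy) is UNRESOLVED.

Over a bootstrap forest the per-triple resolution counts give a frequency
table; a triple is *retained* when one resolution appears in strictly more
than a threshold fraction (default 50%) of the forest's trees, which
guarantees at most one retained resolution per triple.  The dissimilarity
between a reference tree T_s and a forest F (and between two forests) is the
fraction of retained triples resolved differently:

    d = n_diff / (n_same + n_diff)

Internally, resolutions are encoded as small integers over the triples of a
fixed taxon ordering, so forests are tabulated with vectorized numpy ops:
code 0 = ab|c, 1 = ac|b, 2 = bc|a (a < b < c in the taxon order),
3 = unresolved, 4 = leaf absent from the tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .treeio import BootstrapForest, PhyloTree

__all__ = [
    "UNRESOLVED",
    "ABSENT",
    "TripletFrequencyTable",
    "TripletComparison",
    "DistanceMatrix",
    "UndefinedTripletDistance",
    "NonBinaryReferenceError",
    "triplet_index",
    "mrca_depth_matrix",
    "triplet_codes",
    "extract_triplets",
    "count_forest_triplets",
    "retained_resolution_codes",
    "retained_triplets",
    "tree_forest_distance",
    "forest_forest_distance",
    "pairwise_matrix",
]

UNRESOLVED = 3
ABSENT = 4
NOT_RETAINED = -1


class UndefinedTripletDistance(ValueError):
    """No jointly retained triplet: the dissimilarity has an empty denominator."""


class NonBinaryReferenceError(ValueError):
    """The reference tree is not fully resolved on the comparison leaf set."""


@lru_cache(maxsize=64)
def triplet_index(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays (I, J, K), I < J < K, enumerating the C(n,3) triples of
    ``range(n)`` in lexicographic order."""
    if n < 3:
        raise ValueError("need at least 3 taxa")
    combos = np.array(list(combinations(range(n), 3)), dtype=np.intp)
    return combos[:, 0], combos[:, 1], combos[:, 2]


def mrca_depth_matrix(tree: PhyloTree, index: dict[str, int]) -> np.ndarray:
    """n x n matrix of pairwise MRCA depths (edges from the root), restricted
    to the taxa in ``index``; -1 marks pairs with an absent leaf."""
    n = len(index)
    D = np.full((n, n), -1, dtype=np.int32)
    root = tree.dendropy_tree.seed_node
    # postorder: collect per-node lists of leaf indices, assign MRCA depths
    # for pairs that straddle distinct child subtrees
    depth = {root: 0}
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd is not root:
            depth[nd] = depth[nd.parent_node] + 1
    leaves_below: dict = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            i = index.get(nd.taxon.label)
            leaves_below[nd] = [i] if i is not None else []
            if i is not None:
                D[i, i] = depth[nd]
            continue
        child_lists = [leaves_below.pop(ch) for ch in nd.child_nodes()]
        d = depth[nd]
        for a in range(len(child_lists)):
            la = child_lists[a]
            if not la:
                continue
            for b in range(a + 1, len(child_lists)):
                lb = child_lists[b]
                if not lb:
                    continue
                D[np.ix_(la, lb)] = d
                D[np.ix_(lb, la)] = d
        leaves_below[nd] = [i for lst in child_lists for i in lst]
    return D


def triplet_codes(tree: PhyloTree, taxa: Sequence[str]) -> np.ndarray:
    """Resolution code per triple of ``taxa`` (lexicographic triple order).

    Codes: 0 = ab|c, 1 = ac|b, 2 = bc|a with (a, b, c) the triple in taxon
    order; 3 = unresolved (shared MRCA); 4 = a leaf absent from the tree.
    """
    taxa = list(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    D = mrca_depth_matrix(tree, index)
    I, J, K = triplet_index(len(taxa))
    dab, dac, dbc = D[I, J], D[I, K], D[J, K]
    codes = np.full(len(I), UNRESOLVED, dtype=np.int8)
    codes[(dab > dac) & (dab > dbc)] = 0
    codes[(dac > dab) & (dac > dbc)] = 1
    codes[(dbc > dab) & (dbc > dac)] = 2
    present = np.diag(D) >= 0
    codes[~(present[I] & present[J] & present[K])] = ABSENT
    return codes


def extract_triplets(tree: PhyloTree):
    """Map each 3-leaf subset to its cherry pair, or ``None`` if unresolved.

    Returns ``{frozenset({a,b,c}): frozenset({x,y}) | None}`` where {x, y}
    is the pair more closely related than either is to the third leaf.
    """
    if tree.n_leaves < 3:
        raise ValueError("triplet extraction needs >= 3 leaves")
    taxa = sorted(tree.leaf_labels)
    codes = triplet_codes(tree, taxa)
    I, J, K = triplet_index(len(taxa))
    out = {}
    for idx in range(len(codes)):
        a, b, c = taxa[I[idx]], taxa[J[idx]], taxa[K[idx]]
        code = codes[idx]
        if code == 0:
            cherry = frozenset((a, b))
        elif code == 1:
            cherry = frozenset((a, c))
        elif code == 2:
            cherry = frozenset((b, c))
        else:
            cherry = None
        out[frozenset((a, b, c))] = cherry
    return out


@dataclass
class TripletFrequencyTable:
    """Per-triple resolution counts over a forest.

    ``counts[t]`` holds (ab|c, ac|b, bc|a, unresolved) counts for triple t of
    ``taxa`` (lexicographic order); ``absent[t]`` counts member trees missing
    at least one of the triple's leaves.  Row sums + absent == n_trees.
    """

    taxa: tuple
    counts: np.ndarray  # (n_triplets, 4) int64
    absent: np.ndarray  # (n_triplets,) int64
    n_trees: int

    def __post_init__(self):
        total = self.counts.sum(axis=1) + self.absent
        if not np.all(total == self.n_trees):
            raise ValueError("triplet counts do not sum to the forest size")

    @property
    def n_triplets(self) -> int:
        return self.counts.shape[0]


def count_forest_triplets(
    forest: BootstrapForest, taxa: Iterable[str] | None = None
) -> TripletFrequencyTable:
    """Tabulate resolution counts for every triple of ``taxa`` over the
    forest's trees.

    ``taxa`` defaults to the forest's nominal leaf set.  Trees repeated by
    object identity (as produced by the bootstrap simulator) are coded once.
    """
    taxa = tuple(sorted(taxa if taxa is not None else forest.taxa))
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa to tabulate triplets")
    I, _, _ = triplet_index(len(taxa))
    counts = np.zeros((len(I), 4), dtype=np.int64)
    absent = np.zeros(len(I), dtype=np.int64)
    cache: dict[int, np.ndarray] = {}
    eye = np.eye(5, dtype=np.int64)
    for tree in forest.trees:
        codes = cache.get(id(tree))
        if codes is None:
            codes = triplet_codes(tree, taxa)
            cache[id(tree)] = codes
        onehot = eye[codes]
        counts += onehot[:, :4]
        absent += onehot[:, 4]
    return TripletFrequencyTable(taxa=taxa, counts=counts, absent=absent,
                                 n_trees=len(forest.trees))


def _as_fraction(threshold) -> Fraction:
    if isinstance(threshold, Fraction):
        return threshold
    # route floats through their decimal repr so 0.6 means 3/5 exactly
    return Fraction(str(threshold))


def retained_resolution_codes(
    table: TripletFrequencyTable,
    threshold=Fraction(1, 2),
    denominator: str = "forest",
) -> np.ndarray:
    """Retained resolution code per triple (0/1/2), or -1 where no resolution
    clears the threshold.

    A resolution is retained iff ``count > threshold * N`` with strict
    inequality, compared in exact integer arithmetic; with threshold >= 1/2
    at most one resolution can qualify.  ``denominator`` selects N: the full
    forest size (``"forest"``, default — absent/unresolved trees count
    against retention) or the number of trees containing all three leaves
    (``"present"``).
    """
    thr = _as_fraction(threshold)
    if not (Fraction(1, 2) <= thr < 1):
        raise ValueError("retention threshold must lie in [0.5, 1)")
    if denominator == "forest":
        N = np.full(table.n_triplets, table.n_trees, dtype=np.int64)
    elif denominator == "present":
        N = table.n_trees - table.absent
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    res = table.counts[:, :3]
    best = res.argmax(axis=1)
    best_count = res.max(axis=1)
    ok = best_count * thr.denominator > thr.numerator * N
    out = np.where(ok, best, NOT_RETAINED).astype(np.int8)
    return out


def retained_triplets(
    table: TripletFrequencyTable, threshold=Fraction(1, 2),
    denominator: str = "forest",
):
    """Retained triples as ``{frozenset({a,b,c}): frozenset(cherry pair)}``."""
    codes = retained_resolution_codes(table, threshold, denominator)
    I, J, K = triplet_index(len(table.taxa))
    taxa = table.taxa
    out = {}
    for idx in np.nonzero(codes != NOT_RETAINED)[0]:
        a, b, c = taxa[I[idx]], taxa[J[idx]], taxa[K[idx]]
        cherry = {0: (a, b), 1: (a, c), 2: (b, c)}[int(codes[idx])]
        out[frozenset((a, b, c))] = frozenset(cherry)
    return out


@dataclass
class TripletComparison:
    """Outcome of a triplet-fit comparison (reference-vs-forest or
    forest-vs-forest)."""

    n_same: int
    n_diff: int
    threshold: Fraction
    n_retained: int        # triples entering the comparison
    n_skipped: int         # candidate triples excluded (not retained / absent)
    n_one_sided: int = 0   # retained in exactly one forest (Eq. 3 diagnostic)

    @property
    def distance(self) -> float:
        total = self.n_same + self.n_diff
        if total == 0:
            raise UndefinedTripletDistance("no jointly retained triplets")
        return self.n_diff / total


def _shared_taxa(a: Iterable[str], b: Iterable[str]) -> tuple:
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared leaves for a triplet comparison, got {len(shared)}"
        )
    return tuple(shared)


def tree_forest_distance(
    reference: PhyloTree,
    forest: BootstrapForest,
    threshold=Fraction(1, 2),
    denominator: str = "forest",
) -> TripletComparison:
    """Triplet-fit dissimilarity between a reference tree T_s and a bootstrap
    forest F_j.

    The comparison runs over the triples of the shared leaf set that are
    retained in the forest at ``threshold``; the distance is the fraction of
    those resolved differently from T_s.  T_s must be fully resolved on the
    shared leaves.
    """
    taxa = _shared_taxa(reference.leaf_labels, forest.taxa)
    ref_codes = triplet_codes(reference, taxa)
    if np.any(ref_codes == UNRESOLVED):
        raise NonBinaryReferenceError(
            "reference tree has unresolved triples on the shared leaf set; "
            "apply resolve_polytomies() or restrict the leaf set first"
        )
    table = count_forest_triplets(forest, taxa)
    ret = retained_resolution_codes(table, threshold, denominator)
    mask = ret != NOT_RETAINED
    n_same = int(np.sum(mask & (ret == ref_codes)))
    n_diff = int(np.sum(mask & (ret != ref_codes)))
    return TripletComparison(
        n_same=n_same,
        n_diff=n_diff,
        threshold=_as_fraction(threshold),
        n_retained=int(mask.sum()),
        n_skipped=int((~mask).sum()),
    )


def forest_forest_distance(
    forest_a: BootstrapForest,
    forest_b: BootstrapForest,
    threshold=Fraction(1, 2),
    denominator: str = "forest",
) -> TripletComparison:
    """Triplet-fit dissimilarity between two bootstrap forests.

    Only triples retained in *both* forests enter the comparison; triples
    retained in exactly one are reported in ``n_one_sided``.  Symmetric in
    its arguments.
    """
    taxa = _shared_taxa(forest_a.taxa, forest_b.taxa)
    ra = retained_resolution_codes(count_forest_triplets(forest_a, taxa),
                                   threshold, denominator)
    rb = retained_resolution_codes(count_forest_triplets(forest_b, taxa),
                                   threshold, denominator)
    both = (ra != NOT_RETAINED) & (rb != NOT_RETAINED)
    one = (ra != NOT_RETAINED) ^ (rb != NOT_RETAINED)
    n_same = int(np.sum(both & (ra == rb)))
    n_diff = int(np.sum(both & (ra != rb)))
    return TripletComparison(
        n_same=n_same,
        n_diff=n_diff,
        threshold=_as_fraction(threshold),
        n_retained=int(both.sum()),
        n_skipped=int((~both).sum()),
        n_one_sided=int(one.sum()),
    )


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal distance matrix over labeled loci.

    Entries whose pairwise comparison was undefined (no jointly retained
    triplet) hold NaN and are listed in ``undefined``.
    """

    labels: tuple
    values: np.ndarray
    undefined: list

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(np.isnan(v), np.isnan(v.T)) or not np.allclose(
            v[~np.isnan(v)], v.T[~np.isnan(v.T)]
        ):
            raise ValueError("matrix must be symmetric")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_matrix(
    forests: Sequence[BootstrapForest],
    threshold=Fraction(1, 2),
    denominator: str = "forest",
) -> DistanceMatrix:
    """Symmetric matrix M of forest-forest triplet distances, M_ij =
    d(F_i, F_j); undefined pairs are NaN-flagged."""
    if len(forests) < 2:
        raise ValueError("need >= 2 forests")
    labels = tuple(f.locus for f in forests)
    n = len(forests)
    # precompute retained codes per forest on its own taxa? comparisons need
    # the pairwise shared taxon set, so cache full-taxa tables when equal
    values = np.zeros((n, n), dtype=float)
    undefined = []
    cache: dict[tuple, np.ndarray] = {}

    all_taxa = sorted(set().union(*(set(f.taxa) for f in forests)))

    def codes_for(i: int, taxa: tuple) -> np.ndarray:
        key = (i, taxa)
        if key not in cache:
            cache[key] = retained_resolution_codes(
                count_forest_triplets(forests[i], taxa), threshold, denominator
            )
        return cache[key]

    for i in range(n):
        for j in range(i + 1, n):
            taxa = tuple(sorted(set(forests[i].taxa) & set(forests[j].taxa)))
            if set(taxa) == set(all_taxa):
                taxa = tuple(all_taxa)
            ra, rb = codes_for(i, taxa), codes_for(j, taxa)
            both = (ra != NOT_RETAINED) & (rb != NOT_RETAINED)
            n_same = int(np.sum(both & (ra == rb)))
            n_diff = int(np.sum(both & (ra != rb)))
            if n_same + n_diff == 0:
                values[i, j] = values[j, i] = np.nan
                undefined.append((labels[i], labels[j]))
            else:
                values[i, j] = values[j, i] = n_diff / (n_same + n_diff)
    return DistanceMatrix(labels=labels, values=values, undefined=undefined)
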