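"""Independent brute-force oracles for the triplet machinery.

Everything here works on nested-tuple tree representations and plain
dictionaries — no shared code with the package's MRCA-depth encoding.
"""

from itertools import combinations


def all_rooted_binary_trees(labels):
    """Every rooted binary leaf-labeled tree on ``labels`` as nested tuples.

    Built by inserting each new leaf on every edge (including above the
    root); yields (2n-3)!! trees for n leaves.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need >= 2 labels")

    def insert_everywhere(tree, leaf):
        # attach above the current (sub)tree root
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for sub in insert_everywhere(left, leaf):
                yield (sub, right)
            for sub in insert_everywhere(right, leaf):
                yield (left, sub)

    trees = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        trees = [t for base in trees for t in insert_everywhere(base, leaf)]
    return trees


def tuple_to_newick(tree) -> str:
    def rec(t):
        if isinstance(t, tuple):
            return "(" + ",".join(rec(c) for c in t) + ")"
        return t

    return rec(tree) + ";"


def leafset(tree):
    if isinstance(tree, tuple):
        out = set()
        for child in tree:
            out |= leafset(child)
        return out
    return {tree}


def subtree_leafsets(tree):
    """Leaf sets of every (sub)tree, including leaves and the root."""
    out = [leafset(tree)]
    if isinstance(tree, tuple):
        for child in tree:
            out.extend(subtree_leafsets(child))
    return out


def oracle_triplets(tree):
    """{frozenset{a,b,c}: frozenset cherry | None} by clade containment: the
    cherry is the pair lying together in some subtree that excludes the
    third leaf."""
    sets = subtree_leafsets(tree)
    leaves = sorted(leafset(tree))
    out = {}
    for trio in combinations(leaves, 3):
        cherry = None
        for x, y in combinations(trio, 2):
            z = next(t for t in trio if t not in (x, y))
            if any(x in s and y in s and z not in s for s in sets):
                cherry = frozenset((x, y))
                break
        out[frozenset(trio)] = cherry
    return out


def oracle_forest_counts(trees, taxa):
    """{trio: {cherry|None: count, 'absent': count}} over tuple trees."""
    taxa = sorted(taxa)
    counts = {frozenset(t): {} for t in combinations(taxa, 3)}
    for tree in trees:
        present = leafset(tree)
        trip = oracle_triplets(tree) if len(present) >= 3 else {}
        for trio, slot in counts.items():
            if not trio <= present:
                slot["absent"] = slot.get("absent", 0) + 1
            else:
                res = trip[trio]
                slot[res] = slot.get(res, 0) + 1
    return counts


def oracle_retained(counts, n_trees, threshold=0.5):
    """{trio: cherry} for resolutions with count strictly above
    threshold * n_trees."""
    out = {}
    for trio, slot in counts.items():
        for res, c in slot.items():
            if res in (None, "absent"):
                continue
            if c > threshold * n_trees:
                out[trio] = res
    return out


def oracle_tree_forest_distance(ref_tree, forest_trees, taxa, threshold=0.5):
    """(n_same, n_diff) of the retained forest triplets against the
    reference tuple tree; distance = n_diff / (n_same + n_diff)."""
    ref = oracle_triplets(ref_tree)
    counts = oracle_forest_counts(forest_trees, taxa)
    retained = oracle_retained(counts, len(forest_trees), threshold)
    n_same = sum(1 for trio, res in retained.items() if ref[trio] == res)
    n_diff = sum(1 for trio, res in retained.items() if ref[trio] != res)
    return n_same, n_diff


def oracle_forest_forest_distance(trees_a, trees_b, taxa, threshold=0.5):
    ra = oracle_retained(oracle_forest_counts(trees_a, taxa), len(trees_a), threshold)
    rb = oracle_retained(oracle_forest_counts(trees_b, taxa), len(trees_b), threshold)
    joint = set(ra) & set(rb)
    n_same = sum(1 for trio in joint if ra[trio] == rb[trio])
    n_diff = sum(1 for trio in joint if ra[trio] != rb[trio])
    return n_same, n_diff


def random_tuple_tree(labels, rng):
    """Random rooted binary tree by sequential random joins."""
    lineages = list(labels)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append((a, b))
    return lineages[0]
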