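"""Rooted, leaf-labeled phylogenetic trees in Newick format.

All downstream triplet analyses are purely topological: branch lengths are
parsed (and preserved on round-trip where possible) but never interpreted,
and trees are treated as rooted exactly as written.  dendropy provides the
Newick machinery behind this module's surface; the classes here enforce the
invariants the analysis relies on (unique leaf labels, no unary nodes) and
expose only topological operations.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "BootstrapForest",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "load_forest",
    "load_forests",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a tree invariant."""


class PhyloTree:
    """A rooted leaf-labeled tree, possibly with polytomies.

    Wraps a :class:`dendropy.Tree`.  Instances are treated as immutable by
    every analysis function; all mutating operations return a new tree.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree; unary nodes are collapsed on construction.
    name : str, optional
        Free-form tag, typically a locus id.
    """

    __slots__ = ("_tree", "name", "_leaf_labels")

    def __init__(self, tree: dendropy.Tree, name: str | None = None):
        tree.suppress_unifurcations()
        self._tree = tree
        self.name = name
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(not lbl for lbl in labels):
            raise TreeValidationError("empty leaf label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dupes}")
        self._leaf_labels = frozenset(labels)

    # -- construction -------------------------------------------------

    @classmethod
    def parse(cls, newick: str, name: str | None = None) -> "PhyloTree":
        return parse_newick(newick, name=name)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "PhyloTree":
        text = Path(path).read_text()
        return parse_newick(text, name=name)

    # -- basic queries -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> frozenset:
        return self._leaf_labels

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    @property
    def is_binary(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._tree.preorder_internal_node_iter()
        )

    def write(self) -> str:
        """Newick string with a trailing semicolon."""
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True)
        return s.strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1), name=self.name)

    def __repr__(self) -> str:  # pragma: no cover
        tag = f" {self.name!r}" if self.name else ""
        return f"<PhyloTree{tag} n_leaves={self.n_leaves}>"

    # -- topological operations ---------------------------------------

    def restrict_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Induced subtree on ``keep`` ∩ leaf set.

        Unary nodes created by pruning are suppressed and their branch
        lengths summed.  Raises if fewer than two leaves survive.
        """
        keep = set(keep)
        surviving = keep & self._leaf_labels
        if len(surviving) < 2:
            raise TreeValidationError(
                f"restriction leaves {len(surviving)} leaf/leaves; need >= 2"
            )
        if surviving == self._leaf_labels:
            return self.copy()
        sub = self._tree.extract_tree_with_taxa_labels(labels=surviving)
        return PhyloTree(sub, name=self.name)

    def rerooted_on(self, outgroup: str | Iterable[str]) -> "PhyloTree":
        """Place the root on the edge subtending the outgroup.

        ``outgroup`` may be a single leaf label or a set of labels that is
        monophyletic in the tree as currently rooted.
        """
        labels = {outgroup} if isinstance(outgroup, str) else set(outgroup)
        missing = labels - self._leaf_labels
        if missing:
            raise TreeValidationError(f"outgroup labels not in tree: {sorted(missing)}")
        new = self._tree.clone(depth=1)
        if len(labels) == 1:
            (label,) = labels
            node = next(
                lf for lf in new.leaf_node_iter() if lf.taxon.label == label
            )
        else:
            taxa = [t for t in new.taxon_namespace if t.label in labels]
            node = new.mrca(taxa=taxa)
            clade = {lf.taxon.label for lf in node.leaf_iter()}
            if clade != labels:
                raise TreeValidationError(
                    "outgroup not monophyletic; smallest containing clade adds "
                    f"{sorted(clade - labels)}"
                )
        if node.parent_node is None or node.parent_node.parent_node is None:
            # root already sits on the subtending edge
            return PhyloTree(new, name=self.name)
        new.reroot_at_edge(node.edge, update_bipartitions=False)
        return PhyloTree(new, name=self.name)

    def resolve_polytomies(self, seed: int) -> "PhyloTree":
        """Randomly resolve every polytomy into bifurcations (multi2di analog).

        Deterministic for a fixed seed; binary input is returned unchanged
        (as a copy).  Every clade of the input is a clade of the output.
        """
        new = self._tree.clone(depth=1)
        rng = random.Random(seed)
        tree = dendropy.Tree(new)
        tree.resolve_polytomies(rng=rng)
        return PhyloTree(tree, name=self.name)


def parse_newick(newick: str, name: str | None = None) -> PhyloTree:
    """Parse a single-tree Newick string into a :class:`PhyloTree`.

    Labels may be quoted; underscores are preserved verbatim; internal node
    labels (e.g. support values) are parsed but unused downstream.
    """
    if not newick.strip():
        raise NewickParseError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"Newick parse failed: {exc}") from exc
    return PhyloTree(tree, name=name)


@dataclass
class BootstrapForest:
    """Ordered collection of trees for one locus (100 bootstrap trees in the
    motivating study design)."""

    locus: str
    trees: Sequence[PhyloTree]
    taxa: frozenset = field(default=None)  # nominal leaf set

    def __post_init__(self):
        if len(self.trees) < 1:
            raise TreeValidationError("forest must contain at least one tree")
        union = frozenset().union(*(t.leaf_labels for t in self.trees))
        if self.taxa is None:
            self.taxa = union
        else:
            self.taxa = frozenset(self.taxa)
            extra = union - self.taxa
            if extra:
                raise TreeValidationError(
                    f"member trees carry leaves outside the nominal set: {sorted(extra)}"
                )

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def load_forest(path: str | Path, locus: str | None = None) -> BootstrapForest:
    """Load a bootstrap forest from a multi-tree Newick file (one tree per
    line or ';'-separated)."""
    path = Path(path)
    locus = locus or path.stem
    text = path.read_text()
    chunks = [c.strip() for c in text.replace("\n", " ").split(";") if c.strip()]
    trees = [parse_newick(c + ";", name=f"{locus}#{i}") for i, c in enumerate(chunks)]
    return BootstrapForest(locus=locus, trees=trees)


def load_forests(directory: str | Path, pattern: str = "*") -> list[BootstrapForest]:
    """Load one forest per Newick file in ``directory`` (.nwk/.tre/.trees)."""
    directory = Path(directory)
    exts = {".nwk", ".tre", ".trees", ".newick"}
    files = sorted(p for p in directory.glob(pattern) if p.suffix in exts)
    if not files:
        raise FileNotFoundError(f"no Newick forest files in {directory}")
    return [load_forest(p) for p in files]
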