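"""Synthetic species trees, discordant gene trees and bootstrap forests.

The generator emulates the statistical structure the incongruence analysis
assumes, without simulating sequences or an explicit multispecies
coalescent:

* a rooted binary species tree from a random-join (Yule/coalescent
  topology) process;
* per-locus gene trees obtained by applying a Poisson number of random
  rooted nearest-neighbor-interchange (NNI) moves to the species tree, with
  mean lambda(x) = lambda0 * (1 + kappa * p(x)) where p(x) is the locus's
  genetic position normalized to [0, 1] within its arm — so telomeric loci
  are more discordant, the coupling the analysis is designed to detect;
* per-locus bootstrap forests in which each replicate is the gene tree
  itself with probability 1 - noise_rate, else the gene tree after one
  random NNI (replicates equal to the gene tree share one object, which the
  triplet tabulation exploits).

Randomness: a single master seed is expanded through numpy's SeedSequence
spawning, with a dedicated stream for the species tree and one per locus,
so adding loci never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_map import ChromosomeModel, classify_region, genetic_distance
from .treeio import BootstrapForest, PhyloTree, parse_newick

__all__ = [
    "SyntheticConfig",
    "SyntheticStudy",
    "default_layout",
    "simulate_species_tree",
    "random_nni",
    "simulate_gene_tree",
    "simulate_bootstrap_forest",
    "simulate_study",
]


def default_layout() -> list[tuple[str, float]]:
    """(arm, x) positions of the 21 chromosome-3 loci of the packaged
    annotation table — the physical layout the study design assumes."""
    from .genome_map import load_locus_annotations

    df = load_locus_annotations()
    chr3 = df[df["rel_dist_centromere"].notna()]
    return [(row.arm, float(row.rel_dist_centromere)) for row in chr3.itertuples()]


@dataclass
class SyntheticConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the motivating design: 20 taxa, 21 positioned loci laid
    out like the chromosome-3 loci of the packaged table, 6 unpositioned
    loci, 100-tree bootstrap forests, base discordance lambda0 = 1 expected
    NNI move per gene tree, position coupling kappa = 5, bootstrap noise
    0.3.
    """

    n_taxa: int = 20
    layout: Sequence[tuple[str, float]] = field(default_factory=default_layout)
    n_unpositioned: int = 6
    base_discordance: float = 1.0      # lambda0, expected NNI moves at p(x)=0
    position_coupling: float = 5.0     # kappa
    bootstrap_noise: float = 0.3       # P(replicate gets one extra NNI)
    n_bootstrap: int = 100
    chromosome_model: ChromosomeModel = field(default_factory=ChromosomeModel)
    seed: int | None = None

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.base_discordance < 0 or self.position_coupling < 0:
            raise ValueError("discordance rates must be nonnegative")
        if not (0.0 <= self.bootstrap_noise <= 1.0):
            raise ValueError("bootstrap noise must lie in [0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("need at least one bootstrap replicate")
        for arm, x in self.layout:
            if arm not in ("short", "long") or not (0.0 <= x <= 1.0):
                raise ValueError(f"bad layout entry ({arm!r}, {x})")

    @property
    def n_loci(self) -> int:
        return len(self.layout) + self.n_unpositioned


@dataclass
class SyntheticStudy:
    """Full synthetic dataset: species tree, per-locus annotations
    (DataFrame), gene trees and bootstrap forests, plus the seeds used."""

    species_tree: PhyloTree
    annotations: "object"  # pandas DataFrame
    gene_trees: list
    forests: list
    config: SyntheticConfig
    seed: int | None


def simulate_species_tree(n_taxa: int, rng) -> PhyloTree:
    """Rooted binary species tree on labels t01..tNN via uniformly random
    sequential joins (the Yule/coalescent topology process)."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(rng)
    width = max(2, len(str(n_taxa)))
    lineages = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(f"({a},{b})")
    return parse_newick(lineages[0] + ";", name="species_tree")


def _nni_candidates(tree: PhyloTree) -> list:
    """Internal non-root nodes: each defines one NNI edge (to its parent)."""
    root = tree.dendropy_tree.seed_node
    return [
        nd
        for nd in tree.dendropy_tree.preorder_internal_node_iter()
        if nd is not root
    ]


def random_nni(tree: PhyloTree, rng) -> PhyloTree:
    """One random rooted NNI: pick an internal edge (u, v), swap one child of
    v with v's sibling subtree.  Returns a new tree."""
    rng = np.random.default_rng(rng)
    new = tree.copy()
    cands = _nni_candidates(new)
    if not cands:
        return new
    v = cands[int(rng.integers(len(cands)))]
    u = v.parent_node
    siblings = [ch for ch in u.child_nodes() if ch is not v]
    s = siblings[int(rng.integers(len(siblings)))]
    children = v.child_nodes()
    c = children[int(rng.integers(len(children)))]
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)
    return PhyloTree(new.dendropy_tree, name=tree.name)


def simulate_gene_tree(species_tree: PhyloTree, mean_moves: float, rng) -> PhyloTree:
    """Gene tree = species tree after Poisson(mean_moves) random NNI moves.

    Zero moves returns the species tree itself; expected triplet distance to
    the species tree grows with the mean number of moves.
    """
    rng = np.random.default_rng(rng)
    n_moves = int(rng.poisson(mean_moves))
    tree = species_tree
    for _ in range(n_moves):
        tree = random_nni(tree, rng)
    return tree


def simulate_bootstrap_forest(
    gene_tree: PhyloTree,
    noise_rate: float,
    n_reps: int,
    rng,
    locus: str | None = None,
) -> BootstrapForest:
    """Bootstrap forest for one locus: each replicate is the gene tree, or
    with probability ``noise_rate`` the gene tree after one random NNI.

    Unperturbed replicates reuse the gene-tree object, so downstream triplet
    tabulation codes them once.
    """
    rng = np.random.default_rng(rng)
    trees = []
    for _ in range(n_reps):
        if rng.random() < noise_rate:
            trees.append(random_nni(gene_tree, rng))
        else:
            trees.append(gene_tree)
    return BootstrapForest(
        locus=locus or (gene_tree.name or "locus"),
        trees=trees,
        taxa=gene_tree.leaf_labels,
    )


def discordance_intensity(
    arm: str | None, x: float | None, config: SyntheticConfig
) -> float:
    """Expected NNI moves for a locus at (arm, x): lambda0 * (1 + kappa *
    p(x)) with p(x) the genetic position normalized within the arm;
    unpositioned loci use the midpoint intensity p = 0.5."""
    if arm is None or x is None:
        p = 0.5
    else:
        total = genetic_distance(1.0, arm, config.chromosome_model)
        p = genetic_distance(x, arm, config.chromosome_model) / total
    return config.base_discordance * (1.0 + config.position_coupling * p)


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full synthetic study: species tree, positioned +
    unpositioned loci with gene trees and bootstrap forests, and an
    annotation table in the analysis dialect."""
    import pandas as pd

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(1 + config.n_loci)
    species = simulate_species_tree(config.n_taxa, np.random.default_rng(streams[0]))

    records, gene_trees, forests = [], [], []
    layout_full: list[tuple[str | None, float | None]] = list(config.layout)
    layout_full += [(None, None)] * config.n_unpositioned
    for k, (arm, x) in enumerate(layout_full):
        locus = f"locus{k + 1:02d}"
        lam = discordance_intensity(arm, x, config)
        rng = np.random.default_rng(streams[1 + k])
        gtree = simulate_gene_tree(species, lam, rng)
        gtree.name = locus
        forest = simulate_bootstrap_forest(
            gtree, config.bootstrap_noise, config.n_bootstrap, rng, locus=locus
        )
        gene_trees.append(gtree)
        forests.append(forest)
        records.append(
            {
                "locus": locus,
                "chromosome": "3" if arm is not None else None,
                "arm": arm,
                "rel_dist_centromere": x,
                "region": classify_region(x) if x is not None else None,
                "lambda_moves": lam,
            }
        )
    annotations = pd.DataFrame.from_records(records)
    return SyntheticStudy(
        species_tree=species,
        annotations=annotations,
        gene_trees=gene_trees,
        forests=forests,
        config=config,
        seed=config.seed,
    )
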