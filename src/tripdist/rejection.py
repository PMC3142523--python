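"""Chi-square screen for triplets of a multigenic tree strongly rejected by
the pooled bootstrap gene-tree collection.

A triplet of the reference (multigenic) tree is *strongly rejected* when it
is contradicted by at least one bootstrap triplet and a chi-square frequency
test prefers the best conflicting resolution: with n_ref the pooled count of
the reference resolution and n_conf the pooled count of the most frequent
conflicting resolution,

    chi2 = (n_conf - n_ref)**2 / (n_conf + n_ref)

tested against the chi-square(1 df) critical value at the configured
confidence (2.706 at 0.9), requiring n_conf > n_ref.  The statistic is a
two-cell goodness-of-fit against a 50:50 null and is pluggable should a
different pairwise frequency test be preferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .treeio import BootstrapForest, PhyloTree
from .triplets import (
    NonBinaryReferenceError,
    TripletFrequencyTable,
    UNRESOLVED,
    count_forest_triplets,
    triplet_codes,
    triplet_index,
)

__all__ = [
    "RejectedTriplet",
    "pairwise_chi_square",
    "pooled_triplet_counts",
    "strongly_rejected_triplets",
    "per_taxon_counts",
]


def pairwise_chi_square(n_ref: int, n_conf: int) -> float:
    """Two-cell goodness-of-fit statistic between the reference and the best
    conflicting resolution under an equal-frequency null; 1 df."""
    total = n_ref + n_conf
    if total == 0:
        return 0.0
    return (n_conf - n_ref) ** 2 / total


@dataclass(frozen=True)
class RejectedTriplet:
    """One screened triple of the reference tree."""

    leaves: frozenset          # the 3 taxa
    ref_cherry: frozenset      # reference resolution's cherry pair
    conf_cherry: frozenset     # best conflicting resolution's cherry pair
    n_ref: int
    n_conf: int
    chi2: float
    rejected: bool


def pooled_triplet_counts(
    forests: Sequence[BootstrapForest], taxa: Iterable[str]
) -> TripletFrequencyTable:
    """Resolution counts pooled over the concatenation of all forests'
    trees (2,700 trees in the motivating design: 27 loci x 100)."""
    taxa = tuple(sorted(taxa))
    pooled = None
    for forest in forests:
        t = count_forest_triplets(forest, taxa)
        if pooled is None:
            pooled = t
        else:
            pooled = TripletFrequencyTable(
                taxa=taxa,
                counts=pooled.counts + t.counts,
                absent=pooled.absent + t.absent,
                n_trees=pooled.n_trees + t.n_trees,
            )
    if pooled is None:
        raise ValueError("no forests supplied")
    return pooled


def strongly_rejected_triplets(
    reference: PhyloTree,
    forests: Sequence[BootstrapForest],
    confidence: float = 0.9,
    statistic: Callable[[int, int], float] = pairwise_chi_square,
    keep_all: bool = False,
) -> list[RejectedTriplet]:
    """Screen every triple of the reference tree against the pooled
    bootstrap collection.

    Returns the strongly rejected triples (or every screened triple when
    ``keep_all``).  ``confidence`` sets the chi-square(1) critical value;
    it is a confidence level, not a p-value.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    critical = sps.chi2.ppf(confidence, df=1)
    taxa = tuple(sorted(set(reference.leaf_labels) &
                        set().union(*(set(f.taxa) for f in forests))))
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa shared by reference and forests")
    ref_codes = triplet_codes(reference, taxa)
    if np.any(ref_codes == UNRESOLVED):
        raise NonBinaryReferenceError(
            "reference tree must be fully resolved on the pooled taxon set"
        )
    pooled = pooled_triplet_counts(forests, taxa)
    I, J, K = triplet_index(len(taxa))
    out = []
    for idx in range(len(ref_codes)):
        rc = int(ref_codes[idx])
        row = pooled.counts[idx, :3]
        n_ref = int(row[rc])
        conflicting = [c for c in range(3) if c != rc]
        cc = max(conflicting, key=lambda c: row[c])
        n_conf = int(row[cc])
        chi2 = statistic(n_ref, n_conf)
        rejected = n_conf >= 1 and n_conf > n_ref and chi2 > critical
        if rejected or keep_all:
            a, b, c = taxa[I[idx]], taxa[J[idx]], taxa[K[idx]]
            trio = (a, b, c)
            cherry = lambda code: frozenset(
                {0: (a, b), 1: (a, c), 2: (b, c)}[code]
            )
            out.append(
                RejectedTriplet(
                    leaves=frozenset(trio),
                    ref_cherry=cherry(rc),
                    conf_cherry=cherry(cc),
                    n_ref=n_ref,
                    n_conf=n_conf,
                    chi2=chi2,
                    rejected=rejected,
                )
            )
    return out


def per_taxon_counts(
    rejected: Iterable[RejectedTriplet], taxa: Iterable[str]
) -> pd.Series:
    """Number of strongly rejected triplets each taxon belongs to.

    Taxa never involved are reported with count 0; the column sum equals
    3 x (number of rejected triplets).
    """
    counts = pd.Series(0, index=sorted(taxa), dtype=int, name="n_rejected")
    for rt in rejected:
        if not rt.rejected:
            continue
        for leaf in rt.leaves:
            if leaf in counts.index:
                counts[leaf] += 1
    return counts
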