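"""Genetic-map coordinates along Triticeae-style chromosome arms.

Recombination intensity in large cereal chromosomes increases steeply from
centromere to telomere; the cM/Mb profile is modelled as an exponential
c(x) = a * exp(b * x) of the relative arm position x in [0, 1].  The genetic
distance of a locus from the centromere is the integral of that intensity
over the physical interval,

    g(x) = L_arm * a * (exp(b * x) - 1) / b      (L_arm * a * x as b -> 0)

with arm lengths defaulting to 388 Mb (short) and 437 Mb (long).  Signed
coordinates place the short arm on the negative half-axis and the long arm
on the positive one, so a chromosome reads telomere < centromere(0) <
telomere in strictly increasing order.

Loci at less than 70% of the arm are classified centromeric (low
recombination), beyond 70% telomeric; x exactly 0.70 is assigned
centromeric (boundary convention; no real locus sits exactly there).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .triplets import DistanceMatrix

__all__ = [
    "ChromosomeModel",
    "genetic_distance",
    "signed_coordinate",
    "classify_region",
    "pairwise_genetic_distance",
    "load_locus_annotations",
    "REGION_BOUNDARY",
]

REGION_BOUNDARY = 0.70

ANNOTATION_COLUMNS = [
    "locus", "length_bp", "chromosome", "arm", "rel_dist_centromere",
    "region", "evo_rate", "alpha", "prop_variable",
    "td_supermatrix", "td_bucky",
]


@dataclass(frozen=True)
class ChromosomeModel:
    """Arm lengths (Mb) and the exponential cM/Mb intensity c(x)=a*exp(b*x).

    Defaults: L_short=388, L_long=437 Mb; a=0.01 cM/Mb at the centromere,
    b=4.0 (about a 55-fold centromere-to-telomere intensity ratio, yielding
    arm map lengths of ~52 and ~59 cM).
    """

    arm_length_short: float = 388.0
    arm_length_long: float = 437.0
    intensity_scale: float = 0.01   # a, cM/Mb
    intensity_shape: float = 4.0    # b, dimensionless

    def __post_init__(self):
        if self.arm_length_short <= 0 or self.arm_length_long <= 0:
            raise ValueError("arm lengths must be positive")
        if self.intensity_scale < 0:
            raise ValueError("intensity scale must be nonnegative")

    def arm_length(self, arm: str) -> float:
        if arm == "short":
            return self.arm_length_short
        if arm == "long":
            return self.arm_length_long
        raise ValueError(f"arm must be 'short' or 'long', got {arm!r}")

    def intensity(self, x) -> np.ndarray:
        """c(x) in cM/Mb at relative arm position x."""
        return self.intensity_scale * np.exp(self.intensity_shape * np.asarray(x, float))


def _check_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("relative position x must lie in [0, 1]")
    return x


def genetic_distance(x, arm: str, model: ChromosomeModel | None = None):
    """Genetic distance (cM) from the centromere of a locus at relative arm
    position ``x``: L_arm times the integral of c(u) du over [0, x]."""
    model = model or ChromosomeModel()
    x = _check_x(x)
    L = model.arm_length(arm)
    a, b = model.intensity_scale, model.intensity_shape
    if abs(b) < 1e-12:
        g = L * a * x
    else:
        g = L * a * (np.exp(b * x) - 1.0) / b
    return g if g.shape else float(g)


def signed_coordinate(x, arm: str, model: ChromosomeModel | None = None):
    """Signed genetic coordinate: +g(x) on the long arm, -g(x) on the short
    arm, 0 at the centromere."""
    g = genetic_distance(x, arm, model)
    return g if arm == "long" else -g


def classify_region(x) -> str:
    """'centromeric' for x <= 0.70 of the arm, 'telomeric' beyond."""
    x = _check_x(x)
    if x.shape:
        return np.where(x > REGION_BOUNDARY, "telomeric", "centromeric")
    return "telomeric" if x > REGION_BOUNDARY else "centromeric"


def pairwise_genetic_distance(
    annotations: pd.DataFrame, model: ChromosomeModel | None = None
) -> DistanceMatrix:
    """Matrix of |signed coordinate differences| between positioned loci.

    ``annotations`` needs columns locus/arm/rel_dist_centromere; rows with
    missing arm or position are excluded (with a printed warning).
    """
    model = model or ChromosomeModel()
    ok = annotations["rel_dist_centromere"].notna() & annotations["arm"].notna()
    dropped = annotations.loc[~ok, "locus"].tolist()
    if dropped:
        import warnings

        warnings.warn(f"excluding loci without positions: {dropped}")
    sub = annotations.loc[ok]
    coords = np.array([
        signed_coordinate(row.rel_dist_centromere, row.arm, model)
        for row in sub.itertuples()
    ])
    values = np.abs(coords[:, None] - coords[None, :])
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=tuple(sub["locus"]), values=values, undefined=[])


def load_locus_annotations(path: str | Path | None = None) -> pd.DataFrame:
    """Load a locus annotation table (TSV).

    With no argument, loads the packaged 27-locus table (alignment length,
    genomic location, relative centromere distance, region class,
    evolutionary rate, gamma shape, proportion of variable sites, and the
    per-locus triplet distances to the supermatrix and BCF consensus trees).
    """
    if path is None:
        src = resources.files("tripdist.data").joinpath("table2.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", na_values=["NA"])
    else:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return df
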