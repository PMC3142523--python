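"""Statistical layer: rank correlations, quadratic position regression, and
the two within-arm permutation tests.

Both permutation tests respect the chromosome-arm structure of the design:
locus identities are shuffled only among loci on the same arm, never across
arms, because pair statistics are defined within arms (median-difference
test) or derive from a coordinate system that is arm-specific (matrix
correlation test).  Empirical p-values use the add-one convention
p = (1 + #{null >= observed}) / (1 + replicates), so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .genome_map import ChromosomeModel, signed_coordinate
from .triplets import DistanceMatrix

__all__ = [
    "ConstantInputError",
    "PermutationResult",
    "RegressionFit",
    "spearman",
    "quadratic_fit",
    "median_difference_test",
    "within_arm_matrix_correlation_test",
    "column_summary",
]


class ConstantInputError(ValueError):
    """A correlation was requested on a constant vector."""


@dataclass
class PermutationResult:
    observed: float
    n_reps: int
    pvalue: float
    tail: str
    seed: int | None
    scheme: str
    null_values: np.ndarray = field(repr=False, default=None)


@dataclass
class RegressionFit:
    """OLS fit of distances on (1, g, g^2) of the signed genetic position."""

    intercept: float
    linear: float
    quadratic: float
    residual_variance: float
    n: int

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.intercept, self.linear, self.quadratic])

    def predict(self, positions) -> np.ndarray:
        g = np.asarray(positions, dtype=float)
        return self.intercept + self.linear * g + self.quadratic * g**2


def spearman(xs, ys, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    ``method='t'`` (default) returns the t-approximation p-value on n-2 df;
    ``method='exact'`` enumerates all permutations (n <= 8 only) and returns
    the two-sided exact p.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(xs) < 4:
        raise ValueError("need n >= 4")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    if method == "t":
        res = sps.spearmanr(xs, ys)
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        from itertools import permutations

        n = len(xs)
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        rx = sps.rankdata(xs)
        ry = sps.rankdata(ys)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            total += 1
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
        return float(obs), count / total
    raise ValueError(f"unknown method {method!r}")


def quadratic_fit(positions, distances) -> RegressionFit:
    """Least-squares quadratic regression of per-locus distances on the
    signed genetic coordinate."""
    g = np.asarray(positions, dtype=float)
    d = np.asarray(distances, dtype=float)
    if g.shape != d.shape or g.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(g)
    if n < 4:
        raise ValueError("need n >= 4")
    X = np.column_stack([np.ones(n), g, g**2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (positions not distinct enough)")
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    resid = d - X @ beta
    dof = max(n - 3, 1)
    return RegressionFit(
        intercept=float(beta[0]),
        linear=float(beta[1]),
        quadratic=float(beta[2]),
        residual_variance=float(resid @ resid / dof),
        n=n,
    )


def _empirical_p(observed: float, null: np.ndarray, tail: str) -> float:
    if tail == "greater":
        b = int(np.sum(null >= observed))
    elif tail == "less":
        b = int(np.sum(null <= observed))
    elif tail == "two-sided":
        b = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + b) / (1 + len(null))


def _within_arm_permutation(rng: np.random.Generator, arms: np.ndarray) -> np.ndarray:
    """Random permutation of range(n) that maps each arm's index block onto
    itself (no locus crosses arms)."""
    perm = np.arange(len(arms))
    for arm in np.unique(arms):
        idx = np.nonzero(arms == arm)[0]
        perm[idx] = rng.permutation(idx)
    return perm


def median_difference_test(
    M: DistanceMatrix | np.ndarray,
    arms: Sequence[str],
    regions: Sequence[str],
    reps: int = 10_000,
    seed: int | None = None,
    tail: str = "greater",
) -> PermutationResult:
    """Permutation test for telomeric-vs-centromeric pairwise incongruence.

    Observed statistic: median of the telomere-telomere pair distances minus
    median of the centromere-centromere pair distances, pairs taken only
    between loci on the same chromosome arm.  The null shuffles loci within
    each arm (region labels travel with the shuffle) and recomputes the pair
    groupings each replicate; default tail tests telomeric > centromeric.
    """
    V = M.values if isinstance(M, DistanceMatrix) else np.asarray(M, float)
    arms = np.asarray(arms)
    regions = np.asarray(regions)
    if V.shape != (len(arms), len(arms)) or len(arms) != len(regions):
        raise ValueError("matrix and label lengths do not conform")

    # all same-arm pairs once; per replicate only the region masks change
    n = len(arms)
    pi, pj = np.triu_indices(n, k=1)
    same_arm = arms[pi] == arms[pj]
    pi, pj = pi[same_arm], pj[same_arm]
    pair_vals = V[pi, pj]
    is_cen = regions == "centromeric"
    is_tel = regions == "telomeric"

    def stat(perm: np.ndarray) -> float:
        # permuting loci within arms == permuting (region) labels over the
        # fixed distance matrix within arms
        cen_p, tel_p = is_cen[perm], is_tel[perm]
        cen_mask = cen_p[pi] & cen_p[pj]
        tel_mask = tel_p[pi] & tel_p[pj]
        if cen_mask.sum() < 2 or tel_mask.sum() < 2:
            raise ValueError(
                "need >= 2 centromere-centromere and >= 2 telomere-telomere "
                "same-arm pairs"
            )
        return float(np.median(pair_vals[tel_mask]) - np.median(pair_vals[cen_mask]))

    identity = np.arange(n)
    observed = stat(identity)
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        null[r] = stat(_within_arm_permutation(rng, arms))
    return PermutationResult(
        observed=observed,
        n_reps=reps,
        pvalue=_empirical_p(observed, null, tail),
        tail=tail,
        seed=seed,
        scheme="within-arm locus permutation, median(tel-tel) - median(cen-cen)",
        null_values=null,
    )


def within_arm_matrix_correlation_test(
    M: DistanceMatrix | np.ndarray,
    annotations=None,
    reps: int = 10_000,
    seed: int | None = None,
    tail: str = "greater",
    method: str = "spearman",
    model: ChromosomeModel | None = None,
    G: DistanceMatrix | np.ndarray | None = None,
    arms: Sequence[str] | None = None,
) -> PermutationResult:
    """Mantel-style correlation of pairwise triplet distances with pairwise
    genetic distances, permuting locus locations within arms.

    The observed statistic correlates the off-diagonal upper triangles of M
    (triplet distances) and G (genetic distances).  The null permutes locus
    positions within each chromosome arm and recomputes G — equivalent to
    jointly permuting G's rows/columns by a within-arm permutation while M
    stays fixed.  One-sided (positive correlation) by default.

    Supply either ``annotations`` (DataFrame with locus/arm/
    rel_dist_centromere, positions turned into signed coordinates via
    ``model``) or precomputed ``G`` plus ``arms``.
    """
    V = M.values if isinstance(M, DistanceMatrix) else np.asarray(M, float)
    if G is None:
        if annotations is None:
            raise ValueError("supply annotations or a precomputed G")
        model = model or ChromosomeModel()
        coords = np.array([
            signed_coordinate(row.rel_dist_centromere, row.arm, model)
            for row in annotations.itertuples()
        ])
        arms = annotations["arm"].to_numpy()
        GV = np.abs(coords[:, None] - coords[None, :])
    else:
        GV = G.values if isinstance(G, DistanceMatrix) else np.asarray(G, float)
        if arms is None:
            raise ValueError("arms must accompany a precomputed G")
        arms = np.asarray(arms)
    n = V.shape[0]
    if GV.shape != (n, n) or len(arms) != n:
        raise ValueError("M, G and arms do not conform")
    iu = np.triu_indices(n, k=1)
    m_flat = V[iu]
    valid = ~np.isnan(m_flat)

    if method == "spearman":
        # rank M's triangle once; only G's ranks change across replicates
        rm = sps.rankdata(m_flat[valid])
        rm = rm - rm.mean()
        rm_norm = float(np.sqrt(rm @ rm))
        if rm_norm == 0:
            raise ConstantInputError("triplet-distance triangle is constant")

        def corr(g_vals: np.ndarray) -> float:
            rg = sps.rankdata(g_vals)
            rg = rg - rg.mean()
            return float(rm @ rg / (rm_norm * np.sqrt(rg @ rg)))

    elif method == "pearson":
        mv = m_flat[valid]

        def corr(g_vals: np.ndarray) -> float:
            return float(np.corrcoef(mv, g_vals)[0, 1])

    else:
        raise ValueError(f"unknown method {method!r}")

    def stat(perm: np.ndarray) -> float:
        return corr(GV[perm][:, perm][iu][valid])

    observed = stat(np.arange(n))
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        null[r] = stat(_within_arm_permutation(rng, arms))
    return PermutationResult(
        observed=observed,
        n_reps=reps,
        pvalue=_empirical_p(observed, null, tail),
        tail=tail,
        seed=seed,
        scheme=f"within-arm position permutation, {method} on upper triangles",
        null_values=null,
    )


def column_summary(values) -> dict:
    """Mean, sample (n-1) SD, minimum and maximum of a numeric column."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("need n >= 2")
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "n": int(len(v)),
    }
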