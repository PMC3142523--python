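# Methods

## Triplet encoding and the retention rule

A rooted triplet on leaves {a, b, c} is encoded by which pair's MRCA is
strictly deeper than the trio's MRCA; if all three pairwise MRCAs coincide
the trio is unresolved (a polytomy). Internally each tree is reduced to an
integer code per trio of a fixed, lexicographically ordered taxon set
(0/1/2 for the three resolutions, 3 unresolved, 4 leaf absent), computed
from a pairwise MRCA-depth matrix filled in one postorder pass; forests are
then tabulated with vectorized counts. Branch lengths and internal labels
are parsed but ignored — every statistic here is purely topological — and
trees are rooted exactly as written; no unrooted interpretation is offered.

Retention over a forest of N trees uses a strict majority: a resolution is
retained iff its count exceeds θ·N with θ ≥ 1/2, compared in exact integer
arithmetic (floats are routed through their decimal representation, so
θ = 0.6 means exactly 3/5). Strictness plus θ ≥ 1/2 guarantees at most one
retained resolution per trio. The denominator is the full forest size by
default — trees missing the trio's leaves or leaving it unresolved count
*against* retention — with an option to count only trees containing all
three leaves; the two coincide for complete forests, which is the designed
use. Comparisons between trees/forests with different leaf sets are
computed on the leaf-set intersection, and the number of excluded trios is
reported alongside every distance.

The tree-forest dissimilarity is n_diff/(n_same + n_diff) over the forest's
retained trios; the reference must be fully resolved on the shared leaves
(callers resolve polytomies first, with a logged seed). The forest-forest
dissimilarity restricts to trios retained in *both* forests; trios retained
in exactly one are reported as a diagnostic count, not silently mixed in.
An empty denominator raises an explicit error rather than returning 0 or
NaN, and pairwise matrices flag such cells as NaN with the offending pair
listed.

## Chi-square rejection screen

Counts are pooled over the concatenation of all loci's bootstrap trees.
For each trio resolved in the reference tree, the statistic is a two-cell
goodness-of-fit between the reference resolution (count n_ref) and the
single best-supported conflicting resolution (n_conf) under an equal-
frequency null: χ² = (n_conf − n_ref)²/(n_conf + n_ref), 1 df. A trio is
strongly rejected iff n_conf ≥ 1, n_conf > n_ref and χ² exceeds the
χ²₁ critical value at the configured confidence — the 0.9 threshold is read
as a confidence level (critical value 2.706), not a p-value, and this
reading is stated in output metadata. The statistic is an injectable
function so an alternative pairwise frequency test can be swapped in
without touching the screen. Unresolved bootstrap trios contribute to
neither count. Per-taxon tallies increment each rejected trio's three
members, so their sum is always 3× the rejected count.

## Genetic map

The cM/Mb intensity along an arm is modelled as c(x) = a·e^(bx) on relative
position x ∈ [0, 1]; the genetic distance of a locus is
g(x) = L·a·(e^(bx) − 1)/b (limit L·a·x as b → 0) with arm lengths
L = 388 Mb (short) and 437 Mb (long). The defaults a = 0.01 cM/Mb, b = 4
give a ~55-fold centromere-to-telomere intensity ratio and arm map lengths
of ≈52/59 cM, a plausible scale for a large cereal chromosome; both are
configurable, and no claim is made that they equal any particular published
fit. Signed coordinates are −g(x) on the short arm and +g(x) on the long
arm, so position increases strictly from short-arm telomere to long-arm
telomere. Region classification is centromeric for x ≤ 0.70 and telomeric
beyond; the boundary is assigned centromeric by convention (no locus in the
packaged table sits exactly there). Pairwise genetic distances are absolute
differences of signed coordinates (unsigned separation); the quadratic
regression uses the signed coordinate itself. Loci without positions are
excluded from all recombination analyses.

## Permutation tests

Both tests condition on the arm structure: locus identities are shuffled
only within arms, never across, because cross-arm pairs are excluded from
the median comparison and the coordinate system is arm-specific.

* Median-difference test: observed statistic = median(tel–tel pairs) −
  median(cen–cen pairs) over same-arm pairs; the null permutes loci within
  each arm and regroups pairs each replicate. One-sided (telomeric >
  centromeric) by default.
* Matrix-correlation test: Spearman (optionally Pearson) correlation of the
  off-diagonal upper triangles of the incongruence matrix M and the
  genetic-distance matrix G; the null permutes locus positions within arms
  and recomputes G, which is implemented exactly as a joint row/column
  permutation of G with M fixed. One-sided (positive) by default.

Empirical p-values use the add-one convention (1 + b)/(1 + reps), standard
Monte-Carlo practice that avoids zero p-values; 10,000 replicates by
default. Spearman correlations elsewhere use the t-approximation on n − 2
df, with exact enumeration available for n ≤ 8.

## Synthetic generator

The generator emulates the *shape* of the motivating study, not its
sequences: a rooted binary species tree from uniformly random sequential
joins (the coalescent/Yule topology process — note its topology law is not
uniform over labeled topologies; on 4 taxa balanced shapes have probability
1/9 and caterpillars 1/18, and tests check against that law); per-locus
gene trees made by applying a Poisson number of random rooted NNI moves to
the species tree; and bootstrap forests whose replicates are the gene tree
or, with probability equal to the noise rate, the gene tree after one
random NNI.

The discordance intensity couples to position as λ(x) = λ₀(1 + κ·p(x)),
where p(x) = g(x)/g(1) is the locus's genetic position normalized within
its arm — chosen over raw physical position because it concentrates
discordance where recombination is, maximizing the centromere/telomere
contrast the analysis is designed to detect. Defaults: 20 taxa, the 21
chromosome-3 (arm, x) positions of the packaged table plus 6 unpositioned
loci (simulated at midpoint intensity p = 0.5), λ₀ = 1, κ = 5, noise 0.3,
100 replicates per forest. Randomness flows from one master seed through
numpy SeedSequence spawning, one stream per locus, so adding loci never
perturbs existing ones; identical config + seed reproduces byte-identical
trees.

What the generator does *not* emulate: multispecies-coalescent branch
lengths, introgression vs lineage-sorting structure, alignment-length or
rate effects on bootstrap noise, and realistic gene-tree error
heterogeneity. Passing tests therefore demonstrate that the pipeline
detects position-coupled topological discordance of the assumed form, not
that any particular biological mechanism produces it.

A scale consequence worth knowing: one rooted NNI changes only ~2% of the
C(20,3) = 1140 triplets of a 20-taxon tree, so at λ₀ = 1 the telomere/
centromere contrast in expected moves (~1.6 vs ~3.7) shifts pair-distance
medians by only ≈0.05–0.1 while Poisson move counts add large between-locus
variance. The median-difference test is exactly calibrated under κ = 0 and
has full power against a direct +0.3 telomeric shift, but against this
generator at λ₀ = 1, κ = 5 its per-seed power is limited (~30%); the
matrix-correlation statistic, which uses all pairs rather than group
medians, is positive in ~95% of seeds under the same conditions. The
acceptance script reports both rates as computed.

## Numerical and interface choices

Retention comparisons are exact (integer × rational), never floating
thresholds. Distances are computed at full precision and rounded only in
reports. The pipeline writes TSV tables plus one JSON report carrying a
provenance block (package version, seeds — including the two spawned
permutation seeds — thresholds, generator settings) sufficient to reproduce
every number. Problem sizes in the tests and the acceptance script (e.g.
500-replicate permutations, 100–200 synthetic datasets for calibration, 25–
50 seeds for power) were chosen to keep Monte-Carlo error well below the
margins being asserted while remaining quick to run.

## Known limitations

* Triplet tabulation is O(n³) per tree in the taxon count; fine for tens of
  taxa, not designed for hundreds.
* The χ² screen tests each trio marginally against its best rival; no
  multiple-testing correction is applied (raw values are reported, matching
  the analysis it implements).
* The exponential intensity constants are package defaults, not a fitted
  recombination map; analyses that depend on absolute cM values should
  supply their own (a, b).
* Bootstrap forests are modelled as single-NNI perturbations, which cannot
  collapse retention on moderate-size trees — real bootstrap noise is
  heavier-tailed.
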