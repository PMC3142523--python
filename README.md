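# tripdist

Rooted-triplet quantification of gene-tree incongruence, and of its
relationship with recombination along chromosome arms.

## The problem

In groups shaped by hybridization and incomplete lineage sorting — the wheat
tribe Triticeae is the motivating case — individual gene trees disagree both
with each other and with multigenic consensus trees (a concatenation
"supermatrix" tree or a Bayesian concordance tree). `tripdist` is for
phylogeneticists who want to *measure* that disagreement locus by locus and
test whether it tracks recombination intensity along chromosomes, rather
than only inspecting conflicting topologies by eye.

## What it computes

**Triplet-fit dissimilarity.** For a rooted reference tree *T*ₛ and the
bootstrap forest *F*ⱼ of locus *j*, only triplets resolved the same way in
strictly more than 50% of the forest's trees are retained (this keeps at
most one resolution per trio of taxa). With *s* retained triplets resolved
as in *T*ₛ and *d* resolved differently,

d(*T*ₛ, *F*ⱼ) = *d* / (*s* + *d*)

The same construction on the jointly retained triplets of two forests gives
d(*F*ᵢ, *F*ⱼ) and, over all locus pairs, a symmetric incongruence matrix
*M*.

**Strongly rejected triplets.** Pooling all loci's bootstrap trees, a
triplet of the reference tree is strongly rejected when a conflicting
resolution is more frequent and χ² = (n_conf − n_ref)² / (n_conf + n_ref)
exceeds the χ²₁ critical value at the chosen confidence (2.706 at 0.9).
Per-taxon counts of rejected triplets localize the conflict.

**Genetic map.** Physical arm positions *x* ∈ [0, 1] map to centimorgans by
integrating an exponential recombination intensity c(x) = a·e^(bx):
g(x) = L·a·(e^(bx) − 1)/b, with arm lengths 388/437 Mb; short-arm loci take
negative signed coordinates. Loci are centromeric (x ≤ 0.7) or telomeric.

**Statistics.** Spearman correlations of per-locus distances with
evolutionary rate, gamma shape α, and alignment length; a quadratic
regression of distance on signed genetic position; and two within-arm
permutation tests (loci are never permuted across arms): a
median-difference test of telomere-telomere versus centromere-centromere
pair distances, and a Mantel-style correlation of *M* with the pairwise
genetic-distance matrix.

**Synthetic data.** A generator produces a random-join species tree, gene
trees perturbed by Poisson-many random rooted NNI moves with mean
λ(x) = λ₀(1 + κ·p(x)) increasing toward telomeres, and bootstrap forests
with one-NNI replicate noise — so the whole pipeline is testable end to end
without sequence data.

## Worked example

```python
>>> import tripdist as td
>>> ref = td.parse_newick("((a,b),(c,d));")
>>> forest = td.BootstrapForest("locus1",
...     [ref] * 60 + [td.parse_newick("((a,c),(b,d));")] * 40)
>>> cmp = td.tree_forest_distance(ref, forest)
>>> cmp.n_same, cmp.n_diff, cmp.distance
(4, 0, 0.0)
```

All four triplets keep a 60% majority resolution matching the reference, so
the dissimilarity is 0 despite 40% conflicting bootstrap trees — the
retention rule is doing its job of separating locus signal from bootstrap
noise.

The packaged 27-locus annotation table reproduces the study-level
statistics:

```python
>>> report = td.run_annotations_analysis()
>>> report["total_alignment_bp"]
24652
>>> round(report["td_supermatrix"]["mean"], 2), round(report["td_supermatrix"]["sd"], 2)
(0.21, 0.1)
>>> report["region_audit"]["n_agreeing"]
21
```

i.e. a 24,652-bp concatenate, a mean gene-tree-to-supermatrix triplet
distance of 0.21 ± 0.10, and the 70% rule reproducing every printed
centromeric/telomeric label.

A full synthetic analysis from the shell:

```sh
tripdist run --seed 1 --reps 1000 --out report/
```

writes per-locus distances, the pairwise matrix, rejected triplets with
per-taxon counts, and a JSON report with the permutation p-values and
provenance (seeds, thresholds, versions).

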