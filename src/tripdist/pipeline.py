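"""End-to-end orchestration: inputs -> triplet distances -> rejection screen
-> genome map -> statistics -> report.

Reports are plain TSV tables plus one JSON summary; numbers are rounded only
at the reporting layer.  Every run records a provenance block (config,
seeds, package version) sufficient to reproduce it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome_map import (
    ChromosomeModel,
    classify_region,
    load_locus_annotations,
    pairwise_genetic_distance,
    signed_coordinate,
)
from .rejection import per_taxon_counts, strongly_rejected_triplets
from .stats import (
    column_summary,
    median_difference_test,
    quadratic_fit,
    spearman,
    within_arm_matrix_correlation_test,
)
from .synthetic import SyntheticConfig, simulate_study
from .treeio import BootstrapForest, PhyloTree
from .triplets import pairwise_matrix, tree_forest_distance

__all__ = ["AnalysisConfig", "run_annotations_analysis", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    """Study-level constants for a full run."""

    retention_threshold: float = 0.5
    chi2_confidence: float = 0.9
    permutation_reps: int = 10_000
    seed: int | None = None
    chromosome_model: ChromosomeModel = field(default_factory=ChromosomeModel)
    synthetic: SyntheticConfig | None = None
    # external-input mode: reference tree + forest files + annotation TSV
    # (loci matched to forests by locus id); used instead of `synthetic`
    # when all three are set
    tree_path: str | None = None
    forests_dir: str | None = None
    annotations_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if not (0.5 <= self.retention_threshold < 1.0):
            raise ValueError("retention threshold must lie in [0.5, 1)")
        if not (0.0 < self.chi2_confidence < 1.0):
            raise ValueError("chi-square confidence must lie in (0, 1)")
        if self.permutation_reps < 1:
            raise ValueError("need at least one permutation replicate")


def run_annotations_analysis(annotations: pd.DataFrame | None = None) -> dict:
    """Annotation-table analysis: alignment totals, triplet-distance column
    summaries, rank correlations with phylogenetic parameters, and a region
    classification audit against the 70% rule.

    With no argument the packaged 27-locus table is analyzed.
    """
    df = annotations if annotations is not None else load_locus_annotations()
    required = {"locus", "length_bp", "evo_rate", "alpha",
                "td_supermatrix", "td_bucky", "rel_dist_centromere", "region"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")

    report: dict = {
        "n_loci": int(len(df)),
        "total_alignment_bp": int(df["length_bp"].sum()),
        "td_supermatrix": column_summary(df["td_supermatrix"]),
        "td_bucky": column_summary(df["td_bucky"]),
    }
    correlations = {}
    for td_col in ("td_supermatrix", "td_bucky"):
        for param in ("evo_rate", "alpha", "length_bp"):
            rho, p = spearman(df[param], df[td_col])
            correlations[f"{param}_vs_{td_col}"] = {"rho": rho, "p": p}
    report["spearman"] = correlations

    positioned = df[df["rel_dist_centromere"].notna()]
    audit = [
        {
            "locus": row.locus,
            "x": row.rel_dist_centromere,
            "declared": row.region,
            "computed": classify_region(row.rel_dist_centromere),
        }
        for row in positioned.itertuples()
    ]
    report["region_audit"] = {
        "n_positioned": int(len(positioned)),
        "n_unpositioned": int(len(df) - len(positioned)),
        "n_agreeing": sum(a["declared"] == a["computed"] for a in audit),
        "rows": audit,
    }
    return report


def _per_locus_distances(
    reference: PhyloTree,
    forests: list[BootstrapForest],
    threshold,
) -> pd.DataFrame:
    rows = []
    for forest in forests:
        cmp_ = tree_forest_distance(reference, forest, threshold)
        rows.append(
            {
                "locus": forest.locus,
                "n_same": cmp_.n_same,
                "n_diff": cmp_.n_diff,
                "distance": cmp_.distance,
                "n_retained": cmp_.n_retained,
                "n_skipped": cmp_.n_skipped,
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the complete pipeline on a synthetic study.

    Generates the dataset from ``config.synthetic`` (seeded from
    ``config.seed`` when the synthetic config carries no seed of its own),
    then computes per-locus reference-vs-forest distances, the pairwise
    forest distance matrix, the chi-square rejection screen with per-taxon
    counts, the genetic-distance layer, and the correlation/permutation
    statistics.  Returns the report dict; writes TSV/JSON files when
    ``config.output_dir`` is set.
    """
    external = all(
        (config.tree_path, config.forests_dir, config.annotations_path)
    )
    if external:
        from .treeio import load_forests

        reference = PhyloTree.from_file(config.tree_path)
        forests = load_forests(config.forests_dir)
        ann_in = pd.read_csv(config.annotations_path, sep="\t", na_values=["NA"])
        by_locus = {f.locus: f for f in forests}
        missing = [l for l in ann_in["locus"] if l not in by_locus]
        if missing:
            raise ValueError(f"no forest found for loci: {missing}")
        forests = [by_locus[l] for l in ann_in["locus"]]
        if "region" not in ann_in.columns:
            ann_in["region"] = [
                classify_region(x) if pd.notna(x) else None
                for x in ann_in["rel_dist_centromere"]
            ]

        class _Study:  # same duck type as SyntheticStudy
            species_tree = reference
            annotations = ann_in

        study = _Study()
        study.forests = forests
        syn = None
    else:
        syn = config.synthetic or SyntheticConfig()
        if syn.seed is None and config.seed is not None:
            from dataclasses import replace

            syn = replace(syn, seed=config.seed)
        study = simulate_study(syn)
    threshold = Fraction(str(config.retention_threshold))

    per_locus = _per_locus_distances(study.species_tree, study.forests, threshold)

    ann = study.annotations
    positioned_mask = ann["rel_dist_centromere"].notna()
    positioned = ann[positioned_mask].reset_index(drop=True)
    pos_forests = [f for f, ok in zip(study.forests, positioned_mask) if ok]

    M = pairwise_matrix(pos_forests, threshold)

    model = config.chromosome_model
    coords = np.array([
        signed_coordinate(row.rel_dist_centromere, row.arm, model)
        for row in positioned.itertuples()
    ])
    G = pairwise_genetic_distance(positioned, model)

    rng = np.random.default_rng(config.seed)
    perm_seed_a, perm_seed_b = (int(s) for s in rng.integers(2**31, size=2))

    median_test = median_difference_test(
        M,
        arms=positioned["arm"].to_numpy(),
        regions=positioned["region"].to_numpy(),
        reps=config.permutation_reps,
        seed=perm_seed_a,
    )
    mantel_test = within_arm_matrix_correlation_test(
        M,
        G=G,
        arms=positioned["arm"].to_numpy(),
        reps=config.permutation_reps,
        seed=perm_seed_b,
    )
    pos_distances = per_locus.loc[positioned_mask.to_numpy(), "distance"].to_numpy()
    quad = quadratic_fit(coords, pos_distances)

    rejected = strongly_rejected_triplets(
        study.species_tree, study.forests, confidence=config.chi2_confidence
    )
    taxon_counts = per_taxon_counts(rejected, study.species_tree.leaf_labels)

    report = {
        "provenance": {
            "tripdist_version": __version__,
            "seed": config.seed,
            "retention_threshold": float(config.retention_threshold),
            "chi2_confidence": config.chi2_confidence,
            "permutation_reps": config.permutation_reps,
            "permutation_seeds": [perm_seed_a, perm_seed_b],
            "input": (
                {
                    "tree": config.tree_path,
                    "forests": config.forests_dir,
                    "annotations": config.annotations_path,
                }
                if syn is None
                else {
                    "synthetic": {
                        **{k: v for k, v in asdict(syn).items()
                           if k not in ("layout", "chromosome_model")},
                        "n_loci": syn.n_loci,
                    }
                }
            ),
            "chromosome_model": asdict(model),
        },
        "per_locus_distance_mean": float(per_locus["distance"].mean()),
        "median_difference": {
            "observed": median_test.observed,
            "pvalue": median_test.pvalue,
            "tail": median_test.tail,
        },
        "matrix_correlation": {
            "observed": mantel_test.observed,
            "pvalue": mantel_test.pvalue,
            "tail": mantel_test.tail,
        },
        "quadratic_fit": {
            "intercept": quad.intercept,
            "linear": quad.linear,
            "quadratic": quad.quadratic,
            "n": quad.n,
        },
        "n_rejected_triplets": int(len(rejected)),
        "per_taxon_rejection_sum": int(taxon_counts.sum()),
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_locus.to_csv(out / "per_locus_distances.tsv", sep="\t", index=False)
        M.to_dataframe().to_csv(out / "pairwise_matrix.tsv", sep="\t")
        G.to_dataframe().to_csv(out / "genetic_distances.tsv", sep="\t")
        taxon_counts.to_csv(out / "taxon_rejection_counts.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "leaves": ",".join(sorted(rt.leaves)),
                    "ref_cherry": ",".join(sorted(rt.ref_cherry)),
                    "conf_cherry": ",".join(sorted(rt.conf_cherry)),
                    "n_ref": rt.n_ref,
                    "n_conf": rt.n_conf,
                    "chi2": rt.chi2,
                }
                for rt in rejected
            ]
        ).to_csv(out / "rejected_triplets.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
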