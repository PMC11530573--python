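"""Recovery of planted structure: how well pipeline calls match ground truth.

A planted condition-specific site counts as recovered when some called region
of its condition overlapping at least half of the planted span is labelled
specific to that condition.  A planted super-enhancer site counts when an
``is_super`` stitched cluster overlaps it.  A planted region-to-gene link
counts when the gene appears in the concordant set (enhancer or
super-enhancer class) for the matching side of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix, near_vs_global_expression
from .intervals import GenomicInterval, overlap_length
from .pipeline import PipelineResult
from .simulate import GroundTruth

__all__ = ["RecoverySummary", "evaluate_recovery", "null_rejection_rate"]


@dataclass
class RecoverySummary:
    n_specific_planted: int
    n_specific_recovered: int
    n_se_planted: int
    n_se_recovered: int
    n_links_planted: int
    n_links_recovered: int
    cross_population_pvalues: dict[str, float | None]  # condition -> enhancer-class p

    @property
    def specific_fraction(self) -> float:
        return self.n_specific_recovered / max(self.n_specific_planted, 1)

    @property
    def se_fraction(self) -> float:
        return self.n_se_recovered / max(self.n_se_planted, 1)

    @property
    def link_fraction(self) -> float:
        return self.n_links_recovered / max(self.n_links_planted, 1)

    def merged_with(self, other: "RecoverySummary") -> "RecoverySummary":
        merged_p = dict(self.cross_population_pvalues)
        for k, v in other.cross_population_pvalues.items():
            if k in merged_p and merged_p[k] is not None and v is not None:
                merged_p[k] = max(merged_p[k], v)
            else:
                merged_p[k] = v
        return RecoverySummary(
            self.n_specific_planted + other.n_specific_planted,
            self.n_specific_recovered + other.n_specific_recovered,
            self.n_se_planted + other.n_se_planted,
            self.n_se_recovered + other.n_se_recovered,
            self.n_links_planted + other.n_links_planted,
            self.n_links_recovered + other.n_links_recovered,
            merged_p,
        )


def _covers_half(called: GenomicInterval, planted: GenomicInterval) -> bool:
    return overlap_length(called, planted) * 2 >= planted.length


def evaluate_recovery(truth: GroundTruth, result: PipelineResult) -> RecoverySummary:
    cond_a, cond_b = result.comparison
    side_of = {cond_a: "specific_A", cond_b: "specific_B"}

    # Specific-region recovery: specific label on a called region covering
    # at least half of the planted span, in the planted condition.
    label_by_id = {
        (lab.condition, lab.region_id): lab
        for lab in result.enhancer_labels + result.promoter_labels
    }
    intervals_by_id = {}
    for cond in result.comparison:
        for r in result.classified[cond]:
            intervals_by_id[(cond, r.region_id)] = r.interval

    n_spec = n_spec_rec = 0
    for site in truth.regions:
        if site.specificity == "shared":
            continue
        cond = site.specificity
        n_spec += 1
        for (lcond, rid), lab in label_by_id.items():
            if lcond != cond or lab.label != side_of[cond]:
                continue
            if _covers_half(intervals_by_id[(cond, rid)], site.interval):
                n_spec_rec += 1
                break

    n_se = n_se_rec = 0
    for cond in result.comparison:
        supers = [c for c in result.secalls[cond] if c.is_super]
        for site in truth.se_regions(cond):
            n_se += 1
            if any(overlap_length(c.interval, site.interval) > 0 for c in supers):
                n_se_rec += 1

    # Link recovery: the planted gene appears in the concordant set of the
    # matching side (either class; super-enhancer sites are enhancers too).
    concordant_by_cond: dict[str, set[str]] = {c: set() for c in result.comparison}
    for sets in result.concordant.values():
        for cond, cset in sets.items():
            concordant_by_cond[cond].update(cset.gene_ids)
    n_links = len(truth.links)
    n_links_rec = sum(
        1 for link in truth.links if link.gene_id in concordant_by_cond[link.condition]
    )

    cross_p: dict[str, float | None] = {}
    for row in result.validation:
        if row["class"] == "enhancer" and row["test"] == "cross_population":
            cross_p[row["condition"]] = row["pvalue"]
    return RecoverySummary(
        n_spec, n_spec_rec, n_se, n_se_rec, n_links, n_links_rec, cross_p
    )


def null_rejection_rate(
    n_draws: int = 2000,
    seed: int = 0,
    n_genes: int = 400,
    n_region_genes: int = 25,
    n_replicates: int = 4,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.5,
    noise_sd: float = 0.5,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo type-I error of the near-vs-global test under the null.

    Each draw simulates a fresh expression matrix with no planted effect
    (the effect-free configuration of the generator, on one condition) and
    tests a random gene subset against the rest; the returned fraction of
    draws with p < alpha should sit at the nominal level for a calibrated
    test.
    """
    import pandas as pd

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    samples = [f"A:rep{i + 1}" for i in range(n_replicates)]
    genes = [f"g{i:04d}" for i in range(n_genes)]
    rejections = 0
    for _ in range(n_draws):
        baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
        data = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_replicates))
        expr = ExpressionMatrix(
            pd.DataFrame(data, index=genes, columns=samples),
            {s: "A" for s in samples},
        )
        subset = rng.choice(n_genes, size=n_region_genes, replace=False)
        res = near_vs_global_expression([genes[i] for i in subset], expr, "A")
        if res.pvalue is not None and res.pvalue < alpha:
            rejections += 1
    return rejections / n_draws
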