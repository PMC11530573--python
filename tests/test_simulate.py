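"""Synthetic-study generator: determinism, planted structure, noise model."""

import numpy as np
import pytest

from regland.regions import consensus_regions
from regland.simulate import (
    SimulationConfig,
    plant_regions,
    simulate_annotation,
    simulate_expression,
    simulate_peaks,
    simulate_study,
)


def small_config(**overrides):
    """A fast, reduced-size configuration for unit tests."""
    base = dict(
        seed=7,
        n_chromosomes=2,
        chrom_length=12_000_000,
        n_genes=120,
        n_shared_regions=20,
        n_specific_regions_per_condition=5,
        background_fp_rate=1.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("replicate_reproducibility", 1.5),
            ("se_fraction", -0.1),
            ("n_replicates_per_condition", 2),
            ("expr_noise_sd", -1.0),
            ("conditions", ("A", "A")),
        ],
    )
    def test_bad_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            small_config(**{field: value}).validate()

    def test_infeasible_genome_rejected(self):
        with pytest.raises(ValueError, match="genome too small"):
            small_config(chrom_length=100_000,
                         n_specific_regions_per_condition=30).validate()


class TestAnnotation:
    def test_deterministic_given_seed(self):
        cfg = small_config()
        assert simulate_annotation(cfg) == simulate_annotation(cfg)

    def test_no_genes(self):
        assert simulate_annotation(small_config(n_genes=0)) == []

    def test_minimum_spacing_holds(self):
        cfg = small_config(tss_min_spacing=5_000)
        tss = simulate_annotation(cfg)
        by_chrom = {}
        for rec in tss:
            by_chrom.setdefault(rec.chrom, []).append(rec.tss)
        for positions in by_chrom.values():
            diffs = np.diff(sorted(positions))
            assert (diffs >= 5_000).all()
        assert len(tss) == cfg.n_genes


class TestPlanting:
    def test_counts_and_links_reference_existing_entities(self):
        cfg = small_config()
        truth = plant_regions(cfg, simulate_annotation(cfg))
        kinds = [r.kind for r in truth.regions]
        n_prom = round(cfg.n_shared_regions * cfg.promoter_fraction)
        assert kinds.count("promoter") == n_prom
        assert kinds.count("enhancer") == (
            cfg.n_shared_regions - n_prom
            + 2 * cfg.n_specific_regions_per_condition
        )
        genes = {t.gene_id for t in truth.tss}
        sites = {r.site_id for r in truth.regions}
        for link in truth.links:
            assert link.site_id in sites and link.gene_id in genes

    def test_no_gene_linked_to_both_conditions(self):
        cfg = small_config(n_specific_regions_per_condition=8)
        truth = plant_regions(cfg, simulate_annotation(cfg))
        assert not (truth.linked_genes("A") & truth.linked_genes("B"))


class TestPeaks:
    def test_noiseless_consensus_recovers_planted_regions_exactly(self):
        cfg = SimulationConfig.noiseless(seed=11, n_chromosomes=2,
                                         chrom_length=12_000_000, n_genes=120,
                                         n_shared_regions=20,
                                         n_specific_regions_per_condition=5)
        study = simulate_study(cfg)
        for cond in cfg.conditions:
            flat = [p for ps in study.peaks[cond].values() for p in ps]
            regions = consensus_regions(flat, cond, 2)
            planted = sorted(
                r.interval for r in study.truth.regions_in(cond)
            )
            assert sorted(r.interval for r in regions) == planted
            assert all(r.support == cfg.n_replicates_per_condition for r in regions)

    def test_low_reproducibility_discards_most_regions(self):
        # With per-replicate emission probability 1/n, the chance of >=2
        # supporting replicates is 1 - (1-p)^n - n p (1-p)^(n-1).
        cfg = small_config(replicate_reproducibility=0.25, background_fp_rate=0.0,
                           peak_jitter_bp=0, n_shared_regions=40,
                           n_specific_regions_per_condition=10)
        study = simulate_study(cfg)
        p, n = 0.25, cfg.n_replicates_per_condition
        expected = 1 - (1 - p) ** n - n * p * (1 - p) ** (n - 1)
        kept = trials = 0
        for cond in cfg.conditions:
            flat = [pk for ps in study.peaks[cond].values() for pk in ps]
            regions = consensus_regions(flat, cond, 2)
            starts = {r.interval.start for r in regions}
            for site in study.truth.regions_in(cond):
                trials += 1
                kept += site.interval.start in starts
        assert kept / trials == pytest.approx(expected, abs=0.12)
        assert kept / trials < 0.5

    def test_background_peaks_lack_replicate_support(self):
        cfg = small_config(replicate_reproducibility=1.0, peak_jitter_bp=0,
                           background_fp_rate=0.5)
        study = simulate_study(cfg)
        for cond in cfg.conditions:
            flat = [p for ps in study.peaks[cond].values() for p in ps]
            regions = consensus_regions(flat, cond, 2)
            planted_starts = {r.interval.start for r in study.truth.regions_in(cond)}
            # every surviving region is planted (background is single-replicate)
            for r in regions:
                assert r.interval.start in planted_starts


class TestExpression:
    def test_noiseless_fold_change_equals_planted_effect(self):
        cfg = small_config(expr_noise_sd=0.0)
        truth = plant_regions(cfg, simulate_annotation(cfg))
        _, de = simulate_expression(cfg, truth)
        by_gene = {r.gene_id: r for r in de}
        linked_a = truth.linked_genes("A")
        linked_b = truth.linked_genes("B")
        for g in linked_a:
            assert by_gene[g].log2fc == pytest.approx(cfg.effect_log2fc)
            assert by_gene[g].padj == 0.0
        for g in linked_b:
            assert by_gene[g].log2fc == pytest.approx(-cfg.effect_log2fc)
        unlinked = set(by_gene) - linked_a - linked_b
        assert all(by_gene[g].log2fc == 0.0 for g in unlinked)

    def test_null_effect_gives_uniformish_pvalues(self):
        cfg = small_config(effect_log2fc=0.0)
        truth = plant_regions(cfg, simulate_annotation(cfg))
        _, de = simulate_expression(cfg, truth)
        pvals = np.array([r.pvalue for r in de])
        assert 0.3 < pvals.mean() < 0.7  # roughly uniform under the null


class TestDeterminism:
    def test_identical_seed_bitwise_identical_files(self, tmp_path):
        cfg = small_config()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(cfg, d1)
        simulate_study(cfg, d2)
        for f in sorted(d1.rglob("*")):
            if f.is_file():
                twin = d2 / f.relative_to(d1)
                assert f.read_bytes() == twin.read_bytes(), f.name

    def test_different_seeds_differ(self):
        s1 = simulate_study(small_config(seed=1))
        s2 = simulate_study(small_config(seed=2))
        assert s1.truth.regions != s2.truth.regions
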