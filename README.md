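# regland

Calling the H3K27ac regulatory landscape of two cell populations — and the
genes it points at — from replicate ChIP-seq peak sets and a
differential-expression table.

H3K27ac marks active promoters and enhancers.  Given per-replicate broad
peaks (with IP and matched-input signal) for two conditions, a TSS
annotation, and an RNA-seq differential-expression table, `regland`:

1. builds **replicate-consensus regions** per condition — connected
   components of the union of replicate peaks, kept when ≥ 2 distinct
   replicates contribute;
2. classifies each region as **promoter** (centre < 2 kb from the nearest
   TSS) or **enhancer** (> 2 kb), annotating promoters to the nearest-TSS
   gene and enhancers to candidate targets in 100/200/400 kb windows;
3. labels regions **shared or condition-specific** by reciprocal overlap
   (shared requires overlap ≥ 0.3 of *both* regions);
4. calls **super-enhancers**: enhancers wholly inside a ±2.5 kb TSS window
   are excluded, the rest stitched at ≤ 12.5 kb, and stitched clusters
   ranked by input-subtracted signal Σ max(ip − input, 0); with ranks and
   signals scaled to [0, 1], clusters above the slope-1 tangent point of
   the convex rank–signal curve (argmin of scaled signal − scaled rank)
   are super-enhancers;
5. filters window genes of specific regions for **concordant expression**
   (|log2FC| ≥ 1.5 for enhancer-linked, ≥ 1.0 for SE-linked genes,
   Benjamini–Hochberg adjusted p < 0.05, direction set by which condition
   the region is specific to) and validates the expression claims with
   one-sided rank tests (near-vs-global and cross-population).

A synthetic-data generator plants a known architecture — shared and
specific sites, a long-tailed signal with a super-enhancer tail, genes
up-regulated near specific sites — so every stage is testable end to end
without any external data.  See `docs/methods.md` for the full model and
conventions.

Intended for computational biologists who have peak calls and DE tables in
hand and want the region-calling / integration logic as a tested,
deterministic library rather than a stack of one-off scripts.

## Worked example

The numbered scripts under `analysis/` run the whole story on the synthetic
study (seed 1) and write their tables under `results/analysis/`:

```bash
python analysis/01_simulate_study.py
python analysis/02_call_regulatory_regions.py
python analysis/03_cell_specificity.py
python analysis/04_superenhancers.py
python analysis/05_expression_integration.py
python analysis/06_recovery_benchmark.py
```

Selected output, with what it means:

```
A: 953 peaks -> 97 consensus regions (18 promoters, 79 enhancers; ...)
```
953 replicate peaks (4 replicates, including planted sites missed by some
replicates and spurious single-replicate background peaks) collapse to 97
regions with ≥ 2-replicate support — the 90 planted sites present in
condition A survive, background does not.

```
promoters: 18/18 shared on the A side (100%), 0 specific to A, 0 specific to B
enhancers: 41/79 shared on the A side (52%), 38 specific to A, 36 specific to B
```
Promoters are shared between the two conditions while enhancers carry the
condition-specific signal.

```
A: 79 enhancers -> 79 outside the TSS exclusion zone -> 79 stitched clusters
   -> 13 super-enhancers (signal cutoff 219.7)
```
The long-tailed signal gives a hockey-stick rank curve
(`results/analysis/hockey_stick_A.svg`); the 13 clusters above the
slope-1 tangent are the super-enhancer calls.

```
enhancers specific to A: 91 concordant genes (|log2FC| >= 1.5, padj < 0.05, 400 kb windows)
  near_vs_global (A): p = 3.84e-21, median 6.87 vs 5.09
  cross_population (A): p = 8.55e-18, median 1.95 vs 0.00
```
Genes within 400 kb of A-specific enhancers that are up-regulated in A;
they are more highly expressed than background within A, and higher in A
than in B (median paired difference 1.95 log2 units, matching the planted
+2 effect).

```
pooled over 10 studies: specific 99.7% (598/600), SE 97.9% (140/143),
links 92.8% (2187/2357)
```
The recovery benchmark over seeds 1–10 at the default noise conditions.

The same workflow is available as a CLI (`regland simulate / regions /
specificity / se / integrate`, or `regland run --config pipeline.yaml` for
the whole pipeline with a parameter echo and a `report.json` of per-stage
counts and test statistics).

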