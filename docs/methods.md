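# Methods

`regland` implements a desk-scale workflow for defining active regulatory
regions from H3K27ac ChIP-seq peak sets in two cell populations and for
nominating the genes those regions plausibly control.  This note records the
models, conventions, and numerical choices behind each stage, what the
synthetic benchmark does and does not emulate, and the known limitations.

## Coordinates and signal

All intervals are 0-based, half-open (BED convention); abutting intervals do
not overlap, and the distance between sorted non-overlapping intervals is
`start2 − end1`, with "within distance d" meaning `start2 − end1 ≤ d`.
Chromosome names are compared by exact string match — silent "chr"
normalisation hides input errors — with an optional alias map at the reader
boundary for mixed dialects.

Each peak carries an IP read-density score and a matched-input (control)
score.  The quantity ranked throughout is the input-subtracted signal
`net = max(ip − input, 0)`: densities below the control level carry no
enhancer evidence, so negatives are clamped rather than propagated.  The
workflow is agnostic about whether these scores are peak-caller statistics
or re-computed read densities; any non-negative per-peak (ip, input) pair is
accepted, and all results are invariant to rescaling all signals by a common
positive factor.

## Consensus regions and replicate support

Consensus regions for one condition are the connected components of the
union of all replicate peaks (merge gap 0).  Support is evaluated on the
merged component, not base-wise: a component counts every distinct replicate
contributing at least one overlapping peak, and components with support
below `min_replicates` (default 2) are discarded.  A chained component can
therefore contain bases covered by a single replicate; a strict base-wise
mode was considered and rejected as the default because peak boundaries are
noisy at exactly the scale that matters for base-wise agreement.  The
aggregated `net_signal` of a region is the sum over contributing peaks; when
replicate peaks overlap partially this counts overlapping bases more than
once, a convention isolated in one function and deliberate — it weights
reproducible signal upward the same way for every region.

## Promoter/enhancer classification and gene windows

A region is a promoter when its centre, `floor((start+end)/2)`, lies within
2,000 bp (strict `<`) of the nearest TSS on the same chromosome, otherwise
an enhancer; a region at exactly 2,000 bp is an enhancer (both stated
inequalities are strict, so the measure-zero boundary had to be assigned
one way).  The centre is used for classification as well as for promoter
annotation (nearest TSS to the centre, ties broken by lexicographically
smallest gene id) so that one reference point drives both decisions;
boundary-based distance is left as a configuration choice.  Regions on
chromosomes with no annotated TSS are enhancers, flagged.

Enhancer target-gene candidates come from linear windows of 100, 200 and
400 kb around the region boundaries: genes with a TSS in
`[start − w, end + w)` (closed lower, open upper bound, mirroring half-open
intervals).  The window sets are nested by construction.  No contact or TAD
information is used — the windows are an explicit "close enough to be
contacted" heuristic.

## Cell-specificity

Between two conditions, a region is *shared* when some region of the other
condition overlaps it by at least 0.3 of **both** interval lengths
(`reciprocal_mode="both"`, the bedtools `-f 0.3 -r` reading — "reciprocal"
is read as requiring both directions; an either-direction mode is exposed
but not default).  The comparison is `≥` for shared.  When a region overlaps
several partners, per-partner fractions are evaluated pairwise and the best
pair decides; an aggregate mode that sums overlaps exists but is off by
default because the pairwise rule is the simplest falsifiable reading.
Specificity is computed within a class (promoters against promoters,
enhancers against enhancers, super-enhancers against super-enhancers).

## Super-enhancers

Enhancers wholly contained in a ±2,500 bp window around any TSS (a total
5,000 bp promoter exclusion zone; partial overlap does not exclude) are
removed, the rest are stitched when separated by at most 12,500 bp
(boundary inclusive), and each stitched cluster's signal is the sum of its
constituents' input-subtracted signals (raw sums, not length-normalised
densities — the choice is documented rather than assumed, and rescaling
invariance makes it immaterial to the call itself).

Clusters are sorted by ascending signal; ranks are scaled to `rank/N` and
signals to `[0, 1]`.  The cutoff is the point where a line of slope 1 is
tangent from below to the convex rank-signal curve, computed parameter-free
as `argmin(scaled_signal − scaled_rank)`; clusters with signal strictly
above the cutoff signal are super-enhancers.  This tangent construction is
deterministic, needs no smoothing, and on convex curves coincides with an
exhaustive slope-1 secant search (checked against one in the tests).
Degenerate inputs — fewer than three clusters, or a flat signal profile —
produce no super-enhancers, with a warning.  Ties in signal take a stable
secondary sort on (chrom, start), and the strict `>` at the cutoff means an
equal-signal group is never split.

## Expression integration

The differential-expression table (gene, log2FC, raw p, BH-adjusted p) is
consumed, not fitted; log2FC is numerator over denominator as named in the
comparison.  Benjamini–Hochberg adjustment is the standard step-up
(`q_(i) = p_(i)·m/i`, monotonised from the largest rank down, capped at 1)
and is recomputed when a table arrives without the adjusted column.

Concordance: for regions specific to the numerator condition, window genes
must have `log2FC ≥ +t` and `padj < 0.05`; for denominator-specific
regions, `log2FC ≤ −t`.  Thresholds are t = 1.5 for enhancer-linked genes
and t = 1.0 for super-enhancer-linked genes, on the 400 kb window.  The padj
gate is strict and the fold-change gate inclusive (the boundary is measure
zero but has to be fixed).  Genes linked by several regions count once per
set; genes absent from the DE table are excluded and tallied.

Two rank tests validate the expression claims, both one-sided by default
because the claims are directional (two-sided by flag):

* **near vs global** — two-sample rank-sum of per-gene within-condition
  mean expression, region-linked genes against all genes *not* in the
  linked set.  The background excludes the linked genes: with the linked
  genes included in the background the two samples share members, the
  independence assumption fails, and the test is no longer calibrated —
  the Monte-Carlo null check below is exactly what this choice protects.
  The null is enumerated exactly when both groups have ≤ 8 genes and uses
  the continuity-corrected normal approximation otherwise (the two branches
  agree to within 0.01 at the boundary).
* **cross-population** — paired signed-rank of per-gene mean expression in
  the region's own condition minus the other condition, over genes linked
  to that condition's specific regions.  All-zero differences return the
  null (p = 1) rather than an error.

Per-gene within-condition means (rather than per-sample values) are the
unit of analysis; this keeps the two tests on the same footing and avoids
pseudo-replication across samples.

## Synthetic benchmark

The generator plants a known regulatory architecture and corrupts it with
the noise sources the pipeline is supposed to absorb.  Defaults (all in
`SimulationConfig`): a 4 × 20 Mb genome with 400 genes placed uniformly at
≥ 2 kb spacing; 60 shared sites (30% promoters planted at a TSS, the rest
enhancers) and 30 condition-specific enhancers per condition; per-replicate
peak emission with probability 0.9 (4 replicates/condition), ±50 bp
boundary jitter, log-normal per-replicate signal noise (σ = 0.25) on a
long-tailed site signal — LN(ln 20, 0.8) for typical sites, LN(ln 300,
0.3) for the 10% flagged as super-enhancers, a ~15× separation of medians
that makes the rank curve convex with a sharp elbow; 2 spurious
single-replicate background peaks per Mb per replicate; and expression
baseline N(5, 1.5) per gene with a +2 log2FC effect in the matching
condition for genes within 400 kb of a condition-specific site, sample
noise N(0, 0.5), and DE p-values from a two-sample t-test on the 4 + 4
simulated samples (a stand-in for a count-model fit, which needs raw reads
this generator does not produce; in the zero-noise limit the degenerate
test is defined as p = 0 when means differ, 1 otherwise, so the noiseless
identity checks are well-posed).

Placement enforces ≥ 30 kb between any two planted sites (so consensus
merging and 12.5 kb stitching never fuse distinct sites), ≥ 850 kb between
condition-specific sites (more than twice the 400 kb link window, so no
gene can be linked to specific sites of both conditions), and ≥ 5 kb from
any TSS for enhancer sites (so they classify as enhancers and never fall in
the stitching exclusion zone).  These clearances are what make the
noiseless configuration (`SimulationConfig.noiseless()`: perfect
reproducibility, zero jitter/background/expression noise, tightened signal
spread) an exact identity: every stage count equals the planted truth and
repeated runs are byte-identical.  All randomness derives from one seed
through named sub-streams (annotation / planting / peaks / expression), so
changing one component's parameters does not perturb the draws of another.

What the generator does **not** emulate: read-level artefacts (mappability,
GC bias, fragment-length effects), copy-number variation, correlated
replicate failures, peak-width/signal correlation, overdispersed counts
(expression noise is Gaussian on a log scale), and any real genome
annotation.  Passing the benchmark therefore shows the *logic* of every
stage is correct under controlled noise, not that the defaults are tuned
for any particular organism or antibody.

Benchmark sizes were chosen to keep the full suite and the acceptance
script in the low minutes on one core: ten studies (seeds 1–10) for the
recovery benchmark, 2,000 Monte-Carlo draws for the null calibration, 200
random instances for the interval-layer oracle equivalence and 100 curves
for the cutoff oracle.  At the default conditions the pipeline recovers
~99.7% of planted specific regions, ~98% of planted super-enhancers and
~93% of planted region→gene links (pooled over the ten studies; the link
losses are dominated by sampling noise of the estimated fold change around
the 1.5 threshold, since the ±2 planted effect is estimated from 4 + 4
samples with σ = 0.5), and the cross-population test rejects its null in
every study.

## Limitations

* Linear windows over-assign targets relative to contact data; the
  concordance filter compensates only where expression is informative.
* The inflection-point construction assumes a globally convex rank curve;
  heavy ties or bimodal signal can place the cutoff conservatively (more
  clusters called typical).
* Region-level replicate support is permissive for long chained components;
  the strict base-wise variant is not implemented, only the region-level
  rule with the component semantics stated above.
* The Wilcoxon validations treat genes as independent; co-regulated gene
  clusters inside one window violate this mildly, which is one reason the
  validations are reported with medians rather than used as gates.
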