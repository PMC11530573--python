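"""Synthetic two-condition H3K27ac study with known planted structure.

The generator emulates the statistical structure the pipeline assumes:

* a small multi-chromosome genome with uniformly placed gene TSSs;
* planted regulatory sites — shared promoters/enhancers present in both
  conditions and condition-specific enhancers present in one — spaced so
  that consensus merging, stitching, and gene windows of different sites do
  not interfere;
* per-replicate peaks emitted from each site with a controllable
  reproducibility, boundary jitter, log-normal signal noise, and spurious
  single-replicate background peaks;
* a long-tailed (log-normal) net-signal distribution in which a fraction of
  enhancer sites is given an outlier "super-enhancer" tail, producing the
  convex rank-signal curve the cutoff search expects;
* a normalized expression matrix and a differential-expression table in
  which genes within the link window of a condition-specific site are
  up-regulated in the matching condition by ``effect_log2fc``.

All randomness flows from one seed through named sub-streams (annotation,
planting, peaks, expression), so regenerating with the same config is
bit-identical and changing one component does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import DERecord, ExpressionMatrix, bh_adjust, write_de_table
from .intervals import GenomicInterval, Peak, TSSRecord, write_peaks, write_tss

__all__ = [
    "SimulationConfig",
    "PlantedRegion",
    "PlantedLink",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_annotation",
    "plant_regions",
    "simulate_peaks",
    "simulate_expression",
    "simulate_study",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    Signal magnitudes are log-normal: typical sites ~ LN(ln 20, 0.8) per
    replicate, super-enhancer-flagged sites ~ LN(ln 300, 0.3), i.e. a ~15x
    separation of medians that yields a convex hockey-stick rank curve.
    """

    seed: int = 0
    conditions: tuple[str, str] = ("A", "B")
    # genome & annotation
    n_chromosomes: int = 4
    chrom_length: int = 20_000_000
    n_genes: int = 400
    tss_min_spacing: int = 2_000
    # planted regulatory sites
    n_shared_regions: int = 60
    n_specific_regions_per_condition: int = 30
    promoter_fraction: float = 0.3        # of shared sites, planted at a TSS
    enhancer_width_log_mean: float = math.log(1_500.0)
    enhancer_width_log_sd: float = 0.35
    promoter_width: int = 1_500
    region_min_spacing: int = 30_000      # between any two planted sites
    specific_region_spacing: int = 850_000  # between condition-specific sites
    tss_clearance: int = 5_000            # enhancer centre kept this far from TSS
    # ChIP replicates
    n_replicates_per_condition: int = 4
    replicate_reproducibility: float = 0.9
    peak_jitter_bp: int = 50
    signal_log_mean: float = math.log(20.0)
    signal_log_sd: float = 0.8
    se_fraction: float = 0.1
    se_signal_log_mean: float = math.log(300.0)
    se_signal_log_sd: float = 0.3
    replicate_signal_log_sd: float = 0.25
    input_log_mean: float = math.log(2.0)
    input_log_sd: float = 0.3
    background_fp_rate: float = 2.0       # spurious peaks / Mb / replicate
    background_signal_log_mean: float = math.log(5.0)
    background_signal_log_sd: float = 0.5
    # expression
    link_window_kb: int = 400
    effect_log2fc: float = 2.0
    expr_noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5

    def validate(self) -> None:
        for name in ("replicate_reproducibility", "promoter_fraction", "se_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        counts = (
            "n_chromosomes", "chrom_length", "n_genes", "n_shared_regions",
            "n_specific_regions_per_condition", "peak_jitter_bp",
        )
        for name in counts:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates_per_condition < 3:
            raise ValueError("n_replicates_per_condition must be >= 3")
        if self.expr_noise_sd < 0 or self.background_fp_rate < 0:
            raise ValueError("noise/rate parameters must be >= 0")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ValueError("conditions must be two distinct labels")
        genome = self.n_chromosomes * self.chrom_length
        # Rough packing feasibility: specific sites need mutual clearance,
        # everything needs region_min_spacing.  Refuse plainly infeasible setups
        # rather than spinning in rejection sampling.
        need = (
            2 * self.n_specific_regions_per_condition * self.specific_region_spacing
            + self.n_shared_regions * self.region_min_spacing
        )
        if need > 0.8 * genome:
            raise ValueError(
                f"genome too small to place regions non-adjacently: need ~{need} bp "
                f"of clearance on a {genome} bp genome"
            )
        if self.n_genes > 1 and (self.n_genes - 1) * self.tss_min_spacing >= genome:
            raise ValueError("infeasible TSS spacing")

    @classmethod
    def noiseless(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Preset in which every downstream stage is an identity check.

        All stochastic corruption is switched off (perfect reproducibility,
        no jitter, no background peaks, no expression noise) and the signal
        distributions are tightened so the super-enhancer tail is cleanly
        separable.
        """
        base = dict(
            seed=seed,
            replicate_reproducibility=1.0,
            peak_jitter_bp=0,
            background_fp_rate=0.0,
            expr_noise_sd=0.0,
            replicate_signal_log_sd=0.0,
            input_log_sd=0.0,
            signal_log_sd=0.1,
            se_signal_log_sd=0.05,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class PlantedRegion:
    site_id: str
    interval: GenomicInterval
    kind: str                 # "promoter" | "enhancer"
    specificity: str          # "shared" | condition name
    is_se: bool
    base_signal: dict         # condition -> expected per-replicate net signal
    anchor_gene: str | None = None   # promoters: the TSS the site was planted at

    def present_in(self, condition: str) -> bool:
        return self.specificity in ("shared", condition)


@dataclass(frozen=True)
class PlantedLink:
    site_id: str
    gene_id: str
    condition: str            # condition in which the gene is up-regulated
    effect_log2fc: float


@dataclass
class GroundTruth:
    conditions: tuple[str, str]
    tss: list[TSSRecord]
    regions: list[PlantedRegion]
    links: list[PlantedLink]

    def __post_init__(self) -> None:
        sites = {r.site_id for r in self.regions}
        genes = {t.gene_id for t in self.tss}
        for link in self.links:
            if link.site_id not in sites or link.gene_id not in genes:
                raise ValueError(f"dangling planted link {link}")

    def regions_in(self, condition: str) -> list[PlantedRegion]:
        return [r for r in self.regions if r.present_in(condition)]

    def specific_regions(self, condition: str) -> list[PlantedRegion]:
        return [r for r in self.regions if r.specificity == condition]

    def se_regions(self, condition: str) -> list[PlantedRegion]:
        return [r for r in self.regions if r.is_se and r.present_in(condition)]

    def linked_genes(self, condition: str) -> set[str]:
        return {l.gene_id for l in self.links if l.condition == condition}

    def expected_counts(self) -> dict:
        """Per-stage counts a noiseless run must reproduce exactly."""
        a, b = self.conditions
        counts: dict = {}
        for cond in self.conditions:
            present = self.regions_in(cond)
            promoters = [r for r in present if r.kind == "promoter"]
            enhancers = [r for r in present if r.kind == "enhancer"]
            counts[cond] = {
                "consensus_regions": len(present),
                "promoters": len(promoters),
                "enhancers": len(enhancers),
                "stitched": len(enhancers),
                "superenhancers": len([r for r in enhancers if r.is_se]),
            }
        shared_enh = [r for r in self.regions if r.kind == "enhancer"
                      and r.specificity == "shared"]
        shared_prom = [r for r in self.regions if r.kind == "promoter"
                       and r.specificity == "shared"]
        n_se_shared = len([r for r in shared_enh if r.is_se])
        counts["specificity"] = {
            "promoter": {
                "shared": {a: len(shared_prom), b: len(shared_prom)},
                "specific": {a: 0, b: 0},
            },
            "enhancer": {
                "shared": {a: len(shared_enh), b: len(shared_enh)},
                "specific": {
                    a: len([r for r in self.specific_regions(a) if r.kind == "enhancer"]),
                    b: len([r for r in self.specific_regions(b) if r.kind == "enhancer"]),
                },
            },
            "superenhancer": {
                "shared": {a: n_se_shared, b: n_se_shared},
                "specific": {
                    a: len([r for r in self.specific_regions(a) if r.is_se]),
                    b: len([r for r in self.specific_regions(b) if r.is_se]),
                },
            },
        }
        se_links = {
            cond: {l.gene_id for l in self.links if l.condition == cond
                   and any(r.site_id == l.site_id and r.is_se for r in self.regions)}
            for cond in self.conditions
        }
        counts["concordant"] = {
            "enhancer": {cond: len(self.linked_genes(cond)) for cond in self.conditions},
            "superenhancer": {cond: len(se_links[cond]) for cond in self.conditions},
        }
        return counts


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    truth: GroundTruth
    peaks: dict               # condition -> replicate_id -> list[Peak]
    expression: ExpressionMatrix
    de_table: list[DERecord]

    def write(self, out_dir: str | Path) -> None:
        """Write peaks (BED5+ per replicate), tss.tsv, expr.tsv, de_table.tsv, truth.json."""
        out = Path(out_dir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        write_tss(out / "tss.tsv", self.truth.tss)
        for cond, reps in self.peaks.items():
            for rep, plist in reps.items():
                write_peaks(out / "peaks" / f"{cond}.{rep}.bed", plist)
        df = self.expression.values.copy()
        df.index.name = "gene_id"
        df.to_csv(out / "expr.tsv", sep="\t", float_format="%.10g")
        write_de_table(out / "de_table.tsv", self.de_table)
        truth = {
            "conditions": list(self.truth.conditions),
            "regions": [
                {**dataclasses.asdict(r),
                 "interval": [r.interval.chrom, r.interval.start, r.interval.end]}
                for r in self.truth.regions
            ],
            "links": [dataclasses.asdict(l) for l in self.truth.links],
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(config.seed)
    names = ("annotation", "planting", "peaks", "expression")
    return {n: np.random.Generator(np.random.PCG64(s))
            for n, s in zip(names, root.spawn(len(names)))}


def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[TSSRecord]:
    """Place ``n_genes`` TSSs uniformly with minimum spacing; seed-deterministic."""
    config.validate()
    rng = rng or _streams(config)["annotation"]
    chroms = _chrom_names(config)
    per = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per[i] += 1
    records: list[TSSRecord] = []
    gi = 0
    s = config.tss_min_spacing
    for chrom, k in zip(chroms, per):
        if k == 0:
            continue
        free = config.chrom_length - (k - 1) * s
        if free <= 0:
            raise ValueError(f"infeasible TSS spacing on {chrom}")
        # Spacing trick: sorted uniforms on the shrunk axis + i*s restores >= s gaps.
        base = np.sort(rng.uniform(0, free, size=k))
        pos = (base + np.arange(k) * s).astype(np.int64)
        strands = rng.choice(["+", "-"], size=k)
        for p, st in zip(pos, strands):
            records.append(TSSRecord(f"g{gi:04d}", chrom, int(p), str(st)))
            gi += 1
    records.sort(key=lambda r: (r.chrom, r.tss, r.gene_id))
    return records


def _too_close(iv: GenomicInterval, placed: list[GenomicInterval], spacing: int) -> bool:
    for other in placed:
        if other.chrom != iv.chrom:
            continue
        if iv.start - other.end < spacing and other.start - iv.end < spacing:
            return True
    return False


def plant_regions(
    config: SimulationConfig,
    tss: list[TSSRecord],
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Plant shared and condition-specific sites and derive region-gene links."""
    rng = rng or _streams(config)["planting"]
    chroms = _chrom_names(config)
    tss_pos = {c: np.array(sorted(t.tss for t in tss if t.chrom == c), dtype=np.int64)
               for c in chroms}

    placed: list[GenomicInterval] = []
    specific_placed: list[GenomicInterval] = []
    regions: list[PlantedRegion] = []
    site_no = 0

    def tss_dist(chrom: str, pos: int) -> int:
        arr = tss_pos.get(chrom)
        if arr is None or arr.size == 0:
            return 10 ** 12
        return int(np.abs(arr - pos).min())

    def place_enhancer(specificity: str) -> GenomicInterval:
        for _ in range(20_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            width = int(rng.lognormal(config.enhancer_width_log_mean,
                                      config.enhancer_width_log_sd))
            width = max(width, 200)
            start = int(rng.integers(width, config.chrom_length - 2 * width))
            iv = GenomicInterval(chrom, start, start + width)
            if tss_dist(chrom, iv.center) < config.tss_clearance:
                continue
            if _too_close(iv, placed, config.region_min_spacing):
                continue
            if specificity != "shared" and _too_close(
                iv, specific_placed, config.specific_region_spacing
            ):
                continue
            return iv
        raise RuntimeError("could not place region; genome too crowded")

    def draw_signal(is_se: bool) -> float:
        if is_se:
            return float(rng.lognormal(config.se_signal_log_mean,
                                       config.se_signal_log_sd))
        return float(rng.lognormal(config.signal_log_mean, config.signal_log_sd))

    n_prom = round(config.n_shared_regions * config.promoter_fraction)
    n_shared_enh = config.n_shared_regions - n_prom

    # Condition-specific enhancers first: they carry the strongest placement
    # constraint (mutual clearance of twice the link window).
    for cond in config.conditions:
        for _ in range(config.n_specific_regions_per_condition):
            iv = place_enhancer(cond)
            placed.append(iv)
            specific_placed.append(iv)
            is_se = bool(rng.random() < config.se_fraction)
            regions.append(PlantedRegion(
                f"s{site_no:04d}", iv, "enhancer", cond, is_se,
                {cond: draw_signal(is_se)},
            ))
            site_no += 1

    for _ in range(n_shared_enh):
        iv = place_enhancer("shared")
        placed.append(iv)
        is_se = bool(rng.random() < config.se_fraction)
        regions.append(PlantedRegion(
            f"s{site_no:04d}", iv, "enhancer", "shared", is_se,
            {c: draw_signal(is_se) for c in config.conditions},
        ))
        site_no += 1

    # Shared promoters planted at gene TSSs (centre well inside the 2 kb rule).
    prom_candidates = list(tss)
    rng.shuffle(prom_candidates)
    half = config.promoter_width // 2
    planted_prom = 0
    for rec in prom_candidates:
        if planted_prom == n_prom:
            break
        offset = int(rng.integers(-500, 501))
        start = max(0, rec.tss + offset - half)
        iv = GenomicInterval(rec.chrom, start, start + config.promoter_width)
        if _too_close(iv, placed, config.region_min_spacing):
            continue
        placed.append(iv)
        regions.append(PlantedRegion(
            f"s{site_no:04d}", iv, "promoter", "shared", False,
            {c: draw_signal(False) for c in config.conditions},
            anchor_gene=rec.gene_id,
        ))
        site_no += 1
        planted_prom += 1
    if planted_prom < n_prom:
        raise RuntimeError("could not place the requested number of promoters")

    # Region->gene links: genes with a TSS inside the link window of a
    # condition-specific site.  Specific-site spacing exceeds twice the window,
    # so no gene can be linked to sites of both conditions.
    w = config.link_window_kb * 1000
    tss_by_chrom: dict[str, list[TSSRecord]] = {c: [] for c in chroms}
    for t in tss:
        tss_by_chrom[t.chrom].append(t)
    links: list[PlantedLink] = []
    for r in regions:
        if r.specificity == "shared":
            continue
        for t in tss_by_chrom[r.interval.chrom]:
            if r.interval.start - w <= t.tss < r.interval.end + w:
                links.append(PlantedLink(r.site_id, t.gene_id, r.specificity,
                                         config.effect_log2fc))
    return GroundTruth(config.conditions, list(tss), regions, links)


def simulate_peaks(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> dict:
    """Emit per-replicate peak lists per condition from the planted sites."""
    rng = rng or _streams(config)["peaks"]
    chroms = _chrom_names(config)
    reps = [f"rep{i + 1}" for i in range(config.n_replicates_per_condition)]
    out: dict[str, dict[str, list[Peak]]] = {
        c: {r: [] for r in reps} for c in config.conditions
    }
    jitter = config.peak_jitter_bp

    def jittered(iv: GenomicInterval) -> GenomicInterval:
        ds, de = (int(round(x)) for x in rng.normal(0.0, jitter or 0.0, size=2)) \
            if jitter > 0 else (0, 0)
        start = max(0, iv.start + ds)
        end = max(start + 1, iv.end + de)
        return GenomicInterval(iv.chrom, start, end)

    for cond in config.conditions:
        for site in truth.regions:
            if not site.present_in(cond):
                continue
            base = site.base_signal[cond]
            for rep in reps:
                if rng.random() >= config.replicate_reproducibility:
                    continue
                iv = jittered(site.interval)
                noise = float(rng.lognormal(0.0, config.replicate_signal_log_sd))
                inp = float(rng.lognormal(config.input_log_mean, config.input_log_sd))
                out[cond][rep].append(
                    Peak(iv, inp + base * noise, inp, replicate_id=rep, condition=cond)
                )
        # Spurious background peaks: single-replicate, low signal.
        for rep in reps:
            for chrom in chroms:
                n = int(rng.poisson(config.background_fp_rate
                                    * config.chrom_length / 1e6))
                for _ in range(n):
                    width = max(200, int(rng.lognormal(
                        config.enhancer_width_log_mean, config.enhancer_width_log_sd)))
                    start = int(rng.integers(0, config.chrom_length - width))
                    inp = float(rng.lognormal(config.input_log_mean,
                                              config.input_log_sd))
                    sig = float(rng.lognormal(config.background_signal_log_mean,
                                              config.background_signal_log_sd))
                    out[cond][rep].append(
                        Peak(GenomicInterval(chrom, start, start + width),
                             inp + sig, inp, replicate_id=rep, condition=cond)
                    )
        for rep in reps:
            out[cond][rep].sort(
                key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
            )
    return out


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, list[DERecord]]:
    """Normalized expression matrix plus a DE table for conditions[0] vs [1].

    Per-sample values are baseline + planted condition effect + Gaussian
    noise on a log2 scale.  The DE log2FC is the difference of condition
    means (numerator = conditions[0]); p-values come from a two-sample
    equal-variance t-test on the simulated replicates (a stand-in for a
    count-model fit, which consumes raw reads this generator does not
    produce) and are BH-adjusted.  With zero noise the degenerate test is
    defined as p = 0 when the means differ and p = 1 otherwise.
    """
    rng = rng or _streams(config)["expression"]
    genes = [t.gene_id for t in truth.tss]
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    cond_a, cond_b = config.conditions
    n_rep = config.n_replicates_per_condition

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    effect = {c: np.zeros(n_genes) for c in config.conditions}
    for link in truth.links:
        effect[link.condition][gene_idx[link.gene_id]] += link.effect_log2fc

    samples, columns = [], {}
    data = np.empty((n_genes, 2 * n_rep))
    col = 0
    for cond in config.conditions:
        for r in range(n_rep):
            name = f"{cond}:rep{r + 1}"
            noise = rng.normal(0.0, config.expr_noise_sd, size=n_genes) \
                if config.expr_noise_sd > 0 else np.zeros(n_genes)
            data[:, col] = baseline + effect[cond] + noise
            samples.append(name)
            columns[name] = cond
            col += 1
    values = pd.DataFrame(data, index=genes, columns=samples)
    expr = ExpressionMatrix(values, columns)

    xa = data[:, :n_rep]
    xb = data[:, n_rep:]
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    pooled = ((n_rep - 1) * va + (n_rep - 1) * vb) / (2 * n_rep - 2)
    sed = np.sqrt(pooled * (2.0 / n_rep))
    pvals = np.ones(n_genes)
    nz = sed > 0
    if nz.any():
        from scipy import stats as _st

        t = log2fc[nz] / sed[nz]
        pvals[nz] = 2.0 * _st.t.sf(np.abs(t), df=2 * n_rep - 2)
    pvals[(~nz) & (log2fc != 0)] = 0.0
    padj = bh_adjust(pvals)
    de = [DERecord(g, float(log2fc[i]), float(pvals[i]), float(padj[i]))
          for i, g in enumerate(genes)]
    return expr, de


def simulate_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedStudy:
    """Run the full generator (annotation -> planting -> peaks -> expression)."""
    config.validate()
    streams = _streams(config)
    tss = simulate_annotation(config, streams["annotation"])
    truth = plant_regions(config, tss, streams["planting"])
    peaks = simulate_peaks(config, truth, streams["peaks"])
    expr, de = simulate_expression(config, truth, streams["expression"])
    study = SimulatedStudy(config, truth, peaks, expr, de)
    if out_dir is not None:
        study.write(out_dir)
    return study
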