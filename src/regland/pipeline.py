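"""End-to-end orchestration: consensus -> classification -> specificity ->
stitching/super-enhancers -> window genes -> concordance -> validation.

The pipeline is a pure function of (inputs, parameters): re-running with the
same config and inputs produces byte-identical ``report.json``.  Parameters
are validated against their stage preconditions before any stage runs, and a
stage failure aborts with the stage name.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .expression import (
    ConcordantGeneSet,
    DERecord,
    ExpressionMatrix,
    RankTestResult,
    concordant_genes,
    cross_population_validation,
    export_gene_lists,
    near_vs_global_expression,
    read_de_table,
    read_expression,
)
from .intervals import Peak, TSSRecord, read_peaks, read_tss
from .regions import (
    ENHANCER,
    PROMOTER,
    ConsensusRegion,
    RegulatoryRegion,
    TSSIndex,
    assign_window_genes,
    classify_regions,
    consensus_regions,
)
from .specificity import SpecificityLabel, call_specificity
from .superenhancers import (
    SECall,
    StitchedEnhancer,
    call_superenhancers,
    exclude_promoter_proximal,
    stitch_enhancers,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_stages", "run_pipeline",
           "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters, with the workflow's defaults.

    Defaults: consensus requires >=2 replicates; promoters are < 2,000 bp
    from a TSS; specificity needs reciprocal overlap >= 0.3; stitching joins
    enhancers within 12,500 bp after removing those wholly inside a
    +/-2,500 bp TSS window; target genes come from 100/200/400 kb windows;
    concordance gates at |log2FC| >= 1.5 (enhancers) / 1.0 (super-enhancers)
    with BH-adjusted p < 0.05.
    """

    peaks: dict[str, list[str]] = field(default_factory=dict)  # cond -> BED paths
    tss_path: str = ""
    de_path: str = ""
    expr_path: str = ""
    out_dir: str = "regland_out"
    comparison: tuple[str, str] | None = None   # defaults to the two peak keys
    min_replicates: int = 2
    promoter_dist: int = 2000
    min_fraction: float = 0.3
    reciprocal_mode: str = "both"
    stitch_distance: int = 12500
    tss_exclusion: int = 2500
    windows: tuple[int, ...] = (100, 200, 400)
    concordance_window_kb: int = 400
    enhancer_log2fc: float = 1.5
    se_log2fc: float = 1.0
    padj_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if self.promoter_dist < 0 or self.stitch_distance < 0 or self.tss_exclusion < 0:
            raise ValueError("distances must be >= 0")
        if not 0 < self.min_fraction <= 1:
            raise ValueError(f"min_fraction must be in (0, 1], got {self.min_fraction}")
        if self.reciprocal_mode not in ("both", "any"):
            raise ValueError("reciprocal_mode must be 'both' or 'any'")
        if not self.windows or any(w <= 0 for w in self.windows):
            raise ValueError("windows must be positive")
        if self.concordance_window_kb not in self.windows:
            raise ValueError("concordance_window_kb must be one of windows")
        if self.enhancer_log2fc <= 0 or self.se_log2fc <= 0:
            raise ValueError("log2fc thresholds must be > 0")
        if not 0 < self.padj_threshold < 1:
            raise ValueError("padj_threshold must be in (0, 1)")
        if self.comparison is not None and len(self.comparison) != 2:
            raise ValueError("comparison must name exactly two conditions")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("comparison", "windows"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    comparison: tuple[str, str]
    consensus: dict[str, list[ConsensusRegion]]
    classified: dict[str, list[RegulatoryRegion]]
    promoter_labels: list[SpecificityLabel]
    enhancer_labels: list[SpecificityLabel]
    stitched: dict[str, list[StitchedEnhancer]]
    secalls: dict[str, list[SECall]]
    se_labels: list[SpecificityLabel]
    window_genes: dict[str, dict[str, dict[int, list[str]]]]  # cond -> rid -> kb
    se_window_genes: dict[str, dict[str, dict[int, list[str]]]]
    concordant: dict[str, dict[str, ConcordantGeneSet]]  # class -> condition
    validation: list[dict]
    report: dict

    def labels_for(self, klass: str) -> list[SpecificityLabel]:
        return {
            "promoter": self.promoter_labels,
            "enhancer": self.enhancer_labels,
            "superenhancer": self.se_labels,
        }[klass]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _label_counts(labels: list[SpecificityLabel], comparison: tuple[str, str]) -> dict:
    """Shared/specific tallies per side of the comparison.

    Shared counts are reported per side because multi-partner overlaps can
    make them asymmetric (two A regions sharing one B region).
    """
    a, b = comparison
    spec_a = sum(1 for l in labels if l.label == "specific_A")
    spec_b = sum(1 for l in labels if l.label == "specific_B")
    shared_a = sum(1 for l in labels if l.is_shared and l.side == 0)
    shared_b = sum(1 for l in labels if l.is_shared and l.side == 1)
    return {
        "shared": {a: shared_a, b: shared_b},
        "specific": {a: spec_a, b: spec_b},
    }


def run_stages(
    peaks_by_condition: dict[str, dict[str, list[Peak]]],
    tss: list[TSSRecord],
    de: list[DERecord],
    expr: ExpressionMatrix | None,
    config: PipelineConfig,
) -> PipelineResult:
    """Execute every analysis stage on in-memory inputs."""
    config.validate()
    comparison = config.comparison or tuple(peaks_by_condition)
    if len(comparison) != 2:
        raise PipelineError("stage 'setup' failed: need exactly two conditions")
    cond_a, cond_b = comparison
    index = TSSIndex(tss)

    consensus: dict[str, list[ConsensusRegion]] = {}
    classified: dict[str, list[RegulatoryRegion]] = {}
    for cond in comparison:
        flat = [p for plist in peaks_by_condition[cond].values() for p in plist]
        consensus[cond] = _stage("consensus")(consensus_regions)(
            flat, cond, config.min_replicates
        )
        classified[cond] = _stage("classify")(classify_regions)(
            consensus[cond], index, config.promoter_dist
        )

    def by_class(cond: str, klass: str) -> list[RegulatoryRegion]:
        return [r for r in classified[cond] if r.klass == klass]

    promoter_labels = _stage("specificity")(call_specificity)(
        by_class(cond_a, PROMOTER), by_class(cond_b, PROMOTER),
        comparison, config.min_fraction, config.reciprocal_mode,
    )
    enhancer_labels = _stage("specificity")(call_specificity)(
        by_class(cond_a, ENHANCER), by_class(cond_b, ENHANCER),
        comparison, config.min_fraction, config.reciprocal_mode,
    )

    stitched: dict[str, list[StitchedEnhancer]] = {}
    secalls: dict[str, list[SECall]] = {}
    for cond in comparison:
        kept = _stage("se_exclusion")(exclude_promoter_proximal)(
            by_class(cond, ENHANCER), index, config.tss_exclusion
        )
        stitched[cond] = _stage("stitch")(stitch_enhancers)(
            kept, config.stitch_distance
        )
        secalls[cond] = _stage("se_call")(call_superenhancers)(stitched[cond])

    se_only = {c: [s for s in secalls[c] if s.is_super] for c in comparison}
    se_labels = _stage("se_specificity")(call_specificity)(
        se_only[cond_a], se_only[cond_b],
        comparison, config.min_fraction, config.reciprocal_mode,
    )

    window_genes: dict[str, dict[str, dict[int, list[str]]]] = {}
    se_window_genes: dict[str, dict[str, dict[int, list[str]]]] = {}
    for cond in comparison:
        window_genes[cond] = {
            r.region_id: {
                w: assign_window_genes(r, index, w) for w in config.windows
            }
            for r in by_class(cond, ENHANCER)
        }
        se_window_genes[cond] = {
            s.region_id: {
                w: assign_window_genes(s.interval, index, w) for w in config.windows
            }
            for s in se_only[cond]
        }

    de_index = {rec.gene_id: rec for rec in de}
    wkb = config.concordance_window_kb
    enh_links = {rid: wins[wkb]
                 for cond in comparison
                 for rid, wins in window_genes[cond].items()}
    se_links = {rid: wins[wkb]
                for cond in comparison
                for rid, wins in se_window_genes[cond].items()}
    concordant = {
        "enhancer": _stage("concordance")(concordant_genes)(
            enhancer_labels, enh_links, de_index, "enhancer",
            config.enhancer_log2fc, config.padj_threshold, wkb,
        ),
        "superenhancer": _stage("concordance")(concordant_genes)(
            se_labels, se_links, de_index, "superenhancer",
            config.se_log2fc, config.padj_threshold, wkb,
        ),
    }

    validation = _validation_stage(
        comparison, enhancer_labels, se_labels, enh_links, se_links, expr
    )

    report = _build_report(
        config, comparison, consensus, classified, promoter_labels,
        enhancer_labels, stitched, secalls, se_labels, concordant, validation,
    )
    return PipelineResult(
        comparison, consensus, classified, promoter_labels, enhancer_labels,
        stitched, secalls, se_labels, window_genes, se_window_genes,
        concordant, validation, report,
    )


def _specific_linked_genes(
    labels: list[SpecificityLabel], links: dict[str, list[str]], side: str
) -> list[str]:
    genes: set[str] = set()
    for lab in labels:
        if lab.label == side:
            genes.update(links.get(lab.region_id, ()))
    return sorted(genes)


def _validation_stage(
    comparison: tuple[str, str],
    enhancer_labels: list[SpecificityLabel],
    se_labels: list[SpecificityLabel],
    enh_links: dict[str, list[str]],
    se_links: dict[str, list[str]],
    expr: ExpressionMatrix | None,
) -> list[dict]:
    """Rank-test validations of the expression claims, per class and side.

    For each condition: (i) genes linked to that condition's specific
    regions vs the remaining genes, within the condition (near-vs-global);
    (ii) the same genes' expression in their own condition vs the other
    (cross-population, paired).  Sides with fewer than 2 linked genes are
    reported with p = None rather than failing the run.
    """
    if expr is None:
        return []
    rows: list[dict] = []
    sides = {comparison[0]: "specific_A", comparison[1]: "specific_B"}
    for klass, labels, links in (
        ("enhancer", enhancer_labels, enh_links),
        ("superenhancer", se_labels, se_links),
    ):
        for cond, side in sides.items():
            other = comparison[1] if cond == comparison[0] else comparison[0]
            genes = _specific_linked_genes(labels, links, side)
            for test, fn in (
                ("near_vs_global", lambda: near_vs_global_expression(genes, expr, cond)),
                ("cross_population",
                 lambda: cross_population_validation(genes, expr, cond, other)),
            ):
                row = {"class": klass, "condition": cond, "test": test,
                       "n_genes": len(genes)}
                try:
                    res = fn()
                    row.update(statistic=res.statistic, pvalue=res.pvalue,
                               median_region=res.median_region,
                               median_background=res.median_background,
                               method=res.method)
                except ValueError as exc:
                    row.update(statistic=None, pvalue=None, median_region=None,
                               median_background=None, method=f"skipped: {exc}")
                rows.append(row)
    return rows


def _build_report(
    config: PipelineConfig,
    comparison: tuple[str, str],
    consensus: dict[str, list[ConsensusRegion]],
    classified: dict[str, list[RegulatoryRegion]],
    promoter_labels: list[SpecificityLabel],
    enhancer_labels: list[SpecificityLabel],
    stitched: dict[str, list[StitchedEnhancer]],
    secalls: dict[str, list[SECall]],
    se_labels: list[SpecificityLabel],
    concordant: dict[str, dict[str, ConcordantGeneSet]],
    validation: list[dict],
) -> dict:
    # Parameter echo: the analysis parameters only.  Paths are run-local and
    # would break byte-identity of reports across otherwise identical runs.
    params = dataclasses.asdict(config)
    for key in ("peaks", "tss_path", "de_path", "expr_path", "out_dir"):
        params.pop(key, None)
    counts = {}
    for cond in comparison:
        counts[cond] = {
            "consensus_regions": len(consensus[cond]),
            "promoters": sum(1 for r in classified[cond] if r.klass == PROMOTER),
            "enhancers": sum(1 for r in classified[cond] if r.klass == ENHANCER),
            "stitched": len(stitched[cond]),
            "superenhancers": sum(1 for s in secalls[cond] if s.is_super),
        }
    specificity = {
        klass: _label_counts(labels, comparison)
        for klass, labels in (
            ("promoter", promoter_labels),
            ("enhancer", enhancer_labels),
            ("superenhancer", se_labels),
        )
    }
    return {
        "version": __version__,
        "comparison": list(comparison),
        "parameters": params,
        "counts": counts,
        "specificity": specificity,
        "concordant": {
            klass: {cond: len(cset.genes) for cond, cset in sets.items()}
            for klass, sets in concordant.items()
        },
        "validation": validation,
    }


# ---------------------------------------------------------------------------
# File-level entry point


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every stage table plus report.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cond in result.comparison:
        for r in result.classified[cond]:
            rows.append([
                r.interval.chrom, r.interval.start, r.interval.end, cond,
                r.region.support, repr(float(r.region.net_signal)), r.klass,
                r.anchor_gene or ".",
            ])
    _write_tsv(out / "regions.tsv",
               ["chrom", "start", "end", "condition", "support", "net_signal",
                "class", "anchor_gene"], rows)

    for klass in ("promoter", "enhancer", "superenhancer"):
        labels = result.labels_for(klass)
        _write_tsv(
            out / f"specificity_{klass}.tsv",
            ["region_id", "comparison", "label", "partner_id", "frac_self",
             "frac_partner"],
            [[l.region_id, f"{l.comparison[0]}_vs_{l.comparison[1]}", l.label,
              l.partner_id or ".", f"{l.frac_self:.6g}", f"{l.frac_partner:.6g}"]
             for l in labels],
        )

    for cond in result.comparison:
        _write_tsv(
            out / f"superenhancers_{cond}.tsv",
            ["chrom", "start", "end", "n_constituents", "net_signal", "rank",
             "is_super", "cutoff_signal"],
            [[c.interval.chrom, c.interval.start, c.interval.end,
              len(c.stitched.constituents), repr(float(c.net_signal)), c.rank,
              int(c.is_super), repr(float(c.cutoff_signal))]
             for c in result.secalls[cond]],
        )

    rows = []
    for cond in result.comparison:
        for source in (result.window_genes[cond], result.se_window_genes[cond]):
            for rid, wins in source.items():
                for w, genes in wins.items():
                    for g in genes:
                        rows.append([rid, w, g])
    _write_tsv(out / "enhancer_genes.tsv", ["region_id", "window_kb", "gene_id"], rows)

    export_gene_lists(
        [cset for sets in result.concordant.values() for cset in sets.values()], out
    )
    _write_tsv(
        out / "validation_report.tsv",
        ["class", "condition", "test", "n_genes", "statistic", "pvalue",
         "median_region", "median_background", "method"],
        [[v["class"], v["condition"], v["test"], v["n_genes"],
          "." if v["statistic"] is None else f"{v['statistic']:.6g}",
          "." if v["pvalue"] is None else repr(float(v["pvalue"])),
          "." if v["median_region"] is None else f"{v['median_region']:.6g}",
          "." if v["median_background"] is None else f"{v['median_background']:.6g}",
          v["method"]] for v in result.validation],
    )
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    (out / "pipeline.log").write_text(
        f"regland {__version__}\nparameters: "
        + json.dumps(result.report["parameters"], sort_keys=True)
        + "\n"
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read inputs from the paths in ``config``, run all stages, write outputs."""
    config.validate()
    if not config.peaks or not config.tss_path:
        raise PipelineError("stage 'setup' failed: peak files and tss_path required")
    peaks_by_condition: dict[str, dict[str, list[Peak]]] = {}
    for cond, paths in config.peaks.items():
        reps: dict[str, list[Peak]] = {}
        for i, path in enumerate(sorted(paths), start=1):
            plist = read_peaks(path, cond, default_replicate=f"rep{i}")
            for p in plist:
                reps.setdefault(p.replicate_id, []).append(p)
        peaks_by_condition[cond] = reps
    tss = read_tss(config.tss_path)
    de = read_de_table(config.de_path) if config.de_path else []
    expr = read_expression(config.expr_path) if config.expr_path else None
    result = run_stages(peaks_by_condition, tss, de, expr, config)
    write_outputs(result, config.out_dir)
    return result
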