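"""Integration of cell-specific regulatory regions with expression tables.

Covers Benjamini-Hochberg adjustment, concordance filtering of window genes
against a differential-expression table, rank-based validation that genes
near regulatory regions are more highly expressed than background, and
export of ranked gene lists for downstream enrichment tools.

Concordance: for a region specific to the numerator condition of an A-vs-B
comparison, linked genes must have log2FC >= +threshold and BH-adjusted
p < 0.05; for denominator-specific regions, log2FC <= -threshold.  Default
thresholds are 1.5 for enhancer-linked genes and 1.0 for super-enhancer-
linked genes.  The padj gate is strict (<), the fold-change gate inclusive.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .specificity import SpecificityLabel

log = logging.getLogger(__name__)

__all__ = [
    "DERecord",
    "ExpressionMatrix",
    "ConcordantGeneSet",
    "RankTestResult",
    "bh_adjust",
    "concordant_genes",
    "near_vs_global_expression",
    "cross_population_validation",
    "export_gene_lists",
    "read_de_table",
    "write_de_table",
    "read_expression",
]

DEFAULT_LOG2FC = {"enhancer": 1.5, "superenhancer": 1.0, "SE": 1.0}
EXACT_MAX_N = 8  # per group: exact rank-test null enumeration below this size


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-expression table (numerator vs denominator)."""

    gene_id: str
    log2fc: float
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        if not (0 <= self.pvalue <= 1 and 0 <= self.padj <= 1):
            raise ValueError(f"p-values out of [0,1] for {self.gene_id}")


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x samples, with a sample -> condition map."""

    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        unmapped = set(self.values.columns) - set(self.condition_of)
        if unmapped:
            raise ValueError(f"samples without condition label: {sorted(unmapped)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def condition_mean(self, condition: str) -> pd.Series:
        cols = self.samples_for(condition)
        if not cols:
            raise ValueError(f"no samples for condition {condition!r}")
        return self.values[cols].mean(axis=1)


@dataclass
class ConcordantGeneSet:
    """Window genes whose DE direction and magnitude match region specificity."""

    comparison: tuple[str, str]
    region_class: str
    window_kb: int
    specific_to: str
    genes: list[tuple[str, float, float]]  # (gene_id, log2fc, padj)
    n_missing: int = 0                     # linked genes absent from the DE table

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _, _ in self.genes]


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    pvalue: float | None
    n_region: int
    n_background: int
    median_region: float
    median_background: float
    method: str = ""


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = p_(i) * m / i on the ascending sort, monotonised from the largest
    rank downwards and capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(q, 1.0)
    return out


def concordant_genes(
    labels: Iterable[SpecificityLabel],
    gene_links: Mapping[str, Sequence[str]],
    de: Mapping[str, DERecord] | Iterable[DERecord],
    region_class: str,
    log2fc_threshold: float | None = None,
    padj_threshold: float = 0.05,
    window_kb: int = 400,
) -> dict[str, ConcordantGeneSet]:
    """Concordance-filter window genes of condition-specific regions.

    Returns one :class:`ConcordantGeneSet` per side of the comparison, keyed
    by the condition the regions are specific to.  Genes linked by several
    regions are counted once; genes missing from the DE table are excluded
    and tallied in ``n_missing``.
    """
    if log2fc_threshold is None:
        log2fc_threshold = DEFAULT_LOG2FC[region_class]
    if log2fc_threshold <= 0:
        raise ValueError("log2fc_threshold must be > 0")
    de_index: Mapping[str, DERecord]
    if isinstance(de, Mapping):
        de_index = de
    else:
        de_index = {rec.gene_id: rec for rec in de}

    labels = list(labels)
    if not labels:
        raise ValueError("no specificity labels supplied")
    comparison = labels[0].comparison
    sides = {"specific_A": comparison[0], "specific_B": comparison[1]}
    out: dict[str, ConcordantGeneSet] = {}
    for label_name, condition in sides.items():
        sign = 1.0 if condition == comparison[0] else -1.0
        genes: set[str] = set()
        missing = 0
        for lab in labels:
            if lab.label != label_name:
                continue
            for g in gene_links.get(lab.region_id, ()):
                genes.add(g)
        kept: list[tuple[str, float, float]] = []
        for g in genes:
            rec = de_index.get(g)
            if rec is None:
                missing += 1
                continue
            if sign * rec.log2fc >= log2fc_threshold and rec.padj < padj_threshold:
                kept.append((g, rec.log2fc, rec.padj))
        kept.sort(key=lambda t: (-abs(t[1]), t[0]))
        out[condition] = ConcordantGeneSet(
            comparison, region_class, window_kb, condition, kept, missing
        )
        if missing:
            log.info(
                "%d linked gene(s) specific to %s absent from DE table",
                missing, condition,
            )
    return out


def _rank_sum(
    region_values: np.ndarray,
    background_values: np.ndarray,
    alternative: str,
) -> tuple[float, float, str]:
    n1, n2 = len(region_values), len(background_values)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        method, name = "exact", "rank-sum (exact)"
    else:
        method, name = "asymptotic", "rank-sum (normal approx., continuity-corrected)"
    res = stats.mannwhitneyu(
        region_values, background_values, alternative=alternative,
        method=method, use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue), name


def near_vs_global_expression(
    region_genes: Sequence[str],
    expr: ExpressionMatrix,
    condition: str,
    alternative: str = "greater",
) -> RankTestResult:
    """Rank-sum comparison of region-linked vs background gene expression.

    Compares the per-gene mean normalized expression within ``condition`` of
    region-linked genes against all remaining genes.  One-sided ("greater")
    by default, matching the directional claim that genes near active
    regulatory regions are more highly expressed; the null is enumerated
    exactly when both groups have at most 8 genes.
    """
    region_set = set(region_genes)
    if not region_set:
        raise ValueError("empty region gene set")
    means = expr.condition_mean(condition)
    region = means[means.index.isin(region_set)].to_numpy(dtype=float)
    background = means[~means.index.isin(region_set)].to_numpy(dtype=float)
    if len(region) < 2 or len(background) < 2:
        raise ValueError(
            f"need >=2 genes per group, got {len(region)} region / "
            f"{len(background)} background"
        )
    statistic, pvalue, method = _rank_sum(region, background, alternative)
    return RankTestResult(
        statistic, pvalue, len(region), len(background),
        float(np.median(region)), float(np.median(background)), method,
    )


def cross_population_validation(
    region_genes: Sequence[str],
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    alternative: str = "greater",
) -> RankTestResult:
    """Paired signed-rank test of linked-gene expression in cond_a vs cond_b.

    Tests whether genes linked to cond_a-specific regions are more highly
    expressed in cond_a than in cond_b (per-gene within-condition means,
    one-sided by default).  With all differences zero the result is the null
    (p = 1).
    """
    region_set = set(region_genes)
    if not region_set:
        raise ValueError("empty region gene set")
    mean_a = expr.condition_mean(cond_a)
    mean_b = expr.condition_mean(cond_b)
    common = [g for g in mean_a.index if g in region_set]
    if len(common) < 2:
        raise ValueError(f"need >=2 linked genes with expression, got {len(common)}")
    diffs = (mean_a[common] - mean_b[common]).to_numpy(dtype=float)
    median_diff = float(np.median(diffs))
    if np.all(diffs == 0):
        return RankTestResult(0.0, 1.0, len(common), len(common), median_diff, 0.0,
                              "signed-rank (degenerate: all ties)")
    res = stats.wilcoxon(diffs, alternative=alternative, method="auto")
    return RankTestResult(
        float(res.statistic), float(res.pvalue), len(common), len(common),
        median_diff, 0.0, "signed-rank",
    )


def export_gene_lists(
    sets: Iterable[ConcordantGeneSet], out_dir: str | Path
) -> list[Path]:
    """Write one ranked gene list per set (TSV with stats + plain-text ids).

    Ordering is deterministic: |log2fc| descending, then gene id ascending.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for s in sets:
        stem = (
            f"concordant_{s.region_class}_{s.comparison[0]}_vs_{s.comparison[1]}"
            f"_{s.specific_to}_w{s.window_kb}"
        )
        tsv = out_dir / f"{stem}.tsv"
        with open(tsv, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene_id", "log2fc", "padj"])
            for gene, fc, padj in s.genes:
                w.writerow([gene, repr(float(fc)), repr(float(padj))])
        txt = out_dir / f"{stem}.txt"
        txt.write_text("".join(f"{g}\n" for g, _, _ in s.genes))
        written.extend([tsv, txt])
    return written


# ---------------------------------------------------------------------------
# Tabular I/O


def read_de_table(path: str | Path, recompute_padj_if_absent: bool = True) -> list[DERecord]:
    """Read a DE table TSV (gene_id, log2fc, pvalue[, padj]).

    When the padj column is absent it is recomputed from the raw p-values
    with :func:`bh_adjust`.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    if "padj" not in df.columns:
        if not recompute_padj_if_absent:
            raise ValueError("DE table lacks a padj column")
        df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    return [
        DERecord(str(r.gene_id), float(r.log2fc), float(r.pvalue), float(r.padj))
        for r in df.itertuples(index=False)
    ]


def write_de_table(path: str | Path, records: Sequence[DERecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "log2fc", "pvalue", "padj"])
        for r in records:
            w.writerow([r.gene_id, repr(float(r.log2fc)), repr(float(r.pvalue)),
                        repr(float(r.padj))])


def read_expression(
    path: str | Path, sample_conditions: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    Sample columns named ``condition:replicate`` carry their condition label
    in the name; otherwise an explicit ``sample_conditions`` map is required.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if sample_conditions is None:
        sample_conditions = {}
        for col in df.columns:
            if ":" not in col:
                raise ValueError(
                    f"sample {col!r} has no 'condition:replicate' name and no "
                    "explicit condition map was given"
                )
            sample_conditions[col] = col.split(":", 1)[0]
    return ExpressionMatrix(df, dict(sample_conditions))
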