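"""Replicate-consensus H3K27ac regions and promoter/enhancer classification.

A consensus region is a connected component of the union of all replicate
peaks for one condition (gap 0), kept only when at least ``min_replicates``
distinct replicates contribute a peak to the component.  Replicate support is
evaluated on the merged component, not base-wise: a chained component counts
every replicate touching it.

Regions whose centre lies within ``promoter_dist`` (default 2 kb, strict <)
of the nearest TSS on the same chromosome are promoters; all others are
enhancers.  Promoters are annotated to the gene whose TSS is nearest to the
region centre; enhancers carry target-gene candidates from fixed linear
windows (100/200/400 kb by default) around their boundaries.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, Peak, TSSRecord, merge_intervals

__all__ = [
    "ConsensusRegion",
    "RegulatoryRegion",
    "consensus_regions",
    "classify_regions",
    "annotate_promoter",
    "assign_window_genes",
    "TSSIndex",
]

PROMOTER = "promoter"
ENHANCER = "enhancer"


@dataclass(frozen=True)
class ConsensusRegion:
    """Merged replicate-supported H3K27ac span for one condition."""

    interval: GenomicInterval
    condition: str
    support: int          # distinct replicates with >=1 peak in the component
    net_signal: float     # sum of contributing peaks' input-subtracted signal

    @property
    def region_id(self) -> str:
        return f"{self.condition}:{self.interval.chrom}:{self.interval.start}-{self.interval.end}"


@dataclass
class RegulatoryRegion:
    """A consensus region classified as promoter or enhancer."""

    region: ConsensusRegion
    klass: str                                   # "promoter" | "enhancer"
    tss_distance: int | None = None              # centre-to-nearest-TSS, bp
    anchor_gene: str | None = None               # promoters only
    window_genes: dict[int, list[str]] = field(default_factory=dict)  # kb -> genes
    no_tss_chrom: bool = False                   # flagged: no TSS on chromosome

    @property
    def interval(self) -> GenomicInterval:
        return self.region.interval

    @property
    def region_id(self) -> str:
        return self.region.region_id


class TSSIndex:
    """Per-chromosome sorted TSS positions for nearest/window queries."""

    def __init__(self, tss: list[TSSRecord]):
        by_chrom: dict[str, list[TSSRecord]] = defaultdict(list)
        for rec in tss:
            by_chrom[rec.chrom].append(rec)
        self.positions: dict[str, np.ndarray] = {}
        self.genes: dict[str, np.ndarray] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r.tss, r.gene_id))
            self.positions[chrom] = np.array([r.tss for r in recs], dtype=np.int64)
            self.genes[chrom] = np.array([r.gene_id for r in recs], dtype=object)

    def nearest(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """(gene_id, distance) of the nearest TSS; lexicographic tie-break."""
        if chrom not in self.positions:
            return None
        dist = np.abs(self.positions[chrom] - pos)
        dmin = int(dist.min())
        candidates = self.genes[chrom][dist == dmin]
        return min(candidates), dmin

    def in_window(self, chrom: str, lo: int, hi: int) -> list[tuple[str, int]]:
        """(gene_id, tss) pairs with TSS in [lo, hi), sorted by position."""
        if chrom not in self.positions:
            return []
        pos = self.positions[chrom]
        i = int(np.searchsorted(pos, lo, side="left"))
        j = int(np.searchsorted(pos, hi, side="left"))
        return [(str(g), int(p)) for g, p in zip(self.genes[chrom][i:j], pos[i:j])]


def consensus_regions(
    peaks: list[Peak], condition: str, min_replicates: int = 2
) -> list[ConsensusRegion]:
    """Build replicate-consensus regions for one condition.

    Intervals are the connected components of the union of all replicate peaks
    (gap 0).  Components supported by fewer than ``min_replicates`` distinct
    replicates are discarded; ``net_signal`` sums the contributing peaks'
    input-subtracted signals.
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    bad = {p.condition for p in peaks} - {condition}
    if bad:
        raise ValueError(f"peaks from unexpected conditions {sorted(bad)}")
    if not peaks:
        return []
    merged = merge_intervals([p.interval for p in peaks], gap=0)
    # Each peak lies wholly inside exactly one merged component; locate by start.
    starts_by_chrom: dict[str, list[int]] = defaultdict(list)
    comp_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in merged:
        starts_by_chrom[iv.chrom].append(iv.start)
        comp_by_chrom[iv.chrom].append(iv)
    support: dict[GenomicInterval, set[str]] = defaultdict(set)
    signal: dict[GenomicInterval, float] = defaultdict(float)
    for p in peaks:
        starts = starts_by_chrom[p.interval.chrom]
        idx = bisect.bisect_right(starts, p.interval.start) - 1
        comp = comp_by_chrom[p.interval.chrom][idx]
        assert comp.contains(p.interval)
        support[comp].add(p.replicate_id)
        signal[comp] += p.net_signal
    out = [
        ConsensusRegion(iv, condition, len(support[iv]), signal[iv])
        for iv in merged
        if len(support[iv]) >= min_replicates
    ]
    return out


def annotate_promoter(
    region: ConsensusRegion | GenomicInterval, tss: list[TSSRecord] | TSSIndex
) -> str:
    """Gene whose TSS is nearest to the region centre (lexicographic tie-break)."""
    index = tss if isinstance(tss, TSSIndex) else TSSIndex(tss)
    iv = region if isinstance(region, GenomicInterval) else region.interval
    hit = index.nearest(iv.chrom, iv.center)
    if hit is None:
        raise ValueError(f"no TSS on chromosome {iv.chrom}")
    return hit[0]


def classify_regions(
    regions: list[ConsensusRegion],
    tss: list[TSSRecord] | TSSIndex,
    promoter_dist: int = 2000,
) -> list[RegulatoryRegion]:
    """Split consensus regions into promoters (< promoter_dist of a TSS) and enhancers.

    Distance is |centre - nearest TSS| on the same chromosome, with the centre
    at floor((start+end)/2).  The inequality is strict, so a region at exactly
    ``promoter_dist`` is an enhancer.  Regions on chromosomes with no TSS are
    enhancers, flagged via ``no_tss_chrom``.
    """
    index = tss if isinstance(tss, TSSIndex) else TSSIndex(tss)
    out: list[RegulatoryRegion] = []
    for reg in regions:
        hit = index.nearest(reg.interval.chrom, reg.interval.center)
        if hit is None:
            out.append(RegulatoryRegion(reg, ENHANCER, no_tss_chrom=True))
            continue
        gene, d = hit
        if d < promoter_dist:
            out.append(RegulatoryRegion(reg, PROMOTER, tss_distance=d, anchor_gene=gene))
        else:
            out.append(RegulatoryRegion(reg, ENHANCER, tss_distance=d))
    return out


def assign_window_genes(
    region: RegulatoryRegion | GenomicInterval,
    tss: list[TSSRecord] | TSSIndex,
    window_kb: int,
) -> list[str]:
    """Genes with a TSS within ``window_kb`` kilobases of the region boundaries.

    The window is ``[start - w, end + w)`` with w = window_kb * 1000 (closed
    lower bound, open upper bound, mirroring half-open intervals).  Genes are
    returned sorted by distance to the nearest region boundary (0 inside the
    region), then gene id; duplicated gene ids keep the nearest TSS.
    """
    index = tss if isinstance(tss, TSSIndex) else TSSIndex(tss)
    iv = region if isinstance(region, GenomicInterval) else region.interval
    w = window_kb * 1000
    hits = index.in_window(iv.chrom, iv.start - w, iv.end + w)
    best: dict[str, int] = {}
    for gene, pos in hits:
        if pos < iv.start:
            d = iv.start - pos
        elif pos >= iv.end:
            d = pos - iv.end + 1
        else:
            d = 0
        if gene not in best or d < best[gene]:
            best[gene] = d
    return [g for g, _ in sorted(best.items(), key=lambda kv: (kv[1], kv[0]))]
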