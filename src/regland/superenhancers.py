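"""Super-enhancer calling: promoter-proximal exclusion, stitching, rank-signal cutoff.

Enhancers wholly contained in a +/-2,500 bp window around any annotated TSS
(a total 5,000 bp promoter exclusion zone) are removed, the remainder are
stitched when separated by at most 12,500 bp, and stitched clusters are
ranked by aggregate input-subtracted signal.  Ranks and signals are scaled to
[0, 1]; the super-enhancer cutoff is the point where a line of slope 1 is
tangent to the convex rank-signal curve from below, i.e. the rank index
minimising (scaled_signal - scaled_rank).  Clusters with signal strictly
above the cutoff signal are super-enhancers, so they occupy the top ranks
contiguously and the call is invariant to rescaling all signals by c > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, TSSRecord
from .regions import RegulatoryRegion, TSSIndex

log = logging.getLogger(__name__)

__all__ = [
    "StitchedEnhancer",
    "SECall",
    "exclude_promoter_proximal",
    "stitch_enhancers",
    "call_superenhancers",
    "se_cutoff_index",
]


@dataclass(frozen=True)
class StitchedEnhancer:
    """A cluster of stitched enhancers with summed input-subtracted signal."""

    interval: GenomicInterval
    constituents: tuple[str, ...]
    net_signal: float

    @property
    def region_id(self) -> str:
        return f"SE:{self.interval.chrom}:{self.interval.start}-{self.interval.end}"


@dataclass(frozen=True)
class SECall:
    stitched: StitchedEnhancer
    rank: int              # 1-based, ascending signal
    scaled_rank: float     # rank / N
    scaled_signal: float   # (signal - min) / (max - min)
    is_super: bool
    cutoff_signal: float

    @property
    def interval(self) -> GenomicInterval:
        return self.stitched.interval

    @property
    def region_id(self) -> str:
        return self.stitched.region_id

    @property
    def net_signal(self) -> float:
        return self.stitched.net_signal


def _as_region(e) -> tuple[str, GenomicInterval, float]:
    signal = e.region.net_signal if isinstance(e, RegulatoryRegion) else e.net_signal
    return e.region_id, e.interval, signal


def exclude_promoter_proximal(
    enhancers: list,
    tss: list[TSSRecord] | TSSIndex,
    half_window: int = 2500,
) -> list:
    """Drop enhancers wholly contained in [tss - half_window, tss + half_window).

    Partial overlap with the exclusion zone is not grounds for removal; the
    enhancer must be contained entirely within the window of a single TSS.
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    index = tss if isinstance(tss, TSSIndex) else TSSIndex(tss)
    kept = []
    for e in enhancers:
        _, iv, _ = _as_region(e)
        # Containment requires a TSS with tss - hw <= start and end <= tss + hw.
        hits = index.in_window(iv.chrom, iv.end - half_window, iv.start + half_window + 1)
        if not any(t - half_window <= iv.start and iv.end <= t + half_window for _, t in hits):
            kept.append(e)
    return kept


def stitch_enhancers(enhancers: list, distance: int = 12500) -> list[StitchedEnhancer]:
    """Merge enhancers separated by at most ``distance`` bp into clusters.

    The boundary is inclusive: a gap of exactly ``distance`` stitches.  The
    result is independent of input order and idempotent; each cluster spans
    min(start)..max(end) of its constituents and sums their signals.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    items = sorted(
        (_as_region(e) for e in enhancers),
        key=lambda t: (t[1].chrom, t[1].start, t[1].end),
    )
    out: list[StitchedEnhancer] = []
    cur: list[tuple[str, GenomicInterval, float]] = []

    def flush() -> None:
        if not cur:
            return
        iv = GenomicInterval(
            cur[0][1].chrom, min(t[1].start for t in cur), max(t[1].end for t in cur)
        )
        out.append(
            StitchedEnhancer(iv, tuple(t[0] for t in cur), sum(t[2] for t in cur))
        )

    end = None
    for item in items:
        iv = item[1]
        if cur and iv.chrom == cur[0][1].chrom and iv.start - end <= distance:
            cur.append(item)
            end = max(end, iv.end)
        else:
            flush()
            cur, end = [item], iv.end
    flush()
    return out


def se_cutoff_index(scaled_signal: np.ndarray, scaled_rank: np.ndarray) -> int:
    """Index of the slope-1 tangent point on the ascending rank-signal curve.

    For a convex curve lying below the diagonal this is the point the line
    y = x + c touches when raised from below, i.e. argmin(y - x).  The first
    such index is returned when several points attain the minimum.
    """
    return int(np.argmin(scaled_signal - scaled_rank))


def call_superenhancers(stitched: list[StitchedEnhancer]) -> list[SECall]:
    """Separate super-enhancers from typical enhancers on the ranked signal curve.

    Clusters are sorted by ascending net signal (ties broken by chrom, start
    for a stable ranking); clusters with signal strictly above the signal at
    the tangent index are super-enhancers.  With fewer than 3 clusters, or a
    flat signal profile, everything is typical.
    """
    n = len(stitched)
    if n == 0:
        return []
    ordered = sorted(
        stitched, key=lambda s: (s.net_signal, s.interval.chrom, s.interval.start)
    )
    signals = np.array([s.net_signal for s in ordered], dtype=float)
    smin, smax = signals[0], signals[-1]
    if n < 3 or smax == smin:
        if n < 3:
            log.warning("only %d stitched enhancers; all called typical", n)
        return [
            SECall(s, i + 1, (i + 1) / n, 0.0, False, float(smax))
            for i, s in enumerate(ordered)
        ]
    scaled_signal = (signals - smin) / (smax - smin)
    scaled_rank = np.arange(1, n + 1) / n
    cut = se_cutoff_index(scaled_signal, scaled_rank)
    cutoff_signal = float(signals[cut])
    return [
        SECall(
            s,
            i + 1,
            float(scaled_rank[i]),
            float(scaled_signal[i]),
            bool(signals[i] > cutoff_signal),
            cutoff_signal,
        )
        for i, s in enumerate(ordered)
    ]


def plot_hockey_stick(calls: list[SECall], path: str) -> None:
    """Rank-vs-signal plot with the super-enhancer cutoff marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranks = [c.rank for c in calls]
    signals = [c.net_signal for c in calls]
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = ["#d62728" if c.is_super else "#7f7f7f" for c in calls]
    ax.scatter(ranks, signals, s=12, c=colors)
    if calls:
        ax.axhline(calls[0].cutoff_signal, ls="--", lw=0.8, color="k")
    ax.set_xlabel("enhancer rank (ascending signal)")
    ax.set_ylabel("input-subtracted H3K27ac signal")
    n_se = sum(c.is_super for c in calls)
    ax.set_title(f"{n_se} super-enhancers / {len(calls)} stitched")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
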