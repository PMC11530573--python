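"""Cell-specificity of regulatory regions by reciprocal overlap.

When two conditions are compared, a region is *shared* if some region of the
other condition overlaps it by at least ``min_fraction`` (default 0.3) of
BOTH interval lengths — the reciprocal reading, equivalent to bedtools
``-f 0.3 -r``.  Regions with no such partner are specific to their own
condition.  When a region overlaps several partners, per-partner fractions
are evaluated pairwise and the best pair decides (an aggregate mode summing
overlaps over all partners is available but off by default).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .intervals import GenomicInterval, overlap_length

__all__ = ["SpecificityLabel", "reciprocal_overlap", "call_specificity",
           "SHARED", "SPECIFIC_A", "SPECIFIC_B"]

SHARED = "shared"
SPECIFIC_A = "specific_A"
SPECIFIC_B = "specific_B"


@dataclass(frozen=True)
class SpecificityLabel:
    region_id: str
    comparison: tuple[str, str]
    label: str                      # shared | specific_A | specific_B
    partner_id: str | None = None   # set iff shared
    frac_self: float = 0.0          # overlap / own length for the deciding pair
    frac_partner: float = 0.0
    side: int = 0                   # 0: region from the first set, 1: second

    @property
    def is_shared(self) -> bool:
        return self.label == SHARED

    @property
    def condition(self) -> str:
        return self.comparison[self.side]


def reciprocal_overlap(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[float, float]:
    """Overlap expressed as a fraction of each interval: (ov/len(a), ov/len(b))."""
    ov = overlap_length(a, b)
    return ov / a.length, ov / b.length


def _coerce(regions: Sequence) -> list[tuple[str, GenomicInterval]]:
    out = []
    for r in regions:
        if isinstance(r, GenomicInterval):
            out.append((str(r), r))
        else:
            out.append((r.region_id, r.interval))
    return out


def _check_disjoint(items: list[tuple[str, GenomicInterval]], name: str) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for _, iv in items:
        by_chrom[iv.chrom].append(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda i: i.start)
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping regions within set {name} on {chrom}: {prev} / {cur}"
                )


def call_specificity(
    regions_a: Sequence,
    regions_b: Sequence,
    comparison: tuple[str, str] = ("A", "B"),
    min_fraction: float = 0.3,
    reciprocal_mode: str = "both",
    aggregate: bool = False,
) -> list[SpecificityLabel]:
    """Label every region of both sets as shared or condition-specific.

    Parameters
    ----------
    regions_a, regions_b
        Internally disjoint region sets (objects with ``region_id`` and
        ``interval`` attributes, or bare :class:`GenomicInterval`).
    min_fraction
        Overlap fraction threshold in (0, 1]; ``>=`` makes a pair shared.
    reciprocal_mode
        ``"both"`` requires the threshold in both directions (default);
        ``"any"`` accepts either direction.
    aggregate
        Evaluate fractions against the summed overlap over all partners
        instead of the best single pair.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if reciprocal_mode not in ("both", "any"):
        raise ValueError(f"unknown reciprocal_mode {reciprocal_mode!r}")
    items_a = _coerce(regions_a)
    items_b = _coerce(regions_b)
    _check_disjoint(items_a, comparison[0])
    _check_disjoint(items_b, comparison[1])

    labels = []
    labels.extend(
        _label_one_side(items_a, items_b, comparison, SPECIFIC_A,
                        min_fraction, reciprocal_mode, aggregate, side=0)
    )
    labels.extend(
        _label_one_side(items_b, items_a, comparison, SPECIFIC_B,
                        min_fraction, reciprocal_mode, aggregate, side=1)
    )
    return labels


def _label_one_side(
    items: list[tuple[str, GenomicInterval]],
    others: list[tuple[str, GenomicInterval]],
    comparison: tuple[str, str],
    specific_label: str,
    min_fraction: float,
    reciprocal_mode: str,
    aggregate: bool,
    side: int,
) -> list[SpecificityLabel]:
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = defaultdict(list)
    for rid, iv in others:
        by_chrom[iv.chrom].append((rid, iv))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[1].start)

    decide = min if reciprocal_mode == "both" else max
    out: list[SpecificityLabel] = []
    for rid, iv in items:
        partners = [
            (oid, oiv)
            for oid, oiv in by_chrom.get(iv.chrom, [])
            if overlap_length(iv, oiv) > 0
        ]
        best: tuple[float, float, str] | None = None  # (score, frac_self, pid)
        best_fp = 0.0
        if aggregate and partners:
            total = sum(overlap_length(iv, oiv) for _, oiv in partners)
            union_len = sum(oiv.length for _, oiv in partners)
            fs, fp = total / iv.length, total / union_len
            oid = max(partners, key=lambda t: overlap_length(iv, t[1]))[0]
            best, best_fp = (decide(fs, fp), fs, oid), fp
        else:
            for oid, oiv in partners:
                fs, fp = reciprocal_overlap(iv, oiv)
                score = decide(fs, fp)
                if best is None or score > best[0]:
                    best, best_fp = (score, fs, oid), fp
        if best is not None and best[0] >= min_fraction:
            out.append(
                SpecificityLabel(rid, comparison, SHARED, best[2], best[1], best_fp,
                                 side=side)
            )
        else:
            fs = best[1] if best else 0.0
            out.append(
                SpecificityLabel(rid, comparison, specific_label, None, fs,
                                 best_fp if best else 0.0, side=side)
            )
    return out
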