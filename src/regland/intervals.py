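"""Genomic-interval data model, interval arithmetic, and flat-file readers/writers.

Coordinates are 0-based, half-open (BED convention) everywhere: an interval
``[start, end)`` covers ``end - start`` bases and abutting intervals do not
overlap.  Any 1-based dialect (e.g. GTF) is converted at the reader boundary.
Chromosome names are compared by exact string match; no "chr" normalisation is
performed unless an explicit alias map is supplied to a reader.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Peak",
    "TSSRecord",
    "PeakFileError",
    "overlap_length",
    "merge_intervals",
    "read_peaks",
    "write_peaks",
    "read_tss",
    "write_tss",
    "read_tss_from_gtf",
]


class PeakFileError(ValueError):
    """Raised for malformed peak/TSS files; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak with IP and matched-input (control) read-density scores."""

    interval: GenomicInterval
    ip_signal: float
    input_signal: float
    replicate_id: str = "rep1"
    condition: str = ""

    def __post_init__(self) -> None:
        if self.ip_signal < 0 or self.input_signal < 0:
            raise ValueError(
                f"negative signal on {self.interval}: "
                f"ip={self.ip_signal}, input={self.input_signal}"
            )

    @property
    def net_signal(self) -> float:
        """Input-subtracted signal, floored at zero.

        Densities below the matched-control level carry no enhancer evidence,
        so negatives are clamped rather than propagated.
        """
        return max(self.ip_signal - self.input_signal, 0.0)


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site; the reference point for promoter calls."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS position for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two half-open intervals (0 if different chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose separation is at most ``gap`` bases.

    Separation between sorted non-overlapping intervals is ``start2 - end1``;
    "within distance d" means ``start2 - end1 <= d``, matching BED/ROSE
    stitching semantics.  With ``gap=0`` overlapping and abutting intervals
    merge.  The result is sorted, pairwise separated by more than ``gap`` on
    each chromosome, independent of input order, and idempotent.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# File I/O.  Peak files are BED5+ TSV: chrom, start, end, ip_signal,
# input_signal [, replicate_id].  TSS annotation is TSV: gene_id, chrom, tss,
# strand.  Lines starting with '#' or 'track', and a literal header line, are
# skipped.


def _apply_alias(chrom: str, aliases: Mapping[str, str] | None) -> str:
    if aliases is None:
        return chrom
    return aliases.get(chrom, chrom)


def read_peaks(
    path: str | Path,
    condition: str,
    *,
    default_replicate: str = "rep1",
    chrom_aliases: Mapping[str, str] | None = None,
) -> list[Peak]:
    """Read a BED5+ peak file into :class:`Peak` records for one condition.

    Malformed lines raise :class:`PeakFileError` naming the offending line
    number.  An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peaks: list[Peak] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#") or row[0].startswith("track"):
                continue
            if lineno == 1 and row[0].strip().lower() in ("chrom", "chr", "seqnames"):
                continue
            if len(row) < 5:
                raise PeakFileError(
                    f"{path}:{lineno}: expected >=5 tab-separated columns, got {len(row)}"
                )
            try:
                start, end = int(row[1]), int(row[2])
                ip, inp = float(row[3]), float(row[4])
            except ValueError as exc:
                raise PeakFileError(f"{path}:{lineno}: {exc}") from None
            rep = row[5].strip() if len(row) > 5 and row[5].strip() else default_replicate
            try:
                peaks.append(
                    Peak(
                        GenomicInterval(_apply_alias(row[0], chrom_aliases), start, end),
                        ip,
                        inp,
                        replicate_id=rep,
                        condition=condition,
                    )
                )
            except ValueError as exc:
                raise PeakFileError(f"{path}:{lineno}: {exc}") from None
    if not peaks:
        log.warning("no peaks read from %s", path)
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_peaks(path: str | Path, peaks: Sequence[Peak]) -> None:
    """Write peaks as BED5+ TSV (chrom, start, end, ip, input, replicate_id)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for p in peaks:
            w.writerow(
                [
                    p.interval.chrom,
                    p.interval.start,
                    p.interval.end,
                    repr(float(p.ip_signal)),
                    repr(float(p.input_signal)),
                    p.replicate_id,
                ]
            )


def read_tss(
    path: str | Path, *, chrom_aliases: Mapping[str, str] | None = None
) -> list[TSSRecord]:
    """Read a TSS annotation TSV (gene_id, chrom, tss, strand)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[TSSRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() in ("gene_id", "gene", "id"):
                continue
            if len(row) < 3:
                raise PeakFileError(f"{path}:{lineno}: expected >=3 columns")
            try:
                records.append(
                    TSSRecord(
                        row[0],
                        _apply_alias(row[1], chrom_aliases),
                        int(row[2]),
                        row[3] if len(row) > 3 else "+",
                    )
                )
            except ValueError as exc:
                raise PeakFileError(f"{path}:{lineno}: {exc}") from None
    records.sort(key=lambda r: (r.chrom, r.tss, r.gene_id))
    return records


def write_tss(path: str | Path, records: Sequence[TSSRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "chrom", "tss", "strand"])
        for r in records:
            w.writerow([r.gene_id, r.chrom, r.tss, r.strand])


def read_tss_from_gtf(
    path: str | Path,
    *,
    feature: str = "gene",
    chrom_aliases: Mapping[str, str] | None = None,
) -> list[TSSRecord]:
    """Derive TSS records from GTF-style lines.

    GTF is 1-based, closed.  The TSS is the 5' end of the feature: ``start-1``
    (0-based) on the + strand, ``end-1`` on the - strand.  ``gene_id`` is taken
    from the attribute column.
    """
    path = Path(path)
    records: list[TSSRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise PeakFileError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != feature:
                continue
            attrs = fields[8]
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise PeakFileError(f"{path}:{lineno}: no gene_id attribute")
            strand = fields[6]
            start1, end1 = int(fields[3]), int(fields[4])
            tss = start1 - 1 if strand == "+" else end1 - 1
            key = f"{gene_id}@{tss}"
            if key in seen:
                continue
            seen.add(key)
            records.append(
                TSSRecord(gene_id, _apply_alias(fields[0], chrom_aliases), tss, strand)
            )
    records.sort(key=lambda r: (r.chrom, r.tss, r.gene_id))
    return records
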