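"""Independent brute-force oracles used by the test-suite.

Deliberately naive implementations (pairwise union-find, all-pairs scans,
exhaustive enumeration) kept free of any code path they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_consensus(peaks, min_replicates):
    """Union components by pairwise overlap/abutment; (chrom, start, end, support, signal)."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i].interval, peaks[j].interval
            if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    out = []
    for members in groups.values():
        support = len({p.replicate_id for p in members})
        if support < min_replicates:
            continue
        out.append((
            members[0].interval.chrom,
            min(p.interval.start for p in members),
            max(p.interval.end for p in members),
            support,
            sum(max(p.ip_signal - p.input_signal, 0.0) for p in members),
        ))
    out.sort()
    return out


def brute_nearest_tss(tss_records, chrom, pos):
    """(gene_id, distance) by linear scan; lexicographic tie-break; None if no TSS."""
    best = None
    for rec in tss_records:
        if rec.chrom != chrom:
            continue
        d = abs(rec.tss - pos)
        if best is None or d < best[1] or (d == best[1] and rec.gene_id < best[0]):
            best = (rec.gene_id, d)
    return best


def brute_specificity(intervals_a, intervals_b, min_fraction):
    """All-pairs shared/specific labels: (labels_a, labels_b) as lists of bool(shared)."""

    def shared(iv, others):
        for other in others:
            if iv.chrom != other.chrom:
                continue
            ov = max(0, min(iv.end, other.end) - max(iv.start, other.start))
            if ov / iv.length >= min_fraction and ov / other.length >= min_fraction:
                return True
        return False

    return (
        [shared(iv, intervals_b) for iv in intervals_a],
        [shared(iv, intervals_a) for iv in intervals_b],
    )


def brute_bh(pvalues):
    """Step-up BH by explicit loop (sort, scale, monotonise, cap, unsort)."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    scaled = [pvalues[indexed[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for i, idx in enumerate(indexed):
        out[idx] = min(scaled[i], 1.0)
    return out


def tangent_cutoff_index(signals):
    """Slope-1 tangent point of the scaled ascending rank-signal curve.

    For each candidate point, raise a unit-slope line through it and count
    points strictly below; the tangent from below is the (first) line with
    none.  Exhaustive over all candidates.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    y = (s - s[0]) / (s[-1] - s[0])
    x = np.arange(1, n + 1) / n
    eps = 1e-12
    best = None
    for i in range(n):
        c = y[i] - x[i]
        below = np.sum(y < x + c - eps)
        if below == 0 and best is None:
            best = i
    assert best is not None
    return best


def rank_sum_exact_p(x, y, alternative="greater"):
    """Exact one-sided rank-sum p by enumerating all group assignments.

    Assumes no ties across the pooled sample.  Probability, under random
    assignment of the pooled values to groups of the observed sizes, of a
    group-1 rank sum at least (``greater``) / at most (``less``) as extreme
    as observed.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n1 = len(x)
    count = total = 0
    for combo in itertools.combinations(pooled, n1):
        stat = sum(ranks[v] for v in combo)
        total += 1
        if alternative == "greater" and stat >= obs:
            count += 1
        elif alternative == "less" and stat <= obs:
            count += 1
    return count / total
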