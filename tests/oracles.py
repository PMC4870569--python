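"""Independent brute-force oracles used only by the test suite.

Every function here re-derives a pipeline quantity from first principles
(per-base boolean arrays, all-pairs scans, exhaustive enumeration) without
touching the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def coverage_oracle(intervals):
    """Per-base coverage set of a list of (start, end) pairs."""
    covered = set()
    for start, end in intervals:
        covered.update(range(start, end))
    return covered


def classify_oracle(lnc, coding_genes, bidirectional_tss_window):
    """Positional class of a lncRNA by enumerating every coding gene.

    Definitions: antisense = opposite-strand span overlap; intronic =
    entirely inside a single intron of a same-strand coding gene;
    bidirectional = no overlap, opposite strands, divergent orientation,
    TSS distance <= window; else intergenic.  Precedence: antisense >
    intronic > bidirectional.
    """
    span = lnc.span
    for g in coding_genes:
        gspan = g.span
        if gspan.chrom != span.chrom:
            continue
        if gspan.start < span.end and span.start < gspan.end and g.strand != lnc.strand:
            return "antisense"
    for g in coding_genes:
        if g.chrom != span.chrom or g.strand != lnc.strand:
            continue
        blocks = g.merged_exons
        for a, b in zip(blocks, blocks[1:]):
            if a.end <= span.start and span.end <= b.start:
                return "intronic"
    for g in coding_genes:
        gspan = g.span
        if gspan.chrom != span.chrom or g.strand == lnc.strand:
            continue
        if gspan.start < span.end and span.start < gspan.end:
            continue  # overlap: not bidirectional
        if lnc.strand == "-":
            d = g.tss - lnc.tss
        else:
            d = lnc.tss - g.tss
        if 0 <= d <= bidirectional_tss_window:
            return "bidirectional"
    return "intergenic"


def neighbors_oracle(lnc, coding_genes, window):
    """All-pairs scan: coding genes with edge-to-edge gap <= window."""
    span = lnc.span
    hits = []
    for g in coding_genes:
        gspan = g.span
        if gspan.chrom != span.chrom:
            continue
        if gspan.start < span.end and span.start < gspan.end:
            gap = 0
        else:
            gap = max(span.start, gspan.start) - min(span.end, gspan.end)
        if gap <= window:
            hits.append((g.gene_id, gap))
    return sorted(hits, key=lambda t: (t[1], t[0]))


def filter_oracle(normalized, lengths, min_length, quantile, use_median):
    """Three-rule filter cascade, recomputed naively.

    ``normalized``: genes x samples array; ``lengths``: per-gene bp.
    Returns the surviving boolean mask.
    """
    mean_norm = normalized.mean(axis=1)
    keep = np.ones(len(lengths), dtype=bool)
    keep &= ~(np.asarray(lengths) < min_length)
    density = mean_norm / (np.asarray(lengths) / 100.0)
    if keep.any():
        thr = np.quantile(density[keep], quantile, method="linear")
        keep &= ~(keep & (density < thr))
    if use_median and keep.any():
        med = np.median(mean_norm[keep])
        keep &= ~(keep & (mean_norm < med))
    return keep


def hypergeom_enumeration(big_n, big_k, n, k):
    """P[X >= k] by exhaustive enumeration of all n-subsets of the
    universe; tractable for big_n <= 12."""
    universe = list(range(big_n))
    members = set(range(big_k))
    total = 0
    hits = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(members.intersection(subset)) >= k:
            hits += 1
    return hits / total


def bh_oracle(pvalues):
    """Step-up BH by the textbook definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def ward_oracle(points):
    """Exhaustive-search Ward: at each step evaluate every cluster pair's
    increase in within-cluster sum of squares and merge the cheapest.

    Returns a list of (merged_leaf_set_a, merged_leaf_set_b, height) with
    height = sqrt(2 * delta_ESS), the scale scipy reports.
    """
    points = np.asarray(points, dtype=float)
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pa = points[clusters[a]]
            pb = points[clusters[b]]
            ca, cb = pa.mean(axis=0), pb.mean(axis=0)
            na, nb = len(pa), len(pb)
            delta = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
            if best is None or delta < best[0]:
                best = (delta, a, b)
        delta, a, b = best
        merges.append(
            (frozenset(clusters[a]), frozenset(clusters[b]), math.sqrt(2 * delta))
        )
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[min(a, b)] = merged
    return merges
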