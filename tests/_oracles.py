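"""Independent brute-force oracles used to validate the interval engine.

These deliberately avoid the package's sweep-based implementations: every
computation is a pairwise O(n*m) scan over raw (chrom, start, end) tuples,
vectorised with numpy broadcasting only for speed.
"""

from __future__ import annotations

import numpy as np


def _by_chrom(raw):
    out = {}
    for chrom, s, e in raw:
        out.setdefault(chrom, []).append((s, e))
    return out


def _merge_sorted(pairs):
    """Plain sorted-scan union of (start, end) pairs."""
    merged = []
    for s, e in sorted(pairs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def bf_intersect(a_raw, b_raw):
    """All pairwise overlaps of a x b, merged; list of (chrom, start, end)."""
    out = []
    bb = _by_chrom(b_raw)
    for chrom, pairs_a in _by_chrom(a_raw).items():
        if chrom not in bb:
            continue
        sa = np.array([p[0] for p in pairs_a])[:, None]
        ea = np.array([p[1] for p in pairs_a])[:, None]
        sb = np.array([p[0] for p in bb[chrom]])[None, :]
        eb = np.array([p[1] for p in bb[chrom]])[None, :]
        lo = np.maximum(sa, sb)
        hi = np.minimum(ea, eb)
        ii, jj = np.nonzero(hi > lo)
        pieces = [(int(lo[i, j]), int(hi[i, j])) for i, j in zip(ii, jj)]
        out.extend((chrom, s, e) for s, e in _merge_sorted(pieces))
    return sorted(out)


def bf_covered_bp(chrom, start, end, subject_raw):
    """Bases of [start, end) covered by any subject interval (pairwise clip)."""
    pieces = [
        (max(start, s), min(end, e))
        for c, s, e in subject_raw
        if c == chrom and min(end, e) > max(start, s)
    ]
    return sum(e - s for s, e in _merge_sorted(pieces))


def bf_overlap_fraction(query_raw, subject_raw, min_bp=1):
    if not query_raw:
        return 0.0
    hits = sum(
        1
        for c, s, e in query_raw
        if bf_covered_bp(c, s, e, subject_raw) >= min_bp
    )
    return hits / len(query_raw)


def bf_consensus(peaksets_raw, min_overlap):
    """Union-merge all samples' peaks, count per-region supporting samples."""
    union = []
    for raw in peaksets_raw:
        union.extend(raw)
    regions = []
    for chrom, pairs in _by_chrom(union).items():
        regions.extend((chrom, s, e) for s, e in _merge_sorted(pairs))
    out = []
    for chrom, s, e in sorted(regions):
        support = sum(
            1
            for raw in peaksets_raw
            if any(c == chrom and min(e, pe) > max(s, ps) for c, ps, pe in raw)
        )
        if support >= min_overlap:
            out.append((chrom, s, e, support))
    return out


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=2_000):
    raw = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        raw.append((chrom, s, s + length))
    return raw
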