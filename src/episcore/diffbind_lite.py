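"""Consensus peaks, count matrices and differential binding between groups.

A transparent re-implementation of the standard differential-ChIP contrast:
merge all samples' peaks, keep regions supported by at least ``min_overlap``
samples, count coverage per region, normalise to log2 counts-per-million
(pseudo-count 0.5), and test each region between two phenotype groups with a
moderated Welch t (per-group variances floored at a low quantile of all
per-region variances, guarding against spuriously tiny denominators while
keeping null p-values uniform), BH-corrected.  Scale-invariant by
construction: the CPM normalisation absorbs common library-size factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .errors import ArgumentError, DataError
from .intervals import Coverage, GenomicInterval, IntervalSet
from .survival import bh_adjust

__all__ = [
    "ConsensusPeaks",
    "consensus_peaks",
    "occupancy_matrix",
    "count_matrix",
    "sample_correlation",
    "differential_regions",
    "promoter_subset",
]


@dataclass
class ConsensusPeaks:
    """Merged regions supported by >= ``min_overlap`` distinct samples."""

    regions: list[GenomicInterval]
    support: np.ndarray
    min_overlap: int
    samples: list[str]

    def region_ids(self) -> list[str]:
        return [f"{r.chrom}:{r.start}-{r.end}" for r in self.regions]


def consensus_peaks(
    peaksets: Sequence[IntervalSet], min_overlap: int = 2
) -> ConsensusPeaks:
    """Merge the union of all peaksets; keep regions with enough sample support."""
    if len(peaksets) < 2:
        raise ArgumentError("consensus_peaks: need >= 2 peaksets")
    if min_overlap > len(peaksets):
        raise ArgumentError(
            f"min_overlap {min_overlap} exceeds number of samples {len(peaksets)}"
        )
    union = IntervalSet(
        [iv for ps in peaksets for iv in ps], sample="union"
    ).merge()
    regions, support = [], []
    for region in union:
        n = sum(
            1
            for ps in peaksets
            if ps.overlap_bp(region.chrom, region.start, region.end) > 0
        )
        if n >= min_overlap:
            regions.append(region)
            support.append(n)
    return ConsensusPeaks(
        regions,
        np.asarray(support, dtype=int),
        min_overlap,
        [ps.sample or f"sample{i}" for i, ps in enumerate(peaksets)],
    )


def occupancy_matrix(
    consensus: ConsensusPeaks, peaksets: Sequence[IntervalSet]
) -> pd.DataFrame:
    """Region x sample 0/1 matrix: does the sample call a peak in the region."""
    data = {
        ps.sample
        or f"sample{i}": [
            int(ps.overlap_bp(r.chrom, r.start, r.end) > 0) for r in consensus.regions
        ]
        for i, ps in enumerate(peaksets)
    }
    return pd.DataFrame(data, index=consensus.region_ids())


def count_matrix(
    consensus: ConsensusPeaks, coverages: Mapping[str, Coverage]
) -> tuple[pd.DataFrame, pd.Series]:
    """Summed coverage per region per sample, plus per-sample library sizes."""
    counts = {}
    libsizes = {}
    for sample, cov in coverages.items():
        vals = [
            cov.region_sum(r.chrom, r.start, r.end) for r in consensus.regions
        ]
        counts[sample] = np.rint(vals).astype(int)
        libsizes[sample] = cov.total()
    df = pd.DataFrame(counts, index=consensus.region_ids())
    return df, pd.Series(libsizes, name="library_size")


def sample_correlation(
    data: pd.DataFrame, method: str = "occupancy"
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between sample columns plus a dendrogram leaf order.

    ``method="occupancy"`` uses the 0/1 matrix as-is; ``method="affinity"``
    correlates log2(count + 1).  Clustering is average linkage on 1 - r.
    Constant columns get correlation 0 (with a warning), diagonal stays 1.
    """
    if data.shape[1] < 2:
        raise ArgumentError("sample_correlation: need >= 2 samples")
    if method == "affinity":
        mat = np.log2(data.to_numpy(dtype=float) + 1.0)
    elif method == "occupancy":
        mat = (data.to_numpy(dtype=float) > 0).astype(float)
    else:
        raise ArgumentError(f"unknown method {method!r}")
    sd = mat.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"sample_correlation: {int(constant.sum())} constant sample(s); "
            "their correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat, rowvar=False)
    r[np.isnan(r)] = 0.0
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=data.columns, columns=data.columns)
    dist = squareform(np.clip(1.0 - r, 0.0, 2.0), checks=False)
    order = leaves_list(average(dist))
    return corr, [data.columns[i] for i in order]


def logcpm(counts: pd.DataFrame, libsizes: pd.Series | None = None) -> pd.DataFrame:
    """log2 counts-per-million with pseudo-count 0.5."""
    c = counts.to_numpy(dtype=float)
    if np.any(c < 0):
        raise DataError("negative counts")
    lib = (
        libsizes.reindex(counts.columns).to_numpy(dtype=float)
        if libsizes is not None
        else c.sum(axis=0)
    )
    vals = np.log2((c + 0.5) / (lib + 1.0) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def differential_regions(
    counts: pd.DataFrame,
    groups: Sequence,
    fdr_threshold: float = 0.05,
    libsizes: pd.Series | None = None,
    floor_quantile: float = 0.1,
) -> pd.DataFrame:
    """Moderated Welch t on logCPM per region between two phenotype groups.

    Group labels align with the count columns; the two sorted unique labels
    define group A (first) and group B (second).  ``log2_fc`` is mean(A) -
    mean(B) on the logCPM scale; ``direction`` is ``enriched_in_A`` when
    positive.  Per-group variances are floored at the ``floor_quantile``
    quantile of all per-region group variances before the Welch statistic
    (a light moderation that leaves null p-values uniform), and BH-adjusted
    p-values are thresholded at ``fdr_threshold``.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ArgumentError("differential_regions: need exactly two groups")
    in_a = groups == labels[0]
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ArgumentError("differential_regions: need >= 2 samples per group")
    lc = logcpm(counts, libsizes).to_numpy()
    a, b = lc[:, in_a], lc[:, ~in_a]
    n1, n0 = a.shape[1], b.shape[1]
    m1, m0 = a.mean(axis=1), b.mean(axis=1)
    v1, v0 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    floor = float(np.quantile(np.concatenate([v1, v0]), floor_quantile))
    v1f, v0f = np.maximum(v1, floor), np.maximum(v0, floor)
    se2 = v1f / n1 + v0f / n0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se2 > 0, (m1 - m0) / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
        df = np.where(
            se2 > 0,
            se2**2
            / ((v1f / n1) ** 2 / (n1 - 1) + (v0f / n0) ** 2 / (n0 - 1)),
            1.0,
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = bh_adjust(p)
    lfc = m1 - m0
    return pd.DataFrame(
        {
            "mean_a": m1,
            "mean_b": m0,
            "log2_fc": lfc,
            "t": t,
            "p": p,
            "fdr": q,
            "direction": np.where(lfc > 0, "enriched_in_A", "enriched_in_B"),
            "significant": q <= fdr_threshold,
        },
        index=counts.index,
    )


def promoter_subset(
    diff: pd.DataFrame, promoters: Mapping[str, GenomicInterval]
) -> pd.DataFrame:
    """Restrict differential regions to those overlapping a promoter (>= 1 bp).

    Region ids must be ``chrom:start-end`` (as produced by the consensus
    builder); the result gains a ``gene_id`` column and keeps one row per
    (region, overlapping promoter).
    """
    prom_set = IntervalSet(list(promoters.values()))
    rows = []
    for region_id, row in diff.iterrows():
        chrom, _, span = str(region_id).partition(":")
        start_s, _, end_s = span.partition("-")
        start, end = int(start_s), int(end_s)
        for gene_id, prom in promoters.items():
            if prom.chrom == chrom and min(prom.end, end) - max(prom.start, start) >= 1:
                rows.append({**row.to_dict(), "region": region_id, "gene_id": gene_id})
    if not rows:
        return pd.DataFrame(
            columns=list(diff.columns) + ["region", "gene_id"]
        )
    return pd.DataFrame(rows)
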