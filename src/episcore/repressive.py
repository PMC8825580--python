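"""Bivalent repression: promoters co-occupied by H3K9me3 and H3K27me3.

Two co-marking modes are supported.  The default asks only that a promoter
overlap a peak of each mark; the strict mode additionally requires the two
marks' footprints to overlap *each other* within the promoter.  Recurrence
across samples nominates the most frequently co-repressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import ArgumentError
from .intervals import GenomicInterval, IntervalSet, intersect

__all__ = ["CoMarkedPromoter", "promoter_comark", "comark_recurrence"]


@dataclass
class CoMarkedPromoter:
    gene_id: str
    promoter: GenomicInterval
    samples_with_comark: list[str]

    @property
    def recurrence(self) -> int:
        return len(self.samples_with_comark)


def promoter_comark(
    h3k9me3: IntervalSet,
    h3k27me3: IntervalSet,
    promoters: Mapping[str, GenomicInterval],
    min_bp: int = 1,
    mode: str = "both_on_promoter",
) -> set[str]:
    """Gene ids whose promoter carries both repressive marks in one sample.

    ``mode="both_on_promoter"`` (default): the promoter overlaps >= ``min_bp``
    of an H3K9me3 peak and >= ``min_bp`` of an H3K27me3 peak.
    ``mode="marks_overlap"`` (strict): additionally the H3K9me3/H3K27me3
    intersection itself covers >= ``min_bp`` within the promoter.
    """
    if not promoters:
        raise ArgumentError("promoter_comark: empty promoter map")
    if min_bp < 1:
        raise ArgumentError("min_bp must be >= 1")
    if mode not in ("both_on_promoter", "marks_overlap"):
        raise ArgumentError(f"unknown mode {mode!r}")
    both = intersect(h3k9me3, h3k27me3) if mode == "marks_overlap" else None
    hits: set[str] = set()
    for gene_id, prom in promoters.items():
        k9 = h3k9me3.overlap_bp(prom.chrom, prom.start, prom.end)
        k27 = h3k27me3.overlap_bp(prom.chrom, prom.start, prom.end)
        if k9 < min_bp or k27 < min_bp:
            continue
        if both is not None:
            if both.overlap_bp(prom.chrom, prom.start, prom.end) < min_bp:
                continue
        hits.add(gene_id)
    return hits


def comark_recurrence(
    per_sample: Mapping[str, set[str]],
    promoters: Mapping[str, GenomicInterval] | None = None,
) -> list[CoMarkedPromoter]:
    """Tabulate co-marked genes across samples, sorted by descending recurrence.

    Ties break by gene id (ascending).  Genes co-marked in zero samples are
    absent from the output.
    """
    if not per_sample:
        raise ArgumentError("comark_recurrence: need >= 1 sample")
    samples_of: dict[str, list[str]] = {}
    for sample in sorted(per_sample):
        for gene in per_sample[sample]:
            samples_of.setdefault(gene, []).append(sample)
    entries = [
        CoMarkedPromoter(
            gene,
            (promoters or {}).get(gene, GenomicInterval("unknown", 0, 1)),
            samples,
        )
        for gene, samples in samples_of.items()
    ]
    entries.sort(key=lambda c: (-c.recurrence, c.gene_id))
    return entries


def recurrence_table(entries: list[CoMarkedPromoter]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in entries],
            "chrom": [c.promoter.chrom for c in entries],
            "start": [c.promoter.start for c in entries],
            "end": [c.promoter.end for c in entries],
            "recurrence": [c.recurrence for c in entries],
            "samples": [",".join(c.samples_with_comark) for c in entries],
        }
    )
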