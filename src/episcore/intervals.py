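"""Genomic-interval data model, BED-family I/O, peak annotation and TSS profiles.

Coordinates are 0-based half-open throughout, matching the BED dialect the
pipeline consumes; no shifting happens on read or write.  The interval engine
(normalisation, union, intersection, overlap counting) is implemented with
sorted numpy sweeps and is checked against brute-force oracles in the test
suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, BedParseError, DataError

logger = logging.getLogger(__name__)

KNOWN_MARKS = (
    "H3K4me1",
    "H3K4me3",
    "H3K9me3",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "custom",
)

#: peak feature categories in assignment priority order
FEATURE_PRIORITY = (
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional score/name."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.score is not None and self.score < 0:
            raise DataError(f"negative score {self.score} on {self.chrom}:{self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


def _normalize(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort by (chrom, start, end, name) and drop exact duplicates."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=GenomicInterval.sort_key):
        if out and iv == out[-1]:
            continue
        out.append(iv)
    return out


class IntervalSet:
    """A normalized (sorted, deduplicated) collection of intervals.

    Parameters
    ----------
    intervals :
        Any iterable of :class:`GenomicInterval`; normalised on construction.
    sample, mark :
        Provenance labels (one set per sample x histone mark in the pipeline).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        sample: str = "",
        mark: str = "custom",
    ) -> None:
        self.intervals = _normalize(intervals)
        self.sample = sample
        self.mark = mark
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return (
            f"IntervalSet(n={len(self)}, sample={self.sample!r}, mark={self.mark!r})"
        )

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends)`` of the disjoint union, cached."""
        if self._merged is None:
            merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom in self.chroms():
                ivs = [iv for iv in self.intervals if iv.chrom == chrom]
                starts: list[int] = []
                ends: list[int] = []
                for iv in ivs:  # already sorted
                    if ends and iv.start <= ends[-1]:
                        ends[-1] = max(ends[-1], iv.end)
                    else:
                        starts.append(iv.start)
                        ends.append(iv.end)
                merged[chrom] = (np.asarray(starts), np.asarray(ends))
            self._merged = merged
        return self._merged

    def merge(self) -> "IntervalSet":
        """Disjoint union of this set as a new IntervalSet."""
        ivs = [
            GenomicInterval(chrom, int(s), int(e))
            for chrom, (starts, ends) in self.merged_arrays().items()
            for s, e in zip(starts, ends)
        ]
        return IntervalSet(ivs, sample=self.sample, mark=self.mark)

    def total_bp(self) -> int:
        """Number of distinct bases covered (union length)."""
        return int(
            sum((e - s).sum() for s, e in self.merged_arrays().values())
        )

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Bases of ``[start, end)`` covered by this set's union."""
        if chrom not in self.merged_arrays():
            return 0
        starts, ends = self.merged_arrays()[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.maximum(e - s, 0).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
            }
        )


def read_bed(path: str | Path, sample: str = "", mark: str = "custom") -> IntervalSet:
    """Read a BED3/BED5/BED6 file into a normalized :class:`IntervalSet`.

    Column 5 (if present and not ``.``) is parsed as the score.  Malformed
    lines raise :class:`BedParseError` naming the 1-based line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, "
                    f"{fields[2]!r}"
                ) from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, score, name))
            except DataError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    if not intervals:
        warnings.warn(f"{path}: no intervals parsed (empty BED)", stacklevel=2)
    return IntervalSet(intervals, sample=sample, mark=mark)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED3 (or BED6 when any name/score is set)."""
    rich = any(iv.name is not None or iv.score is not None for iv in iset)
    with open(path, "w") as fh:
        for iv in iset:
            if rich:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t.\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-pair intersection of two sets as disjoint intervals."""
    out: list[GenomicInterval] = []
    arrays_b = b.merged_arrays()
    for chrom, (sa, ea) in a.merged_arrays().items():
        if chrom not in arrays_b:
            continue
        sb, eb = arrays_b[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            s = max(sa[i], sb[j])
            e = min(ea[i], eb[j])
            if s < e:
                out.append(GenomicInterval(chrom, int(s), int(e)))
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
    return IntervalSet(out)


def overlap_fraction(query: IntervalSet, subject: IntervalSet, min_bp: int = 1) -> float:
    """Fraction of query intervals overlapping >= ``min_bp`` bases of the subject union."""
    if min_bp < 1:
        raise ArgumentError(f"min_bp must be >= 1, got {min_bp}")
    if len(query) == 0:
        warnings.warn("overlap_fraction: empty query, returning 0", stacklevel=2)
        return 0.0
    hits = sum(
        1
        for iv in query
        if subject.overlap_bp(iv.chrom, iv.start, iv.end) >= min_bp
    )
    return hits / len(query)


# ---------------------------------------------------------------------------
# gene models and peak annotation


@dataclass(frozen=True)
class GeneModel:
    """A gene/transcript with a strand-aware TSS.

    ``strand`` is +1/-1; the TSS equals ``tx_start`` on plus-strand genes and
    ``tx_end - 1`` on minus-strand genes.
    """

    gene_id: str
    chrom: str
    strand: int
    tx_start: int
    tx_end: int
    tss: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise DataError(f"{self.gene_id}: strand must be +1/-1, got {self.strand}")
        if not (0 <= self.tx_start < self.tx_end):
            raise DataError(f"{self.gene_id}: need 0 <= tx_start < tx_end")
        if self.tss == -1:
            object.__setattr__(
                self, "tss", self.tx_start if self.strand == 1 else self.tx_end - 1
            )
        if not (self.tx_start <= self.tss < self.tx_end):
            raise DataError(f"{self.gene_id}: tss {self.tss} outside transcript")

    @property
    def end3(self) -> int:
        """Position of the 3'-most transcribed base."""
        return self.tx_end - 1 if self.strand == 1 else self.tx_start


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (name=gene_id) or a 6-column TSV.

    The TSV dialect is ``gene_id, chrom, strand, tx_start, tx_end, tss`` with
    an optional header line starting with ``gene_id``.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "gene_id":
                continue
            try:
                if len(f) >= 6 and f[5] in ("+", "-"):
                    strand = 1 if f[5] == "+" else -1
                    genes.append(
                        GeneModel(f[3], f[0], strand, int(f[1]), int(f[2]))
                    )
                elif len(f) >= 6:
                    strand = {"+": 1, "-": -1, "1": 1, "-1": -1}[f[2]]
                    genes.append(
                        GeneModel(f[0], f[1], strand, int(f[3]), int(f[4]), int(f[5]))
                    )
                else:
                    raise ValueError("expected BED6 or 6-column TSV")
            except (ValueError, KeyError, DataError) as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttx_start\ttx_end\ttss\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{g.tss}\n"
            )


def promoter_intervals(
    genes: Sequence[GeneModel], upstream: int = 3000, downstream: int = 3000
) -> dict[str, GenomicInterval]:
    """Strand-oriented promoter windows (TSS -upstream/+downstream) per gene."""
    out: dict[str, GenomicInterval] = {}
    for g in genes:
        if g.strand == 1:
            s, e = g.tss - upstream, g.tss + downstream + 1
        else:
            s, e = g.tss - downstream, g.tss + upstream + 1
        out[g.gene_id] = GenomicInterval(g.chrom, max(0, s), e, name=g.gene_id)
    return out


@dataclass(frozen=True)
class FeatureAnnotation:
    """Single-feature assignment of one peak (priority rule, midpoint-decided)."""

    peak: GenomicInterval
    feature: str
    gene_id: str
    distance_to_tss: int


class _ZoneIndex:
    """Merged per-chromosome intervals supporting point and range queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            if s < e:
                by_chrom.setdefault(chrom, []).append((s, e))
        self.arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts: list[int] = []
            ends: list[int] = []
            for s, e in ivs:
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self.arrays[chrom] = (np.asarray(starts), np.asarray(ends))

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self.arrays:
            return False
        starts, ends = self.arrays[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.arrays:
            return False
        starts, ends = self.arrays[chrom]
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and ends[i] > start


def _build_zones(
    genes: Sequence[GeneModel],
    exons: Mapping[str, Sequence[tuple[int, int]]] | None,
    utr5: Mapping[str, Sequence[tuple[int, int]]] | None,
    utr3: Mapping[str, Sequence[tuple[int, int]]] | None,
    tss_window: tuple[int, int],
    downstream_len: int,
) -> dict[str, _ZoneIndex]:
    up, down = tss_window
    prom, ex, u5, u3, body, downs = [], [], [], [], [], []
    for g in genes:
        if g.strand == 1:
            prom.append((g.chrom, g.tss - up, g.tss + down + 1))
            downs.append((g.chrom, g.tx_end, g.tx_end + downstream_len))
        else:
            prom.append((g.chrom, g.tss - down, g.tss + up + 1))
            downs.append((g.chrom, g.tx_start - downstream_len, g.tx_start))
        body.append((g.chrom, g.tx_start, g.tx_end))
        for table, dest in ((exons, ex), (utr5, u5), (utr3, u3)):
            if table and g.gene_id in table:
                dest.extend((g.chrom, int(s), int(e)) for s, e in table[g.gene_id])
    return {
        "promoter": _ZoneIndex((c, max(0, s), e) for c, s, e in prom),
        "five_prime_utr": _ZoneIndex(u5),
        "three_prime_utr": _ZoneIndex(u3),
        "exon": _ZoneIndex(ex),
        "intron": _ZoneIndex(body),  # body minus higher-priority classes
        "downstream": _ZoneIndex((c, max(0, s), e) for c, s, e in downs),
    }


def annotate_peaks(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    exon_table: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    utr5_table: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    utr3_table: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    tss_window: tuple[int, int] = (3000, 3000),
    downstream_len: int = 3000,
    mode: str = "midpoint",
) -> tuple[list[FeatureAnnotation], pd.Series]:
    """Assign each peak exactly one genomic feature plus the nearest gene.

    Features are decided by the priority promoter > 5'UTR > 3'UTR > exon >
    intron > downstream > distal_intergenic, at the peak midpoint
    (``mode="midpoint"``, default) or by any-overlap of the whole peak
    (``mode="overlap"``).  Gene bodies without an exon table annotate as
    intron.  Returns the per-peak annotations and the feature-proportion
    summary (a Series over all seven categories summing to 1).
    """
    if not genes:
        raise ArgumentError("annotate_peaks: empty gene list")
    if mode not in ("midpoint", "overlap"):
        raise ArgumentError(f"unknown mode {mode!r}")
    zones = _build_zones(
        genes, exon_table, utr5_table, utr3_table, tss_window, downstream_len
    )
    # nearest-TSS lookup per chromosome
    tss_by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    tmp: dict[str, list[GeneModel]] = {}
    for g in genes:
        tmp.setdefault(g.chrom, []).append(g)
    for chrom, gs in tmp.items():
        gs.sort(key=lambda g: g.tss)
        tss_by_chrom[chrom] = (np.asarray([g.tss for g in gs]), gs)

    annotations: list[FeatureAnnotation] = []
    counts = dict.fromkeys(FEATURE_PRIORITY, 0)
    for peak in peaks:
        mid = peak.midpoint
        feature = "distal_intergenic"
        for feat in FEATURE_PRIORITY[:-1]:
            idx = zones[feat]
            hit = (
                idx.contains(peak.chrom, mid)
                if mode == "midpoint"
                else idx.overlaps(peak.chrom, peak.start, peak.end)
            )
            if hit:
                feature = feat
                break
        # nearest gene by TSS distance (on the peak's chromosome if present)
        if peak.chrom in tss_by_chrom:
            tss_arr, gs = tss_by_chrom[peak.chrom]
            j = int(np.searchsorted(tss_arr, mid))
            best = min(
                (g for g in gs[max(0, j - 1) : j + 1]),
                key=lambda g: abs(mid - g.tss),
            )
            dist = (mid - best.tss) * best.strand
            gene_id = best.gene_id
        else:
            gene_id, dist = "", 0
        annotations.append(FeatureAnnotation(peak, feature, gene_id, int(dist)))
        counts[feature] += 1
    n = max(len(peaks), 1)
    props = pd.Series({f: counts[f] / n for f in FEATURE_PRIORITY}, name="proportion")
    return annotations, props


# ---------------------------------------------------------------------------
# coverage


class Coverage:
    """bedGraph-like step coverage: disjoint weighted intervals per chromosome.

    Supports vectorised region sums via prefix sums; values must be >= 0.
    """

    def __init__(
        self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    ) -> None:
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(values < 0):
                raise DataError(f"negative coverage values on {chrom}")
            if np.any(ends <= starts):
                raise DataError(f"empty/inverted coverage bin on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise DataError(f"overlapping coverage bins on {chrom}")
            self.data[chrom] = (starts, ends, values)
            self._cum[chrom] = np.concatenate(
                [[0.0], np.cumsum(values * (ends - starts))]
            )

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "Coverage":
        path = Path(path)
        raw: dict[str, list[list[float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise BedParseError(f"{path}:{lineno}: expected 4 columns")
                try:
                    raw.setdefault(f[0], []).append(
                        [int(f[1]), int(f[2]), float(f[3])]
                    )
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: {exc}") from exc
        return cls(
            {
                chrom: tuple(np.asarray(cols) for cols in zip(*rows))  # type: ignore[arg-type]
                for chrom, rows in raw.items()
            }
        )

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                starts, ends, values = self.data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    def region_sums(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorised sum of value x covered-bp over each query ``[start, end)``."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self.data:
            return np.zeros(len(starts))
        bs, be, bv = self.data[chrom]
        cum = self._cum[chrom]
        lo = np.searchsorted(be, starts, side="right")
        hi = np.searchsorted(bs, ends, side="left")
        full = cum[np.maximum(hi, lo)] - cum[lo]
        # subtract partial overhang of the first and last intersecting bins
        out = np.zeros(len(starts))
        inter = hi > lo
        li, hi_i = lo[inter], hi[inter] - 1
        left_trim = np.maximum(starts[inter] - bs[li], 0) * bv[li]
        right_trim = np.maximum(be[hi_i] - ends[inter], 0) * bv[hi_i]
        out[inter] = full[inter] - left_trim - right_trim
        return out

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        return float(self.region_sums(chrom, np.array([start]), np.array([end]))[0])

    def total(self) -> float:
        return float(sum(c[-1] for c in self._cum.values()))


def tss_profile(
    treat: Coverage,
    input_cov: Coverage | None,
    genes: Sequence[GeneModel],
    flank: int = 5000,
    bin_size: int = 50,
    pseudocount: float = 1.0,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene TSS-anchored matrix of log2((treat + c) / (input + c)) bin means.

    Rows are oriented 5'->3' (minus-strand rows reversed); columns are bin-start
    offsets relative to the TSS.  Bins falling off the chromosome are NaN.
    """
    if flank % bin_size != 0:
        raise ArgumentError("flank must be divisible by bin size")
    if pseudocount <= 0:
        raise ArgumentError("pseudocount must be > 0")
    nbins = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size)
    rows = []
    for g in genes:
        bin_starts = g.tss + offsets
        bin_ends = bin_starts + bin_size
        t = treat.region_sums(g.chrom, bin_starts, bin_ends) / bin_size
        if input_cov is not None:
            i = input_cov.region_sums(g.chrom, bin_starts, bin_ends) / bin_size
        else:
            i = np.zeros(nbins)
        vals = np.log2((t + pseudocount) / (i + pseudocount))
        bad = bin_starts < 0
        if chrom_sizes is not None and g.chrom in chrom_sizes:
            bad |= bin_ends > chrom_sizes[g.chrom]
        vals[bad] = np.nan
        if g.strand == -1:
            vals = vals[::-1]
        rows.append(vals)
    return pd.DataFrame(
        rows, index=[g.gene_id for g in genes], columns=offsets
    )
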