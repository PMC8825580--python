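"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the statistical structure of a myeloma cell-line /
patient-cohort study: per-mark peak sets with configurable genomic-feature
proportions, an enhancer landscape whose signal has a typical-enhancer bulk
and a planted super-enhancer regime, log-normal expression with planted group
effects, exponential survival whose hazard depends on planted gene
dichotomies (exactly the model the risk score assumes, which makes parameter
recovery a sharp test), and drug response linear in a planted score.

Every generator is a pure function of the :class:`SimConfig` (including its
seed): the random stream is split deterministically per generator and per
sample, so changing one configuration block never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .intervals import (
    Coverage,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    promoter_intervals,
    write_bed,
    write_genes,
)
from .survival import SurvivalCohort

__all__ = [
    "SimConfig",
    "SyntheticGenome",
    "make_genome",
    "make_peaks",
    "make_enhancer_landscape",
    "make_expression",
    "make_group_expression",
    "make_survival_cohort",
    "make_drug_response",
    "write_simulation",
]

# fixed stream ids so generators stay independent under one seed
_GENOME, _PEAKS, _ENHANCER, _EXPR, _SURV, _RESPONSE = range(6)


#: per-mark genomic-feature proportions emulating the study's annotation
#: profile (activating marks split between promoters/distal enhancers,
#: repressive marks essentially intergenic/intronic)
DEFAULT_MARK_PROPORTIONS: dict[str, dict[str, float]] = {
    "H3K4me1": {"distal_intergenic": 0.454, "intron": 0.354, "promoter": 0.10,
                "exon": 0.05, "downstream": 0.042},
    "H3K4me3": {"promoter": 0.421, "distal_intergenic": 0.362, "intron": 0.15,
                "exon": 0.047, "downstream": 0.02},
    "H3K27ac": {"distal_intergenic": 0.348, "promoter": 0.329, "intron": 0.20,
                "exon": 0.08, "downstream": 0.043},
    "H3K9me3": {"distal_intergenic": 0.70, "intron": 0.30},
    "H3K27me3": {"distal_intergenic": 0.60, "intron": 0.40},
    "H3K36me3": {"intron": 0.45, "exon": 0.25, "distal_intergenic": 0.20,
                 "downstream": 0.10},
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the defaults used throughout."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 30_000_000
    n_genes: int = 400
    gene_min_len: int = 12_000
    gene_max_len: int = 20_000
    # peaks
    n_peaks: int = 1000
    marks: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_MARK_PROPORTIONS
    )
    n_samples: int = 4
    n_comark_genes: int = 30
    comark_sample_prob: float = 0.6
    # enhancer landscape
    n_enhancers: int = 1000
    super_fraction: float = 0.05
    super_multiplier: float = 20.0
    bulk_signal_mean: float = 10.0
    # expression (log2 scale)
    expr_location: float = 5.0
    expr_gene_sd: float = 1.0
    expr_noise_sd: float = 1.0
    planted_log2fc: float = 2.0
    n_planted_de: int = 50
    # survival
    n_patients: int = 600
    baseline_hazard: float = np.log(2) / 72.0  # per month; median OS ~ 6 years
    planted_betas: tuple[float, ...] = (0.7,) * 10
    planted_cut_quantile: float = 0.5
    censoring_rate: float = 0.3
    # drug response
    response_intercept: float = 4.0
    response_slope: float = -0.5
    response_noise_sd: float | None = None  # None -> calibrated to target_r2
    response_target_r2: float = 0.4

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, stream])


@dataclass
class SyntheticGenome:
    genes: list[GeneModel]
    exons: dict[str, list[tuple[int, int]]]
    utr5: dict[str, list[tuple[int, int]]]
    utr3: dict[str, list[tuple[int, int]]]
    chrom_sizes: dict[str, int]

    def promoters(self, upstream: int = 3000, downstream: int = 3000):
        return promoter_intervals(self.genes, upstream, downstream)


def make_genome(cfg: SimConfig) -> SyntheticGenome:
    """Place non-overlapping genes uniformly in slots, strand Bernoulli(0.5).

    Each gene gets a 4-exon structure; the outermost 200 bp of the terminal
    exons are the UTRs.  Genes are separated by at least 40 kb of intergenic
    space so promoter/downstream/distal zones never collide.
    """
    if cfg.n_genes < 1:
        raise ArgumentError("n_genes must be >= 1")
    rng = cfg.rng(_GENOME)
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    slot = cfg.chrom_length // per_chrom
    margin = 20_000
    if slot < cfg.gene_max_len + 2 * margin:
        raise ArgumentError(
            "genes cannot fit: increase chrom_length or reduce n_genes"
        )
    genes: list[GeneModel] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    utr5: dict[str, list[tuple[int, int]]] = {}
    utr3: dict[str, list[tuple[int, int]]] = {}
    g = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        for s in range(per_chrom):
            if g >= cfg.n_genes:
                break
            length = int(rng.integers(cfg.gene_min_len, cfg.gene_max_len + 1))
            lo = s * slot + margin
            start = int(rng.integers(lo, lo + slot - length - 2 * margin))
            strand = 1 if rng.random() < 0.5 else -1
            gene_id = f"G{g:04d}"
            genes.append(GeneModel(gene_id, chrom, strand, start, start + length))
            # 4 exons of 400 bp, equal introns between them
            n_ex, ex_len = 4, 400
            intron_len = (length - n_ex * ex_len) // (n_ex - 1)
            ex_list = []
            pos = start
            for _ in range(n_ex):
                ex_list.append((pos, pos + ex_len))
                pos += ex_len + intron_len
            ex_list[-1] = (start + length - ex_len, start + length)
            exons[gene_id] = ex_list
            if strand == 1:
                utr5[gene_id] = [(ex_list[0][0], ex_list[0][0] + 200)]
                utr3[gene_id] = [(ex_list[-1][1] - 200, ex_list[-1][1])]
            else:
                utr5[gene_id] = [(ex_list[-1][1] - 200, ex_list[-1][1])]
                utr3[gene_id] = [(ex_list[0][0], ex_list[0][0] + 200)]
            g += 1
    return SyntheticGenome(
        genes,
        exons,
        utr5,
        utr3,
        {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)},
    )


def _anchor_position(
    rng: np.random.Generator, feature: str, gene: GeneModel, genome: SyntheticGenome
) -> int:
    """A midpoint position whose priority-rule annotation equals ``feature``."""
    if feature == "promoter":
        return gene.tss + int(rng.integers(-2000, 2001))
    if feature == "downstream":
        off = int(rng.integers(500, 2500))
        return gene.end3 + off if gene.strand == 1 else gene.end3 - off
    ex = genome.exons[gene.gene_id]
    if feature == "exon":
        # interior exons only: away from the promoter window and both UTRs
        inner = [
            (s, e)
            for s, e in ex[1:-1]
            if abs((s + e) // 2 - gene.tss) > 3600
        ]
        s, e = inner[int(rng.integers(len(inner)))]
        return int(rng.integers(s + 50, e - 50))
    if feature == "intron":
        introns = [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]
        # introns fully outside the promoter window (with peak-width slack)
        cand = [
            (s, e) for s, e in introns if s > gene.tss + 3600 or e < gene.tss - 3600
        ]
        if not cand:  # fall back: deep midpoint of the longest intron
            s, e = max(introns, key=lambda iv: iv[1] - iv[0])
            return (s + e) // 2
        s, e = cand[int(rng.integers(len(cand)))]
        return int(rng.integers(s + 100, e - 100))
    raise ArgumentError(f"no anchor rule for feature {feature!r}")


def _distal_positions(genome: SyntheticGenome, clearance: int = 10_000):
    """Intergenic intervals at least ``clearance`` bp from every gene."""
    by_chrom: dict[str, list[tuple[int, int]]] = {
        c: [] for c in genome.chrom_sizes
    }
    for g in genome.genes:
        by_chrom[g.chrom].append((g.tx_start, g.tx_end))
    gaps: list[tuple[str, int, int]] = []
    for chrom, spans in by_chrom.items():
        spans.sort()
        prev = 0
        for s, e in spans + [(genome.chrom_sizes[chrom], genome.chrom_sizes[chrom] + 1)]:
            lo, hi = prev + clearance, s - clearance
            if hi - lo > 2000:
                gaps.append((chrom, lo, hi))
            prev = e
    return gaps


def make_peaks(
    cfg: SimConfig, genome: SyntheticGenome
) -> tuple[dict[tuple[str, str], IntervalSet], dict]:
    """Per-sample, per-mark peak sets with planted feature labels and co-marks.

    Returns ``(peaksets, truth)`` where ``peaksets`` maps ``(sample, mark)``
    to an :class:`IntervalSet` and ``truth`` carries the planted feature label
    table and the planted co-marked promoter membership (gene -> samples).
    """
    rng = cfg.rng(_PEAKS)
    gaps = _distal_positions(genome)
    gap_arr = [(c, lo, hi) for c, lo, hi in gaps]
    gap_weights = np.array([hi - lo for _, lo, hi in gap_arr], dtype=float)
    gap_weights /= gap_weights.sum()
    samples = [f"S{i:02d}" for i in range(cfg.n_samples)]
    peaksets: dict[tuple[str, str], IntervalSet] = {}
    label_rows = []
    for sample in samples:
        for mark, props in cfg.marks.items():
            feats = list(props)
            pvec = np.array([props[f] for f in feats], dtype=float)
            if np.any(pvec < 0) or pvec.sum() > 1 + 1e-9:
                raise ArgumentError(f"{mark}: proportions must be in [0,1], sum <= 1")
            pvec = pvec / pvec.sum()
            intervals = []
            if cfg.n_peaks:
                labels = rng.choice(len(feats), size=cfg.n_peaks, p=pvec)
                for k, li in enumerate(labels):
                    feature = feats[li]
                    if feature == "distal_intergenic":
                        gi = int(rng.choice(len(gap_arr), p=gap_weights))
                        chrom, lo, hi = gap_arr[gi]
                        pos = int(rng.integers(lo + 500, hi - 500))
                    else:
                        gene = genome.genes[int(rng.integers(len(genome.genes)))]
                        chrom = gene.chrom
                        pos = _anchor_position(rng, feature, gene, genome)
                    half = int(rng.integers(100, 300))
                    iv = GenomicInterval(
                        chrom, pos - half, pos + half, name=f"{sample}_{mark}_{k}"
                    )
                    intervals.append(iv)
                    label_rows.append(
                        {"sample": sample, "mark": mark, "peak": iv.name,
                         "feature": feature}
                    )
            peaksets[(sample, mark)] = IntervalSet(intervals, sample, mark)

    # planted co-marked promoters (both repressive marks on the promoter)
    comark_truth: dict[str, list[str]] = {}
    if cfg.n_comark_genes:
        chosen = rng.choice(len(genome.genes), size=cfg.n_comark_genes, replace=False)
        proms = genome.promoters()
        for gi in sorted(chosen):
            gene = genome.genes[gi]
            member = [s for s in samples if rng.random() < cfg.comark_sample_prob]
            if not member:
                member = [samples[int(rng.integers(len(samples)))]]
            comark_truth[gene.gene_id] = member
            prom = proms[gene.gene_id]
            for s in member:
                for mark in ("H3K9me3", "H3K27me3"):
                    if (s, mark) not in peaksets:
                        peaksets[(s, mark)] = IntervalSet([], s, mark)
                    center = gene.tss + int(rng.integers(-1000, 1001))
                    half = int(rng.integers(200, 400))
                    iv = GenomicInterval(
                        prom.chrom, center - half, center + half,
                        name=f"{s}_{mark}_comark_{gene.gene_id}",
                    )
                    peaksets[(s, mark)] = IntervalSet(
                        list(peaksets[(s, mark)]) + [iv], s, mark
                    )
    truth = {
        "feature_labels": pd.DataFrame(label_rows),
        "comark": comark_truth,
        "samples": samples,
    }
    return peaksets, truth


def make_enhancer_landscape(
    cfg: SimConfig, genome: SyntheticGenome
) -> tuple[IntervalSet, Coverage, pd.DataFrame]:
    """H3K27ac peaks + coverage with a planted super-enhancer regime.

    Bulk locus signals are Exponential(``bulk_signal_mean``); planted supers
    sit in a second regime at ``super_multiplier * bulk_signal_mean`` plus an
    exponential spread.  Constituent peaks of one locus lie within stitching
    distance of each other; distinct loci are separated by more than the
    default stitch gap, so stitching recovers exactly the planted loci.
    Returns (peaks, treat coverage, truth table).
    """
    if not (0 < cfg.super_fraction < 0.5):
        raise ArgumentError("super_fraction must be in (0, 0.5)")
    rng = cfg.rng(_ENHANCER)
    gaps = _distal_positions(genome, clearance=12_000)
    spacing = 16_000  # > default 12.5 kb stitch gap
    slots: list[tuple[str, int]] = []
    for chrom, lo, hi in gaps:
        pos = lo
        while pos + 8000 < hi:
            slots.append((chrom, pos))
            pos += spacing + 8000
    if len(slots) < cfg.n_enhancers:
        raise ArgumentError(
            f"genome too small for {cfg.n_enhancers} enhancer loci "
            f"({len(slots)} slots)"
        )
    pick = np.sort(rng.choice(len(slots), size=cfg.n_enhancers, replace=False))
    n_super = int(round(cfg.super_fraction * cfg.n_enhancers))
    is_super = np.zeros(cfg.n_enhancers, dtype=bool)
    is_super[rng.choice(cfg.n_enhancers, size=n_super, replace=False)] = True
    bulk = rng.exponential(cfg.bulk_signal_mean, size=cfg.n_enhancers)
    super_signal = (
        cfg.super_multiplier * cfg.bulk_signal_mean
        + rng.exponential(cfg.bulk_signal_mean, size=cfg.n_enhancers)
    )
    signal = np.where(is_super, super_signal, bulk)

    peaks: list[GenomicInterval] = []
    cov: dict[str, list[list[float]]] = {}
    rows = []
    for i, (slot_i, sig, sup) in enumerate(zip(pick, signal, is_super)):
        chrom, base = slots[slot_i]
        n_con = int(rng.integers(1, 4))
        pos = base
        constituents = []
        for _ in range(n_con):
            width = int(rng.integers(600, 1200))
            constituents.append((pos, pos + width))
            pos += width + int(rng.integers(500, 2500))  # gap well under stitch gap
        total_len = sum(e - s for s, e in constituents)
        value = sig / total_len
        for s, e in constituents:
            peaks.append(GenomicInterval(chrom, s, e, name=f"E{i:04d}"))
            cov.setdefault(chrom, []).append([s, e, value])
        rows.append(
            {"locus": f"E{i:04d}", "chrom": chrom,
             "start": constituents[0][0], "end": constituents[-1][1],
             "signal": sig, "is_super": bool(sup)}
        )
    coverage = Coverage(
        {
            chrom: tuple(np.asarray(cols) for cols in zip(*sorted(rows_)))
            for chrom, rows_ in cov.items()
        }
    )
    truth = pd.DataFrame(rows)
    return IntervalSet(peaks, sample="sim", mark="H3K27ac"), coverage, truth


def make_expression(
    cfg: SimConfig, gene_ids: Sequence[str], n_samples: int, stream: int = _EXPR
) -> pd.DataFrame:
    """Log-normal expression: log2 values mu_g + N(0, noise_sd) per sample."""
    rng = cfg.rng(stream)
    mu = cfg.expr_location + cfg.expr_gene_sd * rng.standard_normal(len(gene_ids))
    vals = mu[:, None] + cfg.expr_noise_sd * rng.standard_normal(
        (len(gene_ids), n_samples)
    )
    return pd.DataFrame(
        vals, index=list(gene_ids), columns=[f"P{j:04d}" for j in range(n_samples)]
    )


def make_group_expression(
    cfg: SimConfig, gene_ids: Sequence[str], n_a: int, n_b: int
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two-group expression with ``n_planted_de`` genes shifted up in group A."""
    rng = cfg.rng(_EXPR)
    gene_ids = list(gene_ids)
    mu = cfg.expr_location + cfg.expr_gene_sd * rng.standard_normal(len(gene_ids))
    a = mu[:, None] + cfg.expr_noise_sd * rng.standard_normal((len(gene_ids), n_a))
    b = mu[:, None] + cfg.expr_noise_sd * rng.standard_normal((len(gene_ids), n_b))
    up = sorted(rng.choice(len(gene_ids), size=cfg.n_planted_de, replace=False))
    a[up, :] += cfg.planted_log2fc
    expr_a = pd.DataFrame(a, index=gene_ids, columns=[f"A{j:03d}" for j in range(n_a)])
    expr_b = pd.DataFrame(b, index=gene_ids, columns=[f"B{j:03d}" for j in range(n_b)])
    return expr_a, expr_b, [gene_ids[i] for i in up]


def make_survival_cohort(
    cfg: SimConfig, expression: pd.DataFrame
) -> tuple[SurvivalCohort, pd.DataFrame]:
    """Exponential survival whose log hazard is a sum of planted dichotomies.

    hazard(patient) = h0 * exp(sum_g beta_g * 1[expr_g > cut_g]) over the
    planted genes (the first ``len(planted_betas)`` rows of ``expression``);
    cut_g is the planted quantile of that gene's expression.  Censoring is an
    independent uniform time calibrated to the configured censoring rate.
    Returns the cohort plus the planted (gene, beta, cutpoint) truth table.
    """
    rng = cfg.rng(_SURV)
    betas = np.asarray(cfg.planted_betas, dtype=float)
    if len(betas) > expression.shape[0]:
        raise ArgumentError("more planted betas than genes in expression")
    planted = list(expression.index[: len(betas)])
    cuts = np.array(
        [
            np.quantile(expression.loc[g].to_numpy(), cfg.planted_cut_quantile)
            for g in planted
        ]
    )
    above = (
        expression.loc[planted].to_numpy() > cuts[:, None]
    ).astype(float)  # genes x patients
    loghaz = np.log(cfg.baseline_hazard) + betas @ above
    times = rng.exponential(1.0 / np.exp(loghaz))
    event = np.ones(len(times), dtype=int)
    if cfg.censoring_rate > 0:
        u = rng.random(len(times))
        # calibrate the uniform censoring horizon to the requested rate
        lo_t, hi_t = 1e-6, float(times.max()) * 4.0
        for _ in range(60):
            tau = 0.5 * (lo_t + hi_t)
            frac = float(np.mean(u * tau < times))
            if frac > cfg.censoring_rate:  # too much censoring -> raise horizon
                lo_t = tau
            else:
                hi_t = tau
        ctime = u * (0.5 * (lo_t + hi_t))
        event = (times <= ctime).astype(int)
        times = np.minimum(times, ctime)
    times = np.maximum(times, 1e-6)
    cohort = SurvivalCohort(
        list(expression.columns), times, event, expression
    )
    truth = pd.DataFrame({"gene_id": planted, "beta": betas, "cutpoint": cuts})
    return cohort, truth


def make_drug_response(
    cfg: SimConfig, scores: pd.Series | np.ndarray
) -> tuple[np.ndarray, dict]:
    """IC50 = a + b * score + N(0, sd); sd defaults to the target-R^2 calibration."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 4:
        raise ArgumentError("make_drug_response: need >= 4 samples")
    rng = cfg.rng(_RESPONSE)
    sd = cfg.response_noise_sd
    if sd is None:
        spread = s.std()
        if spread == 0 or cfg.response_slope == 0:
            sd = 1.0
        else:
            r2 = cfg.response_target_r2
            sd = abs(cfg.response_slope) * spread * np.sqrt((1 - r2) / r2)
    ic50 = cfg.response_intercept + cfg.response_slope * s + rng.normal(0, sd, len(s))
    truth = {"intercept": cfg.response_intercept, "slope": cfg.response_slope,
             "noise_sd": float(sd)}
    return ic50, truth


def write_simulation(cfg: SimConfig, outdir: str | Path) -> None:
    """Materialise a full simulated study in the formats the pipeline reads."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    genome = make_genome(cfg)
    write_genes(genome.genes, outdir / "genes.tsv")
    peaksets, truth = make_peaks(cfg, genome)
    for (sample, mark), ps in peaksets.items():
        write_bed(ps, outdir / f"{sample}.{mark}.bed")
    truth["feature_labels"].to_csv(
        outdir / "truth" / "feature_labels.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(g, ",".join(ss)) for g, ss in truth["comark"].items()],
        columns=["gene_id", "samples"],
    ).to_csv(outdir / "truth" / "comark.tsv", sep="\t", index=False)
    peaks, coverage, se_truth = make_enhancer_landscape(cfg, genome)
    write_bed(peaks, outdir / "k27ac_enhancers.bed")
    coverage.to_bedgraph(outdir / "k27ac.bdg")
    se_truth.to_csv(outdir / "truth" / "superenhancers.tsv", sep="\t", index=False)
    gene_ids = [g.gene_id for g in genome.genes]
    expr = make_expression(cfg, gene_ids, cfg.n_patients)
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    cohort, surv_truth = make_survival_cohort(cfg, expr)
    pd.DataFrame(
        {"patient_id": cohort.patient_ids, "time": cohort.time, "event": cohort.event}
    ).to_csv(outdir / "survival.tsv", sep="\t", index=False)
    surv_truth.to_csv(outdir / "truth" / "prognostic_genes.tsv", sep="\t", index=False)
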