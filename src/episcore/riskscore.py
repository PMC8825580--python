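"""Prognostic gene selection and the +/-1-weighted Cox-beta risk score.

The score of a patient is ``sum_g beta_g * w_g`` where ``beta_g`` is the Cox
log hazard ratio of gene ``g`` fitted on its maxstat dichotomy in the training
cohort and ``w_g`` is +1 when the patient's expression is strictly above the
gene's cutpoint, else -1 (equality codes as below, configurable).  A global
maxstat cutoff on the score splits patients into high- and low-risk groups.
Cross-cohort transfer keeps betas and the score cutoff, and re-derives each
gene's cutpoint in the validation cohort by matching the training fraction of
patients above the cutpoint (quantile matching).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError
from .survival import (
    CoxFit,
    KaplanMeierEstimate,
    LogrankResult,
    MaxstatResult,
    SurvivalCohort,
    bh_adjust,
    cox_beta_binary,
    cox_beta_continuous,
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
)

__all__ = [
    "RiskGene",
    "RiskScoreModel",
    "ScoreSplit",
    "diff_expression",
    "strongly_expressed",
    "select_prognostic",
    "score_patients",
    "fit_score_cutoff",
    "transfer_model",
    "correlate_score_response",
]


@dataclass
class RiskGene:
    """One score component: beta at the maxstat dichotomy plus its cutpoint."""

    gene_id: str
    beta: float
    cutpoint: float
    prop_above: float
    q_value: float
    separation: bool = False


@dataclass
class RiskScoreModel:
    genes: list[RiskGene]
    score_cutoff: float | None = None
    training_meta: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def max_abs_score(self) -> float:
        return float(sum(abs(g.beta) for g in self.genes))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            cutoff = "" if self.score_cutoff is None else repr(self.score_cutoff)
            meta = ";".join(f"{k}={v}" for k, v in sorted(self.training_meta.items()))
            fh.write(f"# score_cutoff={cutoff}\tmeta={meta}\n")
            fh.write("gene_id\tbeta\tcutpoint\tprop_above\tq_value\tseparation\n")
            for g in self.genes:
                fh.write(
                    f"{g.gene_id}\t{g.beta!r}\t{g.cutpoint!r}\t{g.prop_above!r}\t"
                    f"{g.q_value!r}\t{int(g.separation)}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RiskScoreModel":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("# score_cutoff="):
                raise ArgumentError(f"{path}: missing score_cutoff header")
            cut_field, _, meta_field = header[2:].partition("\t")
            cut_str = cut_field.split("=", 1)[1]
            score_cutoff = None if cut_str == "" else float(cut_str)
            meta: dict = {}
            if meta_field.startswith("meta=") and meta_field[5:]:
                meta = dict(kv.split("=", 1) for kv in meta_field[5:].split(";"))
            df = pd.read_csv(fh, sep="\t")
        genes = [
            RiskGene(
                str(r.gene_id),
                float(r.beta),
                float(r.cutpoint),
                float(r.prop_above),
                float(r.q_value),
                bool(r.separation),
            )
            for r in df.itertuples()
        ]
        return cls(genes, score_cutoff, meta)


# ---------------------------------------------------------------------------
# gene filters


def diff_expression(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame, alternative: str = "over"
) -> pd.DataFrame:
    """Per-gene one-sided Wilcoxon rank-sum of cohort A vs cohort B.

    ``alternative="over"`` tests A > B (e.g. overexpressed in tumor vs normal
    plasma cells), ``"under"`` tests A < B.  Returns a DataFrame with columns
    statistic, p, q (BH-adjusted), indexed like the inputs.
    """
    if alternative not in ("over", "under"):
        raise ArgumentError(f"unknown alternative {alternative!r}")
    if not expr_a.index.equals(expr_b.index):
        raise ArgumentError("diff_expression: gene indices differ")
    if expr_a.shape[1] < 3 or expr_b.shape[1] < 3:
        raise ArgumentError("diff_expression: need >= 3 samples per group")
    side = "greater" if alternative == "over" else "less"
    res = stats.mannwhitneyu(
        expr_a.to_numpy(), expr_b.to_numpy(), axis=1, alternative=side
    )
    return pd.DataFrame(
        {"statistic": res.statistic, "p": res.pvalue, "q": bh_adjust(res.pvalue)},
        index=expr_a.index,
    )


def strongly_expressed(expr: pd.DataFrame, quantile: float = 0.5) -> list[str]:
    """Genes whose median expression exceeds the given quantile of all values."""
    threshold = np.quantile(expr.to_numpy(), quantile)
    med = expr.median(axis=1)
    return list(expr.index[med > threshold])


# ---------------------------------------------------------------------------
# selection and scoring


def select_prognostic(
    candidates: Sequence[str],
    cohort: SurvivalCohort,
    fdr: float = 0.05,
    direction: str = "any",
    eps: tuple[float, float] = (0.1, 0.9),
    beta_on: str = "dichotomy",
) -> list[RiskGene]:
    """Keep candidate genes with a BH-significant maxstat cutpoint.

    Per gene: maxstat cutpoint and selection-adjusted p on the training
    cohort; BH across the candidate list; survivors at q <= ``fdr`` get a Cox
    beta fitted on the dichotomy ``expression > cutpoint`` (or on the
    continuous expression with ``beta_on="continuous"``).  ``direction``
    filters by beta sign: ``adverse_high`` keeps beta > 0 (high expression is
    adverse), ``adverse_low`` keeps beta < 0.
    """
    if len(candidates) == 0:
        raise ArgumentError("select_prognostic: empty candidate list")
    if direction not in ("adverse_high", "adverse_low", "any"):
        raise ArgumentError(f"unknown direction {direction!r}")
    missing = [g for g in candidates if g not in cohort.expression.index]
    if missing:
        raise ArgumentError(f"candidates absent from cohort expression: {missing[:5]}")
    results: dict[str, MaxstatResult] = {}
    for gene in candidates:
        x = cohort.expression.loc[gene].to_numpy(dtype=float)
        try:
            results[gene] = maxstat_cutpoint(cohort.time, cohort.event, x, eps=eps)
        except ArgumentError:
            continue  # constant/degenerate gene: not selectable
    if not results:
        return []
    genes = list(results)
    q = bh_adjust([results[g].p_value for g in genes])
    out: list[RiskGene] = []
    for gene, qv in zip(genes, q):
        if qv > fdr:
            continue
        res = results[gene]
        x = cohort.expression.loc[gene].to_numpy(dtype=float)
        above = (x > res.cutpoint).astype(int)
        if beta_on == "dichotomy":
            fit: CoxFit = cox_beta_binary(cohort.time, cohort.event, above)
        elif beta_on == "continuous":
            fit = cox_beta_continuous(cohort.time, cohort.event, x)
        else:
            raise ArgumentError(f"unknown beta_on {beta_on!r}")
        if direction == "adverse_high" and fit.beta <= 0:
            continue
        if direction == "adverse_low" and fit.beta >= 0:
            continue
        out.append(
            RiskGene(
                gene_id=gene,
                beta=fit.beta,
                cutpoint=res.cutpoint,
                prop_above=float(above.mean()),
                q_value=float(qv),
                separation=not fit.converged,
            )
        )
    out.sort(key=lambda g: (g.q_value, g.gene_id))
    return out


def score_patients(
    model: RiskScoreModel, expr: pd.DataFrame, equality: str = "below"
) -> pd.Series:
    """Per-patient score: sum of beta_g * (+1 above cutpoint_g, else -1).

    Expression exactly at the cutpoint codes as below (w = -1) by default;
    ``equality="above"`` flips that convention.
    """
    missing = [g.gene_id for g in model.genes if g.gene_id not in expr.index]
    if missing:
        raise ArgumentError(f"score_patients: genes missing from expression: {missing}")
    if equality not in ("below", "above"):
        raise ArgumentError(f"unknown equality convention {equality!r}")
    scores = pd.Series(0.0, index=expr.columns)
    for g in model.genes:
        x = expr.loc[g.gene_id]
        above = x > g.cutpoint if equality == "below" else x >= g.cutpoint
        scores += g.beta * np.where(above, 1.0, -1.0)
    return scores


@dataclass
class ScoreSplit:
    """Maxstat split of the score into high-risk (> cutoff) and low-risk."""

    cutoff: float
    maxstat: MaxstatResult
    n_high: int
    n_low: int
    logrank: LogrankResult
    km_high: KaplanMeierEstimate
    km_low: KaplanMeierEstimate

    @property
    def high_fraction(self) -> float:
        return self.n_high / (self.n_high + self.n_low)


def fit_score_cutoff(
    scores, cohort: SurvivalCohort, eps: tuple[float, float] = (0.1, 0.9)
) -> ScoreSplit:
    """Maxstat on the score as covariate; returns the split and its log-rank test."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 20:
        raise ArgumentError("fit_score_cutoff: need >= 20 patients")
    if np.all(scores == scores[0]):
        raise ArgumentError("fit_score_cutoff: constant scores")
    res = maxstat_cutpoint(cohort.time, cohort.event, scores, eps=eps)
    high = scores > res.cutpoint
    lr = logrank_test(cohort.time, cohort.event, high.astype(int))
    return ScoreSplit(
        cutoff=res.cutpoint,
        maxstat=res,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        logrank=lr,
        km_high=km_estimate(cohort.time[high], cohort.event[high]),
        km_low=km_estimate(cohort.time[~high], cohort.event[~high]),
    )


def transfer_cutpoint(values, prop_above: float) -> float:
    """Largest observed value v with fraction{values > v} >= prop_above."""
    vals = np.asarray(values, dtype=float)
    uniq = np.unique(vals)[::-1]
    fracs = np.array([(vals > v).mean() for v in uniq])
    ok = fracs >= prop_above
    if not ok.any():
        warnings.warn(
            "transfer_cutpoint: requested proportion unattainable; using minimum",
            stacklevel=2,
        )
        return float(uniq[-1] - 1.0)
    return float(uniq[ok][0])  # uniq is descending: first ok is the largest


def transfer_model(model: RiskScoreModel, validation_expr: pd.DataFrame) -> RiskScoreModel:
    """Re-derive gene cutpoints in a validation cohort by proportion matching.

    Betas and the global score cutoff are copied unchanged (the training
    dichotomy proportions define the validation cutpoints).
    """
    missing = [g.gene_id for g in model.genes if g.gene_id not in validation_expr.index]
    if missing:
        raise ArgumentError(f"transfer_model: genes missing from validation: {missing}")
    new_genes = []
    for g in model.genes:
        vals = validation_expr.loc[g.gene_id].to_numpy(dtype=float)
        cut = transfer_cutpoint(vals, g.prop_above)
        new_genes.append(
            RiskGene(g.gene_id, g.beta, cut, g.prop_above, g.q_value, g.separation)
        )
    meta = dict(model.training_meta)
    meta["transferred"] = "yes"
    return RiskScoreModel(new_genes, model.score_cutoff, meta)


@dataclass
class ScoreResponseCorrelation:
    pearson_r: float
    r_squared: float
    p_value: float
    n: int


def correlate_score_response(scores, response) -> ScoreResponseCorrelation:
    """Pearson correlation between per-sample scores and a drug readout (IC50).

    Pairs with a missing response are dropped with a warning; needs >= 4
    complete pairs and non-constant vectors.
    """
    s = np.asarray(scores, dtype=float)
    r = np.asarray(response, dtype=float)
    if s.shape != r.shape:
        raise ArgumentError("scores and response must be aligned")
    ok = np.isfinite(s) & np.isfinite(r)
    if (~ok).any():
        warnings.warn(
            f"correlate_score_response: dropping {int((~ok).sum())} pairs with "
            "missing values",
            stacklevel=2,
        )
        s, r = s[ok], r[ok]
    if len(s) < 4:
        raise ArgumentError("correlate_score_response: need >= 4 paired samples")
    if s.std() == 0 or r.std() == 0:
        raise ArgumentError("correlate_score_response: zero variance input")
    res = stats.pearsonr(s, r)
    return ScoreResponseCorrelation(
        pearson_r=float(res.statistic),
        r_squared=float(res.statistic**2),
        p_value=float(res.pvalue),
        n=len(s),
    )
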