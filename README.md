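# episcore

Histone-mark peak annotation, super-enhancer calling, bivalent-promoter
discovery and maxstat/Cox prognostic risk scores — the computational pipeline
of an epigenomic study of multiple myeloma cell lines and patient cohorts,
re-implemented as a tested, reusable Python package exercised end-to-end on
synthetic data with planted structure.

## Who this is for

Computational biologists analysing ChIP-seq panels of histone post-
translational modifications (H3K4me1/3, H3K9me3, H3K27ac, H3K27me3,
H3K36me3) across tumor samples, who want to

* annotate peak calls by genomic feature (promoter / UTR / exon / intron /
  downstream / distal intergenic),
* identify super-enhancers ROSE-style from H3K27ac signal and assign active
  genes to them,
* find promoters co-repressed by H3K9me3 **and** H3K27me3 (bivalent
  heterochromatin/Polycomb marking),
* turn gene lists into survival risk scores transferable across cohorts, and
* test differential binding between phenotype groups (e.g. drug-resistant vs
  -sensitive lines).

## The statistics at the core

**Maximally selected rank statistics (maxstat).** For a continuous covariate
X (gene expression) and right-censored survival (T, δ), every observed value
c inside the ε-quantile window (default ε = (0.1, 0.9)) defines a dichotomy
X > c. The standardized log-rank statistic Z(c) = U(c)/√V(c) is computed for
each split and the cutpoint is argmax |Z(c)|. Because the cutpoint is
selected, the p-value uses the Lausen–Schumacher improved-Bonferroni
approximation (a permutation test is also available).

**Cox-beta risk score.** Each selected gene g gets a log hazard ratio β_g
from a univariate Cox fit (Newton–Raphson, Breslow ties) on its maxstat
dichotomy. A patient's score is

    score = Σ_g β_g · w_g ,   w_g = +1 if expr_g > cutpoint_g else −1.

A maxstat cut on the score itself splits patients into high-risk
(score > cutoff) and low-risk groups; the split is tested by log-rank.
Transfer to a validation cohort keeps β and the score cutoff, and re-derives
each gene's cutpoint by matching the training proportion of patients above
it (quantile matching).

**Super-enhancers.** H3K27ac peaks fully inside TSS ± 2.5 kb are excluded,
the rest are stitched within 12.5 kb, stitched domains are scored by
background-subtracted coverage and ranked; the super-enhancer boundary is
the inflection of the scaled rank–signal curve (two-regime changepoint by
default; the classic slope-1 tangent is available). Active genes with a TSS
within 50 kb of a super-enhancer are assigned to it.

**Differential binding.** Consensus regions supported by ≥ 2 samples are
counted per sample, normalised to log2 CPM (pseudo-count 0.5), and tested
with a variance-floored Welch t per region, BH-corrected at FDR ≤ 0.05.

## Worked example

Build a risk score on a simulated training cohort (600 patients, 200 genes,
10 planted prognostic genes with β = 0.7) and transfer it to a validation
cohort:

```python
from episcore.synthetic_data import SimConfig, make_expression, make_survival_cohort
from episcore.riskscore import (RiskScoreModel, select_prognostic, score_patients,
                                fit_score_cutoff, transfer_model)

cfg = SimConfig(seed=42, n_patients=600)
gene_ids = [f"G{i:04d}" for i in range(200)]
expr = make_expression(cfg, gene_ids, 600)
cohort, truth = make_survival_cohort(cfg, expr)

genes = select_prognostic(gene_ids, cohort, fdr=0.05, direction="any")
model = RiskScoreModel(genes)
scores = score_patients(model, expr)
split = fit_score_cutoff(scores.to_numpy(), cohort)
model.score_cutoff = split.cutoff
```

This prints (via the summary statements in the example script):

```
selected 8 prognostic genes (8 of 10 planted)
score cutoff +1.883: 98 high-risk / 502 low-risk patients (high-risk fraction 16.3%)
log-rank chi-square 231.7, p = 2.55e-52
validation high-risk fraction after transfer: 17.0%
```

Eight of the ten planted genes are recovered at BH FDR ≤ 0.05 with no false
selections; the maxstat cut on the summed score isolates the patients
carrying many adverse dichotomies (hazard e^0.7 ≈ 2 per planted gene), and
quantile-matched transfer reproduces the training high-risk fraction in an
independent cohort to within a few percent.

The same pipeline is scriptable from the shell:

```sh
episcore simulate --seed 42 --out sim/
episcore annotate --peaks sim/S00.H3K4me3.bed --genes sim/genes.tsv --out ann.tsv
episcore se --peaks sim/k27ac_enhancers.bed --coverage sim/k27ac.bdg \
            --genes sim/genes.tsv --out se.tsv
episcore score build --surv sim/survival.tsv --expr sim/expression.tsv \
            --direction any --out model.tsv
```

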