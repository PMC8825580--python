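# Methods

This note documents the models, conventions and calibration decisions behind
the package, in the spirit of the methods documentation of mature statistical
packages: what is computed, under which assumptions, which knobs matter, and
what the synthetic-data tests do and do not demonstrate.

## Coordinates and the interval engine

All coordinates are 0-based half-open, the native BED dialect; files are read
and written without shifting. Interval sets are normalised on construction
(sorted by chromosome, start, end, name; exact duplicates dropped) and all
overlap arithmetic (union, intersection, covered-bp queries, consensus
support) runs on per-chromosome sorted arrays. Chromosome names are compared
as exact strings. Because every downstream module rests on this engine, the
test suite holds it to *exact* agreement with an independent pairwise
O(n·m) oracle on random instances up to 1000 intervals, and the acceptance
script re-measures that agreement on every run.

## Peak annotation

Each peak receives exactly one feature by the priority
promoter > 5'UTR > 3'UTR > exon > intron > downstream > distal intergenic,
decided at the peak midpoint (an any-overlap mode is available). The
promoter window defaults to TSS −3000/+3000 (strand-oriented) and the
downstream window to 3 kb past the 3' end; both are parameters everywhere
they are consumed, because annotation tools differ and the published
analyses rarely state them. Gene bodies without an exon table annotate as
intron — by base-pair coverage introns dominate real gene bodies, and the
convention is explicit rather than silently guessing exon structure. The
reported gene is the nearest-TSS gene with a strand-signed distance.

Note one structural consequence of the priority rule: a 5'UTR that lies
within the promoter window annotates as promoter. The synthetic generator
therefore plants five feature classes (promoter, exon, intron, downstream,
distal); UTR classification is exercised by explicit fixtures whose UTRs lie
outside the promoter window.

## Super-enhancer calling

Stitching follows the ROSE recipe: peaks fully contained in a TSS ± 2.5 kb
exclusion zone are removed (partially overlapping peaks are kept intact),
and surviving same-chromosome peaks merge transitively while consecutive
gaps are ≤ 12.5 kb. Stitched domains are scored by summed treatment
coverage minus summed input coverage, clipped at zero.

**Boundary detection.** The classic construction scales ranks and signals to
[0, 1] and takes the point where the curve's slope passes 1 (the tangent of
the unit diagonal). That geometry implicitly assumes the super-enhancer tail
dominates the signal scale: the tangent sits where the local signal spacing
equals s_max/n, so roughly n·mean/s_max of the largest *typical* enhancers
always land above it. At the moderate contrast of the planted simulation
(bulk exponential with mean 10, supers at 20× the bulk mean) that is ~40
bulk enhancers misclassified, and single-point discrete slopes are noisier
still. The default detector is therefore a **two-regime changepoint**: the
split of the scaled rank curve minimising the total squared error of two
separate least-squares line fits (ties resolved toward fewer supers). On
two-regime data it recovers the planted boundary exactly; on a pure linear
ramp it calls at most one super; with all signals equal it calls none. The
slope-crossing and tangent rules remain available as `method="slope"` and
`method="tangent"` for compatibility with the classic behaviour.

Gene assignment uses edge extension: a transcriptionally active gene is
assigned to a super-enhancer when its TSS lies within the stitched region
extended by 50 kb on both sides. "Active" defaults to expression above the
sample's median (configurable quantile). An optional evidence filter demands
that each super-enhancer overlap at least one peak of a second activating
mark (H3K4me1), reflecting panels where super-enhancers are supported by two
marks; the default is H3K27ac-only.

## Bivalent (co-marked) promoters

A promoter counts as co-marked in a sample when it overlaps ≥ min_bp (default
1 bp) of an H3K9me3 peak *and* of an H3K27me3 peak; a strict mode further
requires the two marks' intersection to cover ≥ min_bp within the promoter.
The default is the inclusive mode — the strict result is always a subset.
Recurrence across samples is an exact count with gene-id tie-breaking, and
thresholding is deliberately left to the downstream scoring configuration.

## Survival primitives

* **Kaplan–Meier** is the standard product-limit estimator over distinct
  event times; at tied times events precede censoring (both stay in the risk
  set at that time).
* **Log-rank** uses observed-minus-expected with the hypergeometric variance
  and its tie correction, summed over distinct event times; the reported Z
  is signed for group 1.
* **Cox (binary covariate)** maximises the Breslow partial likelihood by
  Newton–Raphson (tolerance 1e-8 on the score, ≤ 50 iterations).  Monotone
  likelihood (separation) is detected when |β| exceeds 10; β is clamped
  there and flagged (`converged=False`), and the flag propagates into risk
  genes as `separation`. A continuous-covariate variant (standardised
  internally) backs the optional continuous-β mode of gene selection.
* **Maxstat** candidates are the observed covariate values inside the
  ε-quantile window, default (0.1, 0.9), excluding values tied with the
  maximum so both groups stay populated; ties in |Z| resolve to the smaller
  cutpoint. The scan is vectorised (one pass builds the at-risk group counts
  for every candidate simultaneously) and is held to exact agreement with a
  split-by-split scalar scan.

**Selection-adjusted p-value.** The default is the improved-Bonferroni
approximation evaluated at the actual candidate split sizes m_i/n, which
sums bivariate-normal crossing terms over adjacent splits; an
Ornstein–Uhlenbeck bridge approximation and a seeded permutation test
(default B = 1000) are provided. Monte-Carlo calibration at the package's
standard null-calibration size (n = 100, 30% censoring, 500 replicates)
gives P(p < 0.05) ≈ 0.05; at n = 60 the normal approximation of extreme
splits is slightly liberal (≈ 0.06–0.08), which is why null-calibration
checks in this package are stated at n ≥ 100. The approximation saturates at
1 under deep nulls (it is an upper bound), so approximation and permutation
p-values are comparable only where both are informative; the tests compare
them under a planted moderate association.

A subtlety worth knowing: with perfectly separated data (all deaths below a
threshold, all others censored), the *standardized* statistic is nearly flat
across all pure splits and often peaks at an unbalanced interior cut — the
located cutpoint is then any value inside the early-death region, not
necessarily the largest value below the boundary. The tests assert the
region, not a specific value.

## Risk scores

Gene selection: candidate genes (optionally pre-filtered by a strong-
expression rule — median expression above the dataset's global median — and
by one-sided rank-sum differential expression against a reference tissue)
are scanned by maxstat, BH-adjusted across the candidate list, kept at
q ≤ 0.05, and given a Cox β on their dichotomy. A direction filter keeps
adverse-high (β > 0) genes for activating-mark scores and adverse-low for
repressive-domain scores.

Scoring: score = Σ β_g·w_g with w_g = ±1 by the gene's cutpoint; expression
exactly at the cutpoint codes as below (w = −1), with the symmetric
convention available. Scores are bounded by ±Σ|β_g|, invariant to gene
order, and crossing one gene's cutpoint moves the score by exactly 2β_g.
The global cutoff is a maxstat cut on the score; high-risk = score > cutoff.
Transfer keeps β and the score cutoff verbatim and re-derives gene cutpoints
in the validation cohort as the largest observed value with at least the
training fraction of patients above it, which preserves the training
proportions up to a 1/n discretisation.

β is fitted on the dichotomy by default (consistent with the ±1 weighting by
the same dichotomy); fitting on the continuous covariate is available behind
`beta_on="continuous"`.

## Differential binding

Consensus regions are the union-merge of all samples' peaks restricted to
regions overlapped by ≥ min_overlap (default 2) distinct samples. Counts are
summed coverage per region; normalisation is log2 CPM with pseudo-count 0.5
(scale-invariant: common library-size factors cancel). Each region is tested
with a Welch t on logCPM whose per-group variances are floored at the lower
decile (floor_quantile = 0.1) of all per-region group variances, then
BH-corrected.

The floor level was a genuine calibration decision. Flooring at the trimmed
mean of the variances — a natural first choice — suppresses small p-values
for the entire high-count subpopulation (logCPM variance falls with
abundance), skewing the null p-distribution well away from uniform (KS
≈ 0.09–0.10 on Poisson nulls of 2000 regions, 8 vs 8). The lower-decile
floor keeps the guard against spuriously tiny denominators while leaving
null p-values uniform (KS ≈ 0.03) and the flagged fraction under a permuted-
label null effectively zero; planted four-fold changes are recovered
essentially completely. Occupancy-mode analyses binarise the region × sample
matrix; affinity-mode correlation heatmaps use log2(count + 1) with
average-linkage clustering on 1 − r.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a single configuration (seed included):
the random stream is split deterministically per generator, so changing one
block never perturbs another, and identical configurations reproduce every
byte.

* **Genome**: non-overlapping genes in uniformly jittered slots (strand
  Bernoulli(0.5)), 4-exon structure, ≥ 40 kb intergenic spacing so
  promoter/downstream/distal zones never collide — feature planting is then
  exactly recoverable by the annotator, making proportion-recovery a sharp
  binomial test.
* **Peaks**: feature labels drawn from per-mark proportion targets modelled
  on the study's annotation profile (activating marks split between
  promoters and distal enhancers; repressive marks intergenic/intronic). A
  chosen gene subset receives both repressive marks on its promoter in a
  chosen sample subset, with the membership table returned as ground truth.
* **Enhancer landscape**: bulk locus signals ~ Exponential(mean 10); planted
  supers in a shifted second regime at multiplier × bulk mean (+ exponential
  spread). The shift matters: a purely multiplicative super draw at 20×
  leaves ~29% of supers below the bulk maximum, and no boundary rule could
  then meet a 0.9 Jaccard—the planted structure is a separated regime, which
  is also the regime the changepoint detector is built for. Constituent
  peaks of a locus lie within stitching distance; loci are separated by more
  than the stitch gap, so stitching recovers exactly the planted loci.
* **Survival**: hazard(patient) = h₀·exp(Σ β_g·1[expr_g > cut_g]) with
  exponential times — exactly the model the risk score assumes, which makes
  β recovery a sharp test. Baseline h₀ = ln2/72 per month (median survival
  ~6 years), 10 planted genes at β = 0.7, cutpoints at the median,
  censoring by an independent uniform horizon calibrated by bisection to the
  target rate (default 30%).
* **Drug response**: IC50 = a + b·score + noise, slope negative
  (anti-correlation between score and inhibitor IC50); the noise SD defaults
  to the value giving R² ≈ 0.4, the regime reported for such score–response
  correlations.

None of this mimics read-level noise, GC bias, copy-number effects,
mean–variance trends of real ChIP enrichment, or correlated gene expression.
Passing the recovery tests therefore demonstrates the *algorithms* are
correct and calibrated under their stated models — not that real-data
signatures of any particular size would be recovered.

## Problem sizes and numerical conventions

The standard study sizes used throughout the tests and the acceptance script
are: 600 training / 100 validation patients, 200 candidate genes with 10
planted, 1000 enhancer loci with 5% supers at 20×, 2000 consensus regions
with 8 vs 8 samples, 50–500 replicates for oracle-equality and null-
calibration loops. These are the sizes at which the pipeline's guarantees
are stated and re-measured.

Numerical conventions: BH via the standard step-up; p-values clamped to
(0, 1]; maxstat ties to the smaller cutpoint; stitching ties (gap exactly at
the threshold) merge; changepoint ties resolve to fewer supers; score ties
at a cutpoint code as below; Cox clamp at |β| = 10 with the separation flag;
coverage queries outside the covered domain count as zero, and TSS-profile
bins falling off a chromosome are NaN.

## Known limitations

* Univariate Cox only — no multivariate adjustment, time-varying covariates
  or competing risks.
* The improved-Bonferroni maxstat p is slightly liberal below n ≈ 100 at
  extreme split fractions; use the permutation method for small cohorts.
* The differential-binding test is a moderated t on logCPM, not a
  negative-binomial GLM; it is validated by null calibration, not by
  agreement with any particular NB implementation.
* Gene assignment to super-enhancers is proximity-only; no looping or
  activity-by-contact modelling.
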