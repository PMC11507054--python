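# Methods

This note documents the models, statistics and numerical choices behind
serrapath: what each procedure assumes, which parameters matter and why
their defaults were chosen, and what the synthetic cohorts do and do not
establish about real data.

## The synthetic cohort model

A cohort is a set of samples, each labelled with a pathological stage
(normal, HP, SSL, SSLD, TSA, tumor) and carrying a latent progression
score `s ∈ [0, 1]`. With "auto" scores, samples are ranked by stage (ties
broken by sample index) and spread equispaced over [0, 1], so every sample
has a distinct planted position — the quantity the continuum analysis must
recover.

Counts for cell *c* of sample *k* and gene *g* are negative binomial with

```
mu(c, g) = L_c · b_g · 2^(beta_g · s_k) · r(c, g) · 2^(e(c, g))
Var      = mu + phi · mu²
```

where `L_c` is a lognormal library-size factor (default meanlog 0,
sdlog 0.3), `b_g` a lognormal baseline (default meanlog −1.5, sdlog 1.2,
giving a median per-cell depth near 900–1000 counts at 2000 genes —
deliberately shallow, as sample-level pseudobulk analyses must work on
modest depth), `beta_g` a continuum slope in log2 units (zero except for
the designated continuum genes; magnitudes drawn uniformly from the
configured range with random signs), `r(c, g)` the copy ratio of any
planted arm segment covering *g* in a cell of the segment's stage/type
mask, and `e(c, g)` the log2 elevation of any planted program containing
both *c* and *g*. Dispersion `phi` is shared across genes (default 0.5);
per-gene dispersion would be a config extension, not a default.

Continuum genes are drawn only from genes outside planted CNV arms, and
program genes from genes in neither set, so each planted factor stays
identifiable in recovery tests. Sampling is gamma–Poisson with a single
seeded generator; identical configs are bit-identical.

The generator deliberately omits doublets, ambient RNA, batch effects and
UMI saturation. Passing recovery tests on these cohorts shows the
estimators are correct under clean NB noise at realistic depth and cohort
size; it does not show robustness to batch structure or contamination,
which real studies must handle upstream.

The default cohort (two samples per stage × 150 cells, 2000 genes,
200 continuum genes with |slope| 1–3) is the desk-scale study condition
used throughout the tests; the CNV experiments use the full study layout
(13 normal, 4 HP, 5 SSL, 1 SSLD, 5 TSA, 10 tumor) because arm-level and
stage-level comparisons are sample-level statistics that need the cohort,
not deeper cells.

## Preprocessing

QC keeps cells with ≥ `min_genes` detected genes (default 200, a
conventional whole-transcriptome threshold — scale it down for reduced
gene panels) and mitochondrial fraction ≤ `max_mito_pct` (default 20%,
genes recognised by the `MT-` name prefix). Normalization is
`ln(1 + count · 1e4 / libsize)`. Natural log with pseudocount 1 is used
throughout; downstream log2FC de-logs group means first, so the base
choice cancels.

## Hurdle differential expression

Single-cell expression of one gene is modelled as a hurdle: a detection
event, then a magnitude among expressing cells. The test per gene has two
parts, each an OLS test of the group coefficient with the cell's centered
CDR (fraction of genes detected) as covariate:

* **detection**: linear model on the 0/1 detection indicator over all
  cells;
* **magnitude**: linear model on Blom normal scores
  `Phi⁻¹((rank − 0.375)/(k + 0.25))` of the values among the gene's *k*
  expressing cells.

The CDR covariate matters because sequencing-depth imbalance between two
cell groups shifts detection and magnitude for *every* gene at once; on
null simulations the unadjusted test (selectable with
`depth_adjust=False`) is anti-conservative exactly in proportion to the
chance depth imbalance of the draw. Normal scores replace raw
log-expression in the magnitude part because with few expressing cells
the raw values are too skewed for a t reference in the far tail, which is
what BH selection actually uses.

The two parts are combined by Fisher's method with Brown's dependence
correction: both parts are computed from the same cells, so their
statistics are positively correlated within a gene and plain Fisher
(χ², 4 df) overstates joint significance at extreme quantiles. The
cross-part correlation is estimated per run as the Spearman correlation of
the signed part statistics across genes (rank-based, so heavy tails and
signal genes cannot dominate), mapped to the Pearson scale via
`2·sin(πρ/6)` and converted to a scaled-χ² null (Kost–McDermott
covariance). When only one part is defined the combination is χ² with
2 df; genes below 5% detection in both groups are reported untested.

Measured calibration under the null study condition (two 150-cell groups,
5000 genes): KS distance to uniform ≤ 0.035 across 15 seeds; Monte-Carlo
E[FDP] of BH selection at α = 0.05, estimated over 200 independent
1000-gene replicates, 0.05–0.06. The FDP of a single completely-null run
is 0 or 1 by definition, so the Monte-Carlo average is the meaningful
realised-FDR estimate.

The effect size is `log2((mean(expm1(x_target)) + 1) /
(mean(expm1(x_ref)) + 1))` — de-logged group means with pseudocount 1.

## Continuum ordering

Per-sample profiles are computed against the pooled normal-sample cells of
the target subtype; reference-stage samples are profiled too (against the
pool that includes their own cells) so the normal end of the continuum is
anchored. BH adjustment is per sample across its tested genes. Genes with
`p_adj < 0.05` in ≥ 2 samples are selected; the samples × selected-genes
log2FC matrix (untested entries imputed as 0 — "no evidence of change"
read as neutral, with the imputation count logged) is column-centered and
decomposed by unscaled PCA (log2FC is already on one scale). Component
signs follow a fixed convention (largest-magnitude loading positive).
Exactly collinear sample profiles are valid input — PC2 then carries zero
variance; only identical profiles (rank 0) are an error.

The principal curve is fitted by the Hastie–Stuetzle alternation:
positions initialised on PC1; each coordinate smoothed against current
positions with a locally-linear lowess (span 0.7 — at cohort sizes of
10–40 samples a wide span is needed for stable local fits); samples
re-projected orthogonally onto the fitted polyline; iterate to
`max_iter = 30`. Convergence is declared when the mean squared orthogonal
distance changes by < 1e-4 relative to any of the last six iterates — a
discrete smoother settles into short periodic orbits rather than a fixed
point, and the history comparison accepts an orbit whose amplitude is
below tolerance. Because lowess with local linear fits reproduces affine
data exactly, exactly collinear samples degenerate to their own line and
positions equal normalized orthogonal projections to machine precision.

Arc-length positions are rescaled to [0, 1] and oriented so the mean
normal-sample position is below the mean position of the most progressed
stage present. Gene trends are per-gene Spearman correlations of log2FC
against PC2 by default (the axis that carried progression in the study
data); against arc-length positions as an option — in synthetic cohorts
the continuum typically dominates PC1, so the position axis is the
informative choice there. Constant log2FC vectors are flagged, not
dropped silently; BH is applied across testable genes.

## CNV inference

Reference-anchored and windowed: center each gene on the reference-cell
mean, clip to ±3 (the cap bounds the influence of any single gene; it also
means the "centering zeroes the reference" identity holds only where the
cap does not bind), then moving-average along genomic position within each
chromosome with an odd window, shrinking symmetrically at chromosome
edges. The default window of 101 genes is the whole-transcriptome
convention (~0.7% of ~15,000 genes); on reduced panels scale it to the
same genomic fraction — the desk-scale experiments at 2000 genes use 15,
since a 101-gene window would span entire chromosomes (~90 genes) and
destroy locality. No HMM segmentation or reference subclustering is
attempted; this is deliberately the transparent windowed-mean realization.

The per-cell CNV score is the mean squared smoothed deviation — scale-
stable across gene counts and zero only for a neutral profile. Arm events
are called on sample-mean profiles (per individual, not per cell): the
percentage of an arm's genes whose sample-mean smoothed signal exceeds
+0.1 (gain) or falls below −0.1 (loss). For samples consisting entirely of
reference cells the sample mean uses all their cells.

Power note: a single heterozygous-level arm gain (ratio 1.5, ~2% of genes)
shifts the whole-transcriptome mean-square score by ~0.001 against a
per-cell noise floor with SD ~0.013 at ~900 counts/cell (Cohen's d ≈
0.055); distinguishing stages by score on such a plant would need
thousands of cells per group. Arm-percentage calls detect the same plant
comfortably (≥ 80% of the arm in every tumor sample of the study-layout
cohort; normal samples are usually ≤ 5%, with occasional higher values
from call noise on a 40-odd-gene arm at 150 cells/sample). The stage-wise
Kruskal–Wallis experiment therefore plants a stage-graded burden — a 7p
gain in serrated lesions; 7p gain plus the 5q/17p/18q events typical of
colorectal carcinoma in tumors — which separates normal / SL / tumor
scores at p ≪ 0.01.

## Gene-program scores and phases

Module scores follow the control-bin scheme: genes ranked by mean
expression and cut into 25 equal-size bins; each set gene draws 100
control genes from its own bin (without replacement until the bin is
exhausted, then with replacement), and the score is mean set expression
minus mean control expression per cell. Scores are invariant to adding a
constant to a cell's whole expression vector, and deterministic given the
seed (each program gets an independent substream of a master seed).
Binning parameters are exposed in config; 25/100 are the field's customary
defaults. A planted +1 ln-unit elevation over 50 genes yields a measured
masked-vs-unmasked gap of ~0.65–0.70 — below 1 because log1p compresses a
multiplicative elevation of raw counts.

Phases: G1 iff both S and G2M scores ≤ 0, else the larger score's phase
(ties at equal positive scores go to S). A minimal EMT/S/G2M marker GMT
ships for convenience (`data/programs_minimal.gmt`); real analyses should
supply their preferred signatures (e.g. the hallmark EMT set) — synthetic
cohorts define their own program sets from the planted truth.

## Composition testing

Per-sample proportions over all cell types present anywhere (absent types
get explicit zero rows). Stage pairs are compared by the two-sided
Wilcoxon rank-sum on per-sample proportions: exact null distribution when
both groups have ≤ 10 samples and no ties, normal approximation with tie
correction otherwise. The serrated stages can be pooled into one SL group.
Stars map unadjusted p-values (NS ≥ 0.05 > * ≥ 0.01 > ** ≥ 0.001 > ***) by
default; a BH option across cell types exists. Measured type-I error at
α = 0.05 over 1000 equal-proportion replicates: ~0.04–0.05 (the exact
test's discreteness keeps it at or just under nominal).

## Pipeline

One YAML drives simulate → qc → composition → cnv → score → continuum.
Unknown config keys are errors. The global seed is fanned out per stage
through SHA-256 of `"{seed}:{stage}"`, so disabling one stage never
perturbs another's randomness. All tables are TSV with `#` provenance
headers (parameters, seed, version — no timestamps) and fixed float
formatting, making reruns byte-identical; the report records SHA-256
digests of every output. A failed stage is recorded and its dependents
halted, but the partial report is still written.

## Known limitations

* The hurdle test assumes cells are exchangeable within groups given CDR;
  within-sample correlation beyond depth (e.g. subclonal structure) is
  not modelled, and the per-sample profiles inherit it.
* The continuum is one-dimensional by construction; branching progression
  (e.g. distinct SSL and TSA arms diverging in expression space) would be
  flattened onto one curve.
* CNV calls are expression proxies: arm percentages respond to any
  coherent regional expression shift, not only copy number, and the
  mean-square score cannot resolve small single-arm events per cell.
* Module scores depend on the control-bin match; with very few genes
  (≲ 500) bins are coarse and control matching degrades.
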