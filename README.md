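# serrapath

Analysis toolkit for serrated-pathway colorectal cancer progression in
multi-sample single-cell RNA-seq, built around the idea of a **malignant
continuum**: ordering whole samples — normal mucosa, the serrated polyp
stages (HP, SSL, SSLD, TSA) and carcinoma — by how far their malignant
epithelial cells have drifted from a normal reference, using expression
alone.

It is written for computational biologists studying premalignant
progression who have a cells × genes count matrix with per-cell sample,
stage and cell-type labels, and want sample-level orderings, CNV burden
summaries and gene-program scores with planted-truth validation behind
every statistic.

## What it computes

**Malignant continuum** (the core). For each sample, the target epithelial
subtype's cells are compared with pooled normal-sample cells by a two-part
hurdle test per gene *g*:

* a detection-rate part (is *g* expressed in more/fewer cells?),
* a magnitude part on normal scores among expressing cells,

both as OLS group-effect tests adjusting for each cell's overall detection
rate (CDR), combined by Brown's dependence-corrected Fisher method, with
effect size

```
log2FC(s, g) = log2( (mean_expm1(target) + 1) / (mean_expm1(ref) + 1) )
```

Genes BH-significant in ≥ 2 samples form a samples × genes log2FC matrix;
unscaled PCA of that matrix followed by a Hastie–Stuetzle principal curve
in the PC1–PC2 plane assigns each sample an arc-length position in [0, 1],
oriented from normal to tumor. Spearman correlation of per-gene log2FC
against PC2 (or arc length) finds genes trending along the continuum.

**CNV inference.** Log-normalized expression centered on reference cells,
clipped, and smoothed along genomic position within chromosomes; per-cell
burden score `mean(smoothed²)`; per-sample chromosome-arm gain/loss
percentages; Kruskal–Wallis comparison of scores across stages or cell
types.

**Gene programs.** Control-matched module scores (set mean minus
expression-bin-matched control mean) for arbitrary GMT sets, e.g. EMT;
cell-cycle phase calls from S and G2M scores (G1 iff both ≤ 0, else
argmax).

**Composition.** Per-sample cell-type proportions and two-sided Wilcoxon
rank-sum tests between stage groups (exact null for ≤ 10 samples per
group), starred NS / * / ** / *** at 0.05 / 0.01 / 0.001.

**Simulator.** A negative-binomial cohort generator with per-sample latent
progression scores driving monotone log2FC in designated genes,
chromosome-arm copy-number segments, elevated gene programs and lognormal
library sizes — every planted effect recorded in a truth object, so each
estimator above is testable for parameter recovery.

## Worked example

`examples/02_malignant_continuum.py` simulates the default cohort (12
samples, two per stage, 150 SLC1 cells each, 2000 genes of which 200 carry
planted slopes of 1–3 log2 units) and recovers the sample ordering:

```
selected genes (significant in >= 2 samples): 171
explained variance PC1/PC2: 0.90 / 0.02

sample ordering along the continuum (position 0 = normal-like):
  normal_1   normal  position 0.000  planted s 0.00
  normal_2   normal  position 0.070  planted s 0.09
  HP_1       HP      position 0.154  planted s 0.18
  ...
  tumor_2    tumor   position 1.000  planted s 1.00

Spearman(recovered position, planted score) = 1.000
```

171 genes pass the two-sample selection rule (200 were planted; the rest
lack power in ≥ 2 samples), PC1 carries 90% of the log2FC variance, and
the arc-length ordering reproduces the planted progression exactly
(Spearman ρ = 1.0). The other examples cover simulation, CNV inference,
program scoring, composition testing and the end-to-end pipeline; each
prints what its numbers mean.

## Command line

A thin CLI wraps the library for file-based use:

```bash
serrapath simulate --config sim.yaml --out data/ --seed 1
serrapath cnv --counts data/ --reference-stage normal --window 101 --out cnv/
serrapath continuum --counts data/ --target-subtype SLC1 --out cont/
serrapath run --config run.yaml --out results/     # full pipeline
serrapath validate --config run.yaml
```

`serrapath run` executes simulate → qc → composition → cnv → score →
continuum from one YAML (see `src/serrapath/data/demo_config.yaml`),
writes provenance-headed TSVs and a `report.json`, and is byte-for-byte
reproducible for a fixed config and seed.

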