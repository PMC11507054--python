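# Demo pipeline config: a 12-sample serrated-pathway cohort (two samples per
# stage, 150 SLC1 cells each, 2000 genes) with a planted malignant continuum
# (200 genes, slopes 1-3 log2 units), a 7p gain in tumor cells, and
# EMT / S / G2M programs.  Completes in well under a minute on one CPU.
seed: 1
stages:
  simulate: true
  qc: true
  composition: true
  cnv: true
  score: true
  continuum: true
simulate:
  n_samples_per_stage: {normal: 2, HP: 2, SSL: 2, SSLD: 2, TSA: 2, tumor: 2}
  n_cells_per_sample: 150
  n_genes: 2000
  n_continuum_genes: 200
  slope_range: [1.0, 3.0]
  nb_dispersion: 0.5
  cnv_segments:
    - [7p, 1.5, all, [tumor]]
  program_defs:
    # 1.4427 log2 units = +1 natural-log unit of elevation
    EMT: [50, 1.4427, 0.25]
    S: [50, 1.4427, 0.15]
    G2M: [50, 1.4427, 0.15]
qc:
  min_genes: 200
  max_mito_pct: 20
composition:
  pairs: [[normal, SL], [SL, tumor]]
  merge_sl: true
cnv:
  reference_stage: normal
  # 2000-gene data: ~90 genes per chromosome, so use a window covering the
  # same genomic fraction that 101 genes covers on a whole transcriptome
  window: 15
  cap: 3.0
  gain_thr: 0.1
  loss_thr: 0.1
continuum:
  target_subtype: SLC1
  reference_stage: normal
  alpha: 0.05
  min_samples: 2
  axis: PC2
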