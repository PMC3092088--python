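# "paper_like" cohort preset: a desk-scale cohort emulating the demographic
# and genetic-architecture structure of a multi-center imputed case-control
# GWAS panel for an HLA-driven autoimmune disease: six recruitment strata
# with unequal case rates, ~72% female cases vs ~50% female controls, a
# major HLA-like locus carried by ~25% of controls (tagged by one SNP), and
# many weak risk/protective alleles in LD blocks.  Marker count is scaled to
# desk size; proportions and effect sizes are not.
n_cases: 500
n_controls: 1500
blocks:
  n_markers_per_block: 10
  n_blocks: 120
  within_block_r: 0.9
  maf_range: [0.05, 0.5]
disease:
  # intercept/major-locus/gender values are calibrated so that, after
  # case-control ascertainment, carrier frequency lands near 53% in cases
  # vs 25% in controls and the female share near 72% vs 50%
  intercept: -3.6
  major_locus_or: 4.3
  major_control_freq: 0.28
  n_causal: 40
  causal_or_range: [1.1, 1.6]
  gender_or: 3.5
  center_effects:
    IMSGC_UK: -1.0
    IMSGC_US: -0.7
    BWH: 0.15
    GeneMSA_CH: 1.05
    GeneMSA_NL: 0.9
    GeneMSA_US: 1.0
  imputation_quality: 0.97
center_probs:
  IMSGC_UK: 0.353
  IMSGC_US: 0.209
  BWH: 0.259
  GeneMSA_CH: 0.045
  GeneMSA_NL: 0.045
  GeneMSA_US: 0.089
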