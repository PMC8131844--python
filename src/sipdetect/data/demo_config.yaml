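# Demonstration run: one simulated acetate incubation (50% 13C-labeled
# substrate), paired labeled/control CsCl gradients at day 7, followed by
# preprocessing, dual-criterion labeled-OTU detection, and phylum summaries.
simulate:
  enabled: true
  n_otus: 120
  frac_labeled: 0.1
  preset: acetate
  treatment: acetate
  timepoints_days: [7]
  assimilation_efficiency: 1.0
  composition_jitter: 0.0
  abundance_lognormal_sigma: 1.5
  gradient:
    bd_min: 1.674
    bd_max: 1.737
    n_fractions: 12
    band_sd: 0.006
    depth_per_fraction: 30000
    mean_density: 1.725
preprocess:
  min_rel_abundance: 0.00005
  exclude_taxa: [Cyanobacteria]
  keep_singletons: false
detect:
  heavy_threshold: 1.70
  fdr: 0.10
  lfc_null: 0.25
summarize:
  rank: phylum
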