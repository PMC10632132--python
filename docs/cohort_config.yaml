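# Example cohort configuration for `mcakit simulate --config ...`.
# Top-level keys map onto CohortConfig; each entry under `groups` maps
# onto GroupConfig.

groups:
  AA:                       # group label (used as ancestry group and study)
    n_samples: 20           # samples to simulate in this group
    het_mean: 12000         # mean per-sample heterozygous-marker count
    het_sd: 800             # SD of that count (0 = every sample exact)
    female_fraction: 0.5    # probability a sample is female
    # het_quantiles:        # optional [[p, count], ...] table overriding
    #   [[0.1, 9000], [0.5, 12000], [0.9, 15000]]   # the normal model
  EAS:
    n_samples: 20
    het_mean: 9000
    het_sd: 600

genome:                     # chromosome -> length (bp); omit for GRCh38
  chr1: 100000000
  chr2: 100000000
  chrX: 80000000            # females only; males carry no chrX hets

mean_depth: 38.0            # genome-wide mean read depth (38x WGS)
depth_dispersion: 0.0       # extra gamma-Poisson dispersion; 0 = Poisson
phase_switch_rate: 0.001    # per-marker Markov phase-switch error rate

event_prevalence: 0.05      # probability a sample carries one mCA
event_type_weights:         # relative weights of event types
  gain: 0.25
  loss: 0.25
  cnloh: 0.5
cf_min: 0.005               # cell fractions drawn log-uniformly
cf_max: 0.5                 #   on [cf_min, cf_max]
event_frac_min: 0.1         # event span as a fraction of its chromosome,
event_frac_max: 1.0         #   drawn uniformly on [min, max]

cnv_mask_per_chrom: 0       # germline-CNV mask intervals per chromosome
cnv_mask_len_bp: 50000      # length of each mask interval

chip_prevalence: 0.04       # marginal CHIP carrier probability
chip_mca_odds_ratio: 1.0    # target CHIP x mCA 2x2 odds ratio
chip_genes: [DNMT3A, TET2, ASXL1, JAK2, TP53]   # carrier gene labels

age_range: [40.0, 90.0]     # sample ages drawn uniformly
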