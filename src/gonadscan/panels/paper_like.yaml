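# Expression design mirroring the published study scale: 2000 genes,
# 137 ChIP-bound genes, 94 signaling-dependent genes of which exactly
# two (the primary targets lst-1 and sygl-1) are bound. Five
# replicates per condition in the ON/OFF contrast, four per time point
# in the degradation time course at {0, 0.5, 1, 2, 4, 48} h. Primary
# target mRNAs decay with half-life 0.63 h (a ~3-fold drop by 1 h);
# the three confirmed secondary targets and the two trend-level genes
# decay with half-life 1 h after a 2 h lag (the upper bound on the
# primary targets' protein half-life); the remaining dependent genes
# respond slowly (10 h half-life) and are evident only at 48 h.
name: paper_like
n_genes: 2000
n_bound: 137
n_dependent: 94
primaries: [lst-1, sygl-1]
secondaries: [epg-5, tbx-2, C17H12.36]
weak_dependent: [ucr-2.1, F40D4.13]
effect_log2fc:
  primary: 5.0
  secondary: 3.0
  other_min: 2.5
  other_max: 4.5
targets_effect_log2fc:
  secondary: 3.0
  weak: 0.5
half_life_hours:
  primary: 0.63
  secondary: 1.0
  weak: 1.0
  other: 10.0
decay_lag_hours: 2.0
dispersion: 0.002
library_size: 30000000
reps_contrast: 5
reps_timecourse: 4
timepoints: [0, 0.5, 1, 2, 4, 48]
floor_fraction: 0.05
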