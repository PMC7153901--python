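# LST-1 and SYGL-1 protein loss after degradation of the upstream CSL
# factor (auxin time course; OLLAS-tagged proteins, distal 25 cd).
# Both proteins accumulate in the distal-most ~5 cd. Relative to the
# untreated (0 h) peak set to 100: LST-1 falls ~5-fold by 2 h and
# ~10-fold by 4 h; SYGL-1 falls ~3-fold by 2 h and 10-fold by 4 h.
# Residual protein scales down uniformly.
name: figS10
protein: LST-1/SYGL-1
max_cd: 25
peak_window: [1, 5]
peak_stat: mean
base_cd: 25
control: lst1_t0h
untagged: untagged_n2
background_level: 100.0
signal_scale: 5.0
noise_sd_pct: 2.0
n_germlines: 24
genotypes:
  lst1_t0h:
    tagged: true
    levels_pct: [[1, 100], [5, 100], [10, 12], [25, 12]]
  lst1_t2h:
    tagged: true
    levels_pct: [[1, 20], [5, 20], [10, 2.4], [25, 2.4]]
  lst1_t4h:
    tagged: true
    levels_pct: [[1, 10], [5, 10], [10, 1.2], [25, 1.2]]
  sygl1_t0h:
    tagged: true
    levels_pct: [[1, 100], [5, 100], [10, 12], [25, 12]]
  sygl1_t2h:
    tagged: true
    levels_pct: [[1, 33.333], [5, 33.333], [10, 4], [25, 4]]
  sygl1_t4h:
    tagged: true
    levels_pct: [[1, 10], [5, 10], [10, 1.2], [25, 1.2]]
  untagged_n2:
    tagged: false
    levels_pct: [[1, 0], [25, 0]]
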