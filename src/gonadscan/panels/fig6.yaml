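# FBF-2 accumulation panel over the distal 35 cd (V5-tagged protein,
# young-adult gonads). Levels are percent of the wild-type peak,
# where the peak is the maximum of the mean profile within 8-13 cd.
# Wild type peaks ~4-fold above its 35-cd base; gld-2 gld-1 peaks at
# ~80% of wild type with a faster fall to a flat base from ~18 cd
# (also ~4-fold above base). Removing Notch signaling (glp-1 null) or
# only the targets (lst-1 sygl-1 null) in that background leaves a
# flat 15% of the gld-2 gld-1 peak: the signaling-dependent 85% of the
# peak is accounted for entirely by the two target genes. (The
# quadruple/triple levels encode this 15% split; the alternative
# "~4-fold below the double mutant" phrasing does not reconcile with
# it and is not encoded.)
name: fig6
protein: FBF-2
max_cd: 35
peak_window: [8, 13]
peak_stat: max
base_cd: 35
control: wild_type
untagged: untagged_n2
background_level: 100.0
signal_scale: 5.0
noise_sd_pct: 2.0
n_germlines: 24
decomposition:
  reference: gld2_gld1
  pathway_null: gld2_gld1_glp1
  targets_null: gld2_gld1_lst1_sygl1
genotypes:
  wild_type:
    tagged: true
    levels_pct: [[1, 55], [8, 100], [13, 100], [35, 25]]
  gld2_gld1:
    tagged: true
    levels_pct: [[1, 45], [8, 80], [13, 80], [18, 20], [35, 20]]
  gld2_gld1_glp1:
    tagged: true
    levels_pct: [[1, 12], [35, 12]]
  gld2_gld1_lst1_sygl1:
    tagged: true
    levels_pct: [[1, 12], [35, 12]]
  untagged_n2:
    tagged: false
    levels_pct: [[1, 0], [35, 0]]
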