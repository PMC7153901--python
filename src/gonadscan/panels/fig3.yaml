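# LAG-1 accumulation panel over the distal 25 cd (HA-tagged protein,
# mid/late-L4 gonads). Levels are percent of the wild-type peak: the
# internal normalization sets the wild-type mean at 4 cd to 100.
# Wild type falls ~7-fold from peak to a proximal base (~14.3% of
# peak) reached by ~17 cd. Loss of the meiotic-entry pathway
# (gld-2 gld-1) elevates the peak by ~25% and the 25-cd base 4.5-fold.
# Removing Notch signaling in that background (glp-1 null) leaves 39%
# of the gld-2 gld-1 peak (signaling-independent fraction, with a
# gradual distal-to-proximal rise); removing only the target genes
# (lst-1 sygl-1 null) leaves 70% of it. The untagged strain carries
# non-specific staining only and is used for background subtraction.
name: fig3
protein: LAG-1
max_cd: 25
peak_window: [4]
peak_stat: mean
base_cd: 25
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
    levels_pct: [[1, 95], [4, 100], [5, 95], [17, 14.2857], [25, 14.2857]]
  gld2_gld1:
    tagged: true
    levels_pct: [[1, 118], [4, 125], [5, 118], [17, 64.2857], [25, 64.2857]]
  gld2_gld1_glp1:
    tagged: true
    levels_pct: [[1, 44], [4, 48.75], [25, 60]]
  gld2_gld1_lst1_sygl1:
    tagged: true
    levels_pct: [[1, 82], [4, 87.5], [17, 64.2857], [25, 64.2857]]
  untagged_n2:
    tagged: false
    levels_pct: [[1, 0], [25, 0]]
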