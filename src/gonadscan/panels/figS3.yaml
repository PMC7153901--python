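# Proximal repression of LAG-1 by the meiotic-entry pathway, distal
# 25 cd. Levels are percent of the wild-type peak. At the 25-cd base
# LAG-1 is elevated ~4.5-fold in the gld-2 gld-1 double null and
# almost 3-fold in the gld-1 single null; gld-2 loss alone has no
# effect.
name: figS3
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
genotypes:
  wild_type:
    tagged: true
    levels_pct: [[1, 95], [4, 100], [5, 95], [17, 14.2857], [25, 14.2857]]
  gld1:
    tagged: true
    levels_pct: [[1, 95], [4, 100], [5, 95], [17, 42.857], [25, 42.857]]
  gld2:
    tagged: true
    levels_pct: [[1, 95], [4, 100], [5, 95], [17, 14.2857], [25, 14.2857]]
  gld2_gld1:
    tagged: true
    levels_pct: [[1, 118], [4, 125], [5, 118], [17, 64.2857], [25, 64.2857]]
  untagged_n2:
    tagged: false
    levels_pct: [[1, 0], [25, 0]]
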