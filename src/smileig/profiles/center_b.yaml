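# Center B profile: marginals are [median, p25, p75].
name: B
n_eyes: 702
male_fraction: 0.634
marginals:
  age: [19, 18, 22]
  pre_sd: [-4.38, -5.75, -3.25]
  pre_cd: [-0.75, -1.00, -0.25]
  pre_se: [-4.75, -6.13, -3.50]
  pre_cct: [534, 516, 554]
  pre_km: [43.1, 42.2, 44.1]
ranges:
  optical_zone: [6.2, 7.0]
  cap_thickness: [110, 140]
  laser_energy: [125, 145]
k_spread: 1.5
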