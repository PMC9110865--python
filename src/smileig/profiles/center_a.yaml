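# Center A profile: marginals are [median, p25, p75].
name: A
n_eyes: 818
male_fraction: 0.510
marginals:
  age: [21, 9, 25]
  pre_sd: [-5.00, -6.25, -4.00]
  pre_cd: [-0.75, -1.25, -0.25]
  pre_se: [-5.38, -6.50, -4.38]
  pre_cct: [551, 532, 573]
  pre_km: [43.1, 42.2, 44.0]
ranges:
  optical_zone: [6.2, 7.0]
  cap_thickness: [110, 140]
  laser_energy: [125, 145]
k_spread: 1.5
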