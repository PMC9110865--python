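# Center C profile: marginals are [median, p25, p75].
name: C
n_eyes: 830
male_fraction: 0.683
marginals:
  age: [20, 18, 23]
  pre_sd: [-4.50, -5.50, -3.50]
  pre_cd: [-0.50, -1.00, 0.00]
  pre_se: [-4.75, -5.75, -3.75]
  pre_cct: [550, 532, 571]
  pre_km: [42.7, 41.9, 43.6]
ranges:
  optical_zone: [6.2, 7.0]
  cap_thickness: [110, 140]
  laser_energy: [125, 145]
k_spread: 1.5
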