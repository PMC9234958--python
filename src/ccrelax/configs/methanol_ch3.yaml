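# End-to-end methanol scenario: negative-DNP hyperpolarized 13CH3, transfer
# stand-in of 12 s at the detection field, parallel 1H/13C detection.
name: methanol_ch3
kind: scenario
system: ch3_methanol
B0_T: 11.7
combo: {Hz: -1.0, Cz: -0.01, AE: 3.0}
reference_polarization: 0.1
pre_delay_s: 12.0
mechanisms: [DD_CH-CH, DD_HH-HH, DD_CH-HH, CSA, CSA-DD, rnd]
rho_eq: thermal
detection:
  flip_angles: {1H: 1.0, 13C: 30.0}
  interval_s: 1.0
  n_scans: 60
noise_sigma: 0.02
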