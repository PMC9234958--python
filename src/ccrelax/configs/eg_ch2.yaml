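# End-to-end ethylene glycol scenario: hyperpolarized 13CH2 with a
# triplet-singlet imbalance, 34 s transfer stand-in, 13C-only detection.
name: eg_ch2
kind: scenario
system: ch2_eg
B0_T: 11.7
combo: {Hz: 1.0, Cz: 0.01, TS: 0.5}
reference_polarization: 0.1
pre_delay_s: 34.0
mechanisms: [DD_CH-CH, DD_HH-HH, DD_CH-HH, CSA, CSA-DD, rnd]
rho_eq: thermal
detection:
  flip_angles: {13C: 10.0}
  interval_s: 1.0
  n_scans: 60
noise_sigma: 0.02
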