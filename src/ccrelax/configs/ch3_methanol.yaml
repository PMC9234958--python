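# Methanol-like 13CH3 fragment (ideal tetrahedral geometry, r_CH = 1.09 A).
# Motional model: isotropic tumbling (tau_c) plus fast internal rotation about
# the C3 axis (Woessner rotating top, tau_rotation).  The random-field
# amplitude is calibrated so the 12CH3 proton decay is mono-exponential with
# the fixture time constant proton_t1_fixture_s (R1 = 2a + coherent share).
name: ch3_methanol
kind: spin_system
spins:
  - {label: C,  isotope: 13C, shift_ppm: 50.0, xyz: [0.0, 0.0, 0.0],
     csa_ppm: 25.0, csa_axis: [0.0, 0.0, 1.0]}
  - {label: H1, isotope: 1H, shift_ppm: 3.4, xyz: [1.027662, 0.0, -0.363333],
     csa_ppm: 1.0, csa_axis: [1.027662, 0.0, -0.363333]}
  - {label: H2, isotope: 1H, shift_ppm: 3.4, xyz: [-0.513831, 0.889981, -0.363333],
     csa_ppm: 1.0, csa_axis: [-0.513831, 0.889981, -0.363333]}
  - {label: H3, isotope: 1H, shift_ppm: 3.4, xyz: [-0.513831, -0.889981, -0.363333],
     csa_ppm: 1.0, csa_axis: [-0.513831, -0.889981, -0.363333]}
j_couplings:
  - {pair: [C, H1], hz: 140.0}
  - {pair: [C, H2], hz: 140.0}
  - {pair: [C, H3], hz: 140.0}
  - {pair: [H1, H2], hz: -12.0}
  - {pair: [H1, H3], hz: -12.0}
  - {pair: [H2, H3], hz: -12.0}
tau_c: 5.0e-12
rotation_axis: [0.0, 0.0, 1.0]
tau_rotation: 5.0e-13
random_field: 0.0663402669          # s^-1, calibrated (see header)
proton_t1_fixture_s: 5.0
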