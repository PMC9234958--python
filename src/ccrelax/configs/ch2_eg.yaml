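# Ethylene-glycol-like 13CH2 fragment (ideal tetrahedral geometry, rigid
# isotropic tumbling).  tau_c and the random-field amplitude are calibrated
# jointly against the proton fixture decay with the coherent mechanisms
# supplying half of the rate (see package docs).
name: ch2_eg
kind: spin_system
spins:
  - {label: C,  isotope: 13C, shift_ppm: 63.0, xyz: [0.0, 0.0, 0.0],
     csa_ppm: 30.0, csa_axis: [0.0, 0.0, 1.0]}
  - {label: H1, isotope: 1H, shift_ppm: 3.7, xyz: [0.889981, 0.0, -0.629312],
     csa_ppm: 1.0, csa_axis: [0.889981, 0.0, -0.629312]}
  - {label: H2, isotope: 1H, shift_ppm: 3.7, xyz: [-0.889981, 0.0, -0.629312],
     csa_ppm: 1.0, csa_axis: [-0.889981, 0.0, -0.629312]}
j_couplings:
  - {pair: [C, H1], hz: 142.0}
  - {pair: [C, H2], hz: 142.0}
  - {pair: [H1, H2], hz: -12.0}
tau_c: 6.21132193e-12
random_field: 0.0833623397          # s^-1, calibrated (see header)
proton_t1_fixture_s: 3.0
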