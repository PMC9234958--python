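# Methods

This note records the physical model behind `ccrelax`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the numerical
conventions that make results reproducible.

## Spin systems and basis conventions

Systems are small sets of spin-1/2 nuclei (¹H, ¹³C supported; ²H is declared
but quadrupolar relaxation is out of scope). The Hilbert space is the tensor
product in the order the spins are listed — the bundled builders put the
carbon first — with |m=+1/2⟩ before |m=−1/2⟩ within each spin. Geometry is
Cartesian (Å); the default CHn fragments use ideal tetrahedral geometry with
r(C–H) = 1.09 Å, hence r(H–H) = 1.78 Å for the methyl. Scalar couplings
default to ¹J(CH) = 140 Hz (methyl) / 142 Hz (methylene) and ²J(HH) = −12 Hz;
the HH coupling between equivalent protons has no first-order spectral effect
but is kept in the Hamiltonian, where it usefully splits the singlet from the
central triplet state so that eigenstate labeling is unambiguous.

Simulations run in the multiply rotating frame (Zeeman terms reduce to
chemical-shift offsets; heteronuclear J truncated to its secular IzSz part).
The lab-frame Hamiltonian, with absolute Zeeman energies and full isotropic J,
is kept for two purposes: Boltzmann populations at 298 K and the
eigenfrequencies at which the relaxation spectral densities are sampled.

Energy levels are tagged (manifold, ¹³C α/β) by maximal squared overlap with
(carbon Zeeman) × (symmetry-adapted proton manifold) candidates. Within
numerically degenerate clusters the eigenvectors are rotated onto those
candidates, so the conjugate Eₐ/E_b methyl manifolds come out cleanly; a
cluster that spans both carbon Zeeman states (e.g. everything at B₀ = 0 with
J = 0) has no physical α/β distinction and is reported ambiguous rather than
labeled. The ambiguity threshold is a squared overlap of 0.8.

## Relaxation model

All rank-2 interactions share the normalized spectral density

    J(ω) = (2/5) τc / (1 + ω² τc²),

with each interaction carrying its own amplitude (Haeberlen anisotropy of the
coupling tensor): 2·b_ij for a dipolar pair with
b_ij = −(μ₀/4π) γ_i γ_j ħ / r_ij³, and (2/3)·Δσ·ω₀ for an axially symmetric
CSA. With these conventions the heteronuclear two-spin population block
reproduces the Solomon equations exactly (verified to 1e−8 relative over
τc ∈ {1 ps, 100 ps, 10 ns} × B₀ ∈ {1 mT, 1 T, 11.7 T}), and a single spin
with CSA relaxes at R₁ = (2/15)(Δσ ω₀)² τc in extreme narrowing.

The Redfield superoperator is built in the eigenbasis of the lab-frame
Hamiltonian as a sum of double commutators Σ_q [T_q^a, [K_q^b, ρ]], where
K_q^b samples J at the eigenfrequency differences. Correlated pairs of
interactions (DD–DD between different pairs, CSA–CSA between different spins,
CSA–DD) are weighted by P₂(cos θ) of their inter-axis angle, computed from the
explicit geometry. Components are grouped into six named mechanisms —
`DD_CH-CH`, `DD_HH-HH`, `DD_CH-HH`, `CSA`, `CSA-DD`, `rnd` — each of which can
be excluded to ablate a pathway. Imaginary parts of the half-Fourier
transforms (dynamic frequency shifts) are dropped; the superoperator is
explicitly symmetrized so it maps Hermitian operators to Hermitian operators.

**Secularization.** Elements connecting coherences whose eigenfrequencies
differ by more than 10× the largest relaxation rate are zeroed; populations
(and degenerate zero-quantum blocks) are always retained. Population–coherence
cross blocks are therefore dropped at high field by the frequency criterion,
not by fiat; the unsecularized operator is available with `secular=False`.

**Random field.** Each spin sees an isotropic fluctuating field with aggregate
amplitude a = ω_rf²·τ (units s⁻¹; an isolated spin relaxes at R₁ = 2a in
extreme narrowing). By default the field is *fully correlated across spins of
the same isotope* and independent between isotopes: a global fluctuating field
over the equivalent protons preserves the proton permutation symmetry, so the
random field relaxes T and A manifold populations efficiently but cannot mix
T↔S or A↔E — and, being independent of the carbon's field, cannot convert
proton into carbon polarization. Per-spin independent fields (which do relax
the singlet) remain available via `correlation="independent"`.

**Internal methyl rotation.** Besides rigid isotropic tumbling (the default
for generic systems), a Woessner rotating-top model is available: the
orientational correlation of each interaction pair splits into m = 0, 1, 2
components about the rotation axis with weights
d²ₘ₀(β_a) d²ₘ₀(β_b) cos(mΔφ) and correlation times
1/τ_m = 1/τc + m²/τ_rot, which sum back to P₂(cos θ_ab) as τ_rot → ∞ (the
rigid limit is verified to machine precision). The bundled methanol system
uses this model with τ_rot = τc/10 — a nearly free methyl rotor — because a
rigid methyl is not a realistic motional model; the slow (m = 0) parts of the
three C–H dipoles then share the C₃ axis, which qualitatively changes the
cross-correlated pathways.

## Calibration of relaxation parameters

Absolute rates are pinned by the bundled proton-decay fixture: a clean
mono-exponential decay of the carbon-12 (proton-only) species with
T₁ = 5.0 s (methanol) or 3.0 s (ethylene glycol). These time constants are
the package's declared stand-ins for the observed mono-exponential ¹H decay
of the natural-abundance species; they are stored in the configs, not in code.

The calibration simulates the proton-only species, fits a single exponential
to the total ¹H signal over 0–60 s, and adjusts parameters until the fitted
rate matches the fixture:

- methanol: τc = 5 ps and τ_rot = 0.5 ps are declared; only the random-field
  amplitude is solved (stored value 0.0663 s⁻¹);
- ethylene glycol: one fixture constant cannot pin down both τc and the
  amplitude, so a declared split is used — the coherent (DD + CSA) mechanisms
  supply half the fitted rate, the random field the rest
  (τc = 6.21 ps, a = 0.0834 s⁻¹).

The carbon random-field amplitude is set equal to the proton one.

## Hyperpolarized states and their units

Initial states are affine combinations
ρ = 1/d + (p/d)(c_H Σᵢ2H_iz + c_C 2Cz + c_X Q_X) with
Q_AE = P_E − P_A (equal ranks; eigenvalue +1 on every E level) and
Q_TS = P_S − P_T/3 (rank-balanced). Positive imbalance coefficients
overpopulate E (or S), the situation after negative DNP. At reference
polarization p = 1, c_H = 1 means 100% proton polarization; the bundled
scenarios use p = 0.1 so that the literature combination −1:−0.01:3 maps to
physical (nonnegative) populations — detected line *ratios* are invariant
under p because the whole pipeline is affine in the deviation. Combinations
producing negative populations are rejected with the offending level named.
The absolute normalization of the imbalance coefficient is a convention (the
original report defines its "3" only in supporting material); conclusions are
insulated from it by letting the fit stage estimate the coefficients freely.

## Propagation, detection, transfer

dρ/dt = −i[H,ρ] − R(ρ−ρ_eq) is solved exactly per interval by exponentiating
the augmented affine Liouvillian (dimensions ≤ 256 make this cheap; no ODE
tolerances to tune). ρ_eq is the 298 K Boltzmann state by default; the
infinite-temperature reference ρ_eq = 1/d is used to isolate mechanism effects
on the hyperpolarized scale, where thermal polarizations (~10⁻⁵) would
otherwise force trivial late-time zero crossings. Trace and Hermiticity are
guarded at every stored step (tolerance 1e−9; a single exponential step
spanning hundreds of seconds accumulates ~1e−10 of round-off).

The detection train applies simultaneous read rotations (default 1° ¹H / 30°
¹³C, once per second), records the signed per-line ¹³C multiplet intensities
of the rotated state, keeps the eigenbasis-diagonal (population) part — the
cos-scaled longitudinal orders; coherences dephase within the 1 s between
scans and, secularized, do not feed back into populations — and propagates one
interval. Line m (total proton projection) has intensity Tr(ρ_rot·2Cx·P_m);
lines are indexed left to right from the highest proton projection. Transverse
evolution during acquisition is not simulated: line intensities are amplitudes
at pulse time, synthesized into spectra as Lorentzians when needed.

`backpropagate_window` applies the initial combination at t = −pre_delay
(12 s methyl, 34 s methylene by default) so that t = 0 coincides with the
first detection pulse. Optionally the pre-detection window follows a piecewise
field profile (bundled 4 s and 5 s transfer layouts with 0.21 T solenoid,
0.57 T tunnel and sub-mT gap segments); each segment's random-field amplitudes
are augmented by the sPRE rate at that field, Γ₁(B)/2, and the report states
the "equivalent time" the transfer is worth at the detection field — the
mechanism by which a 4–5 s transfer with a low-field passage matches the
10-s-scale constant-field windows the back-extrapolation requires.

## sPRE model

Outer-sphere, force-free translational diffusion:
Γ₁ = (32π/405)(μ₀/4π)² γ_I²γ_S² ħ² S(S+1) (N_s/dD) [3 j(ω_I) + 7 j(ω_S)],
with the Hwang–Freed spectral density in z = √(2ωτ), τ = d²/D. Defaults for
TEMPOL in water: d = 3.5 Å, D = 2.71e−9 m²/s, S = 1/2, 0.36 mM — the residual
radical concentration after dissolution. Electron relaxation is a config hook
(T1e shortens the effective correlation time); by default it is slow. The rate
is linear in concentration, ≈5× larger at 1 mT than at 11.7 T with the
defaults, and approaches the nuclear-only dispersion branch at high field.

## Synthetic data

`generate_decay_curves` forward-simulates per-line intensities (once per
second, small flip angles) and adds i.i.d. Gaussian noise, σ expressed as a
fraction of the dataset maximum; seeds are mandatory whenever noise is drawn
and datasets are byte-identical for a fixed seed. Ground truth travels in a
JSON sidecar, separate from the observations. What the generator does *not*
emulate: heteroscedastic or correlated noise, field/frequency drift, phase and
baseline errors of real spectra, radiation damping, or inter-molecular
relaxation beyond the random-field aggregate. Passing the recovery tests
therefore demonstrates the estimator's correctness under the stated noise
model, not robustness to instrument artifacts.

## Fitting

Because propagation, pulses and line projections are affine in the density
operator, the per-line signal is baseline + X·c in the combination
coefficients. The design matrix is built from one forward simulation per
component, the solve is ordinary least squares, and standard errors and
t-based confidence intervals follow classically (under 2% Gaussian noise the
95% intervals cover each generating coefficient in ≈95% of repeats). A fit is
flagged unidentifiable when the column-scaled design matrix has condition
number above 1e3 — full multi-line designs sit at 10–20, while a dataset
stripped to a single line's trace can exceed 1e3 when the component responses
become collinear (the methylene case; the methyl single-line design is
marginal rather than flat). τc and the random-field amplitude can additionally
be profiled by nonlinear least squares around the inner linear solve
(`fit(fit_relaxation=True)`); the default fit holds them at their calibrated
values. The Lorentzian multiplet fitter estimates signed amplitudes, a shared
linewidth (per-line optional) and a common center, flags all-zero input as
degenerate and non-convergence explicitly.

## Known limitations

- The printed inverted-quartet ratios of the methanol experiment
  (+0.8:+3.3:+3.1:+1.0, fourth line normalized) are *not* reproduced
  quantitatively by the bundled conditions; the simulation yields
  (−4.4, −2.0, −4.2, +1.0). The shape at t = 0 is controlled by the relative
  weight and sign of the long-lived A–E anti-phase contribution, which depends
  on the imbalance-operator normalization and on motional/CSA parameters that
  the original study specifies only in supporting material. The qualitative
  signatures — sign inversion of ¹³Cz from negative ¹H polarization, its
  abolition when dipolar terms are removed, the symmetry selection rules, and
  the bi-exponential ¹³CH₃ vs mono-exponential ¹²CH₃ proton decay — are all
  reproduced and tested.
- Spins > 1/2 (deuterium), chemical exchange, scalar relaxation of the second
  kind, spin rotation, and explicit electron–nucleus dynamics at level
  anti-crossings are out of scope; the sPRE enters as a rate model only.
- Strong-coupling (second-order) multiplet effects are not modeled; detection
  assumes first-order multiplets, valid at the 11.7 T default.
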